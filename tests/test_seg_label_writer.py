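"""Segmentation objects: the packbits RLE codec (checked against an
independently written decoder and against pydicom's RLE pixel decoder),
the 30-color palette, and lossless label round trips."""

import struct

import numpy as np
import pydicom
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tract2dicom.errors import (
    CorruptFrameError,
    EmptyLabelMapError,
    InvalidInputError,
    NoMatchingReferenceError,
    TooManyLabelsError,
)
from tract2dicom.fixtures import PhantomSpec, make_label_blobs
from tract2dicom.mr_series_writer import save_instances, volume_to_mr_series
from tract2dicom.geometry import ImageVolume
from tract2dicom.seg_label_writer import (
    LabelMap,
    assign_segment_colors,
    describe_segments,
    labelmap_to_seg,
    rle_decode_frame,
    rle_encode_frame,
    seg_to_labelmap,
)


def reference_rle_decode(payload: bytes) -> bytes:
    """Independent packbits decoder, written directly from the run-length
    rules: control 0..127 = that many + 1 literals, 129..255 = replicate
    the next byte 257 - control times, 128 = no-op."""
    offsets = struct.unpack("<16L", payload[:64])
    assert offsets[0] == 1
    data = payload[offsets[1]:]
    out = bytearray()
    i = 0
    while i < len(data):
        ctrl = data[i]
        i += 1
        if ctrl < 128:
            out += data[i:i + ctrl + 1]
            i += ctrl + 1
        elif ctrl > 128:
            out += data[i:i + 1] * (257 - ctrl)
            i += 1
    return bytes(out)


class TestRLECodec:
    def test_replicate_run_worked_example(self):
        """Four 0x07 bytes encode as control 253 (= 257 - 4) + 0x07."""
        frame = rle_encode_frame(b"\x07\x07\x07\x07")
        assert frame.payload[64:66] == bytes([253, 0x07])
        assert reference_rle_decode(frame.payload) == b"\x07\x07\x07\x07"

    def test_literal_run_worked_example(self):
        """Three distinct bytes encode as control 2 + the three literals."""
        frame = rle_encode_frame(b"\x01\x02\x03")
        assert frame.payload[64:68] == bytes([2, 1, 2, 3])
        assert reference_rle_decode(frame.payload)[:3] == b"\x01\x02\x03"

    def test_single_byte_worked_example(self):
        frame = rle_encode_frame(b"\xff")
        assert frame.payload[64:66] == bytes([0, 0xFF])
        assert reference_rle_decode(frame.payload)[:1] == b"\xff"

    def test_header_and_padding_invariants(self):
        for raw in (b"\x01", b"ab", b"abc", b"\x00" * 1001):
            frame = rle_encode_frame(raw)
            assert len(frame.payload) % 2 == 0
            n_seg, first = struct.unpack("<2L", frame.payload[:8])
            assert n_seg == 1 and first == 64
            assert frame.decoded_length == len(raw)

    def test_all_zero_frame_compresses_below_two_percent(self):
        raw = b"\x00" * 4096
        frame = rle_encode_frame(raw)
        # run splitting at 128: 4096/128 = 32 runs of 2 bytes each + header
        assert len(frame.payload) - 64 == 2 * 32
        assert len(frame.payload) - 64 < 0.02 * len(raw)
        assert rle_decode_frame(frame) == raw

    def test_empty_frame_rejected(self):
        with pytest.raises(InvalidInputError):
            rle_encode_frame(b"")

    def test_corrupt_streams_rejected(self):
        header = struct.pack("<16L", 1, 64, *([0] * 14))
        with pytest.raises(CorruptFrameError):
            rle_decode_frame(header + bytes([253]))  # mid replicate run
        with pytest.raises(CorruptFrameError):
            rle_decode_frame(header + bytes([5, 1, 2]), 6)  # mid literal
        with pytest.raises(CorruptFrameError):
            rle_decode_frame(b"\x00" * 10)  # short header
        with pytest.raises(CorruptFrameError):
            rle_decode_frame(struct.pack("<16L", 0, 64, *([0] * 14)))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.binary(min_size=1, max_size=4096))
    def test_codec_identity_on_arbitrary_bytes(self, raw):
        frame = rle_encode_frame(raw)
        assert rle_decode_frame(frame) == raw
        assert reference_rle_decode(frame.payload)[:len(raw)] == raw

    def test_adversarial_run_patterns(self):
        patterns = [
            b"\x01" * 128, b"\x01" * 129, b"\x01" * 257,
            bytes(range(256)) * 3,
            b"ab" * 200,  # alternating, no runs
            b"\x00\x00" + bytes(range(100)) + b"\xff" * 300,
            b"\x80" * 2 + b"\x7f",
        ]
        for raw in patterns:
            assert rle_decode_frame(rle_encode_frame(raw)) == raw


class TestPalette:
    def test_counts_and_distinctness(self):
        assert len(assign_segment_colors(1)) == 1
        colors = assign_segment_colors(30)
        assert len(colors) == 30
        assert len(set(colors)) == 30

    def test_over_limit_and_underflow(self):
        with pytest.raises(TooManyLabelsError):
            assign_segment_colors(31)
        with pytest.raises(InvalidInputError):
            assign_segment_colors(0)

    def test_palette_deterministic_across_calls(self):
        assert assign_segment_colors(12) == assign_segment_colors(12)

    def test_cielab_values_in_range(self):
        for d in describe_segments(range(1, 31)):
            assert all(0 <= c <= 65535 for c in d.cielab)


class TestSegmentDescriptors:
    def test_numbers_consecutive_ascending_by_value(self):
        descs = describe_segments([7, 3])
        assert [(d.segment_number, d.label_value) for d in descs] == \
            [(1, 3), (2, 7)]

    def test_custom_names_applied(self):
        descs = describe_segments([2, 9], names={9: "tumour"})
        assert descs[0].label_text == "Label 2"
        assert descs[1].label_text == "tumour"


def make_reference(shape, affine, template_meta, ctx):
    vol = ImageVolume(np.zeros(shape), affine)
    return volume_to_mr_series(vol, template_meta, ctx)


class TestLabelmapToSeg:
    def test_two_blob_map_recomposes_exactly(self, template_meta, ctx,
                                             tmp_path):
        labels = make_label_blobs(2, PhantomSpec(shape=(8, 8, 4), seed=1),
                                  values=[3, 7])
        ref = make_reference((8, 8, 4), np.eye(4), template_meta, ctx)
        seg = labelmap_to_seg(labels, ref, template_meta, ctx)
        assert len(seg.SegmentSequence) == 2
        assert [int(s.SegmentNumber) for s in seg.SegmentSequence] == [1, 2]
        path = save_instances([seg], tmp_path)[0]
        back = pydicom.dcmread(str(path))
        np.testing.assert_array_equal(seg_to_labelmap(back, ref), labels.data)

    def test_recomposition_via_pydicom_rle_decoder(self, template_meta, ctx,
                                                   tmp_path):
        """pydicom's own RLE Lossless pixel decoder (an independent
        Annex-G implementation) reproduces our frames bit-for-bit."""
        labels = make_label_blobs(4, PhantomSpec(shape=(12, 10, 6), seed=2))
        ref = make_reference((12, 10, 6), np.eye(4), template_meta, ctx)
        seg = labelmap_to_seg(labels, ref, template_meta, ctx)
        path = save_instances([seg], tmp_path)[0]
        back = pydicom.dcmread(str(path))
        frames = back.pixel_array  # (n_frames, rows, cols), RLE-decoded
        ours = [
            np.frombuffer(rle_decode_frame(f, int(back.Rows) *
                                           int(back.Columns)),
                          dtype=np.uint8).reshape(back.Rows, back.Columns)
            for f in pydicom.encaps.generate_frames(
                back.PixelData, number_of_frames=int(back.NumberOfFrames))]
        np.testing.assert_array_equal(frames, np.stack(ours))

    def test_mismatched_affine_raises_no_matching_reference(
            self, template_meta, ctx):
        labels = make_label_blobs(2, PhantomSpec(shape=(8, 8, 4)))
        scaled = np.diag([2.0, 2.0, 2.0, 1.0])
        ref = make_reference((8, 8, 4), scaled, template_meta, ctx)
        with pytest.raises(NoMatchingReferenceError):
            labelmap_to_seg(labels, ref, template_meta, ctx)

    def test_single_voxel_label(self, template_meta, ctx, tmp_path):
        data = np.zeros((6, 6, 3), dtype=int)
        data[2, 3, 1] = 1
        labels = LabelMap(data=data, affine=np.eye(4))
        ref = make_reference((6, 6, 3), np.eye(4), template_meta, ctx)
        seg = labelmap_to_seg(labels, ref, template_meta, ctx)
        assert len(seg.SegmentSequence) == 1
        assert int(seg.NumberOfFrames) == 1
        np.testing.assert_array_equal(seg_to_labelmap(seg, ref), data)

    def test_all_zero_map_rejected(self, template_meta, ctx):
        labels = LabelMap(data=np.zeros((4, 4, 2), dtype=int),
                          affine=np.eye(4))
        ref = make_reference((4, 4, 2), np.eye(4), template_meta, ctx)
        with pytest.raises(EmptyLabelMapError):
            labelmap_to_seg(labels, ref, template_meta, ctx)

    def test_non_integer_labels_rejected_not_rounded(self):
        with pytest.raises(InvalidInputError):
            LabelMap(data=np.full((2, 2, 2), 1.5), affine=np.eye(4))

    def test_over_limit_label_map_rejected(self, template_meta, ctx):
        labels = make_label_blobs(31, PhantomSpec(shape=(32, 32, 32)),
                                  over_limit=True)
        assert len(labels.label_values()) == 31
        ref = make_reference((32, 32, 32), np.eye(4), template_meta, ctx)
        with pytest.raises(TooManyLabelsError):
            labelmap_to_seg(labels, ref, template_meta, ctx)

    def test_frames_reference_matched_series_instances(self, template_meta,
                                                       ctx):
        labels = make_label_blobs(2, PhantomSpec(shape=(8, 8, 4), seed=3))
        ref = make_reference((8, 8, 4), np.eye(4), template_meta, ctx)
        seg = labelmap_to_seg(labels, ref, template_meta, ctx)
        ref_uids = {str(d.SOPInstanceUID) for d in ref}
        assert str(seg.ReferencedSeriesSequence[0].SeriesInstanceUID) == \
            str(ref[0].SeriesInstanceUID)
        for fg in seg.PerFrameFunctionalGroupsSequence:
            src = fg.DerivationImageSequence[0].SourceImageSequence[0]
            assert str(src.ReferencedSOPInstanceUID) in ref_uids

    def test_value_to_segment_mapping_stable_under_voxel_permutation(
            self, template_meta, ctx):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 4, size=(8, 8, 4))
        perm = data.copy().reshape(-1)
        rng.shuffle(perm)
        ref = make_reference((8, 8, 4), np.eye(4), template_meta, ctx)
        seg_a = labelmap_to_seg(LabelMap(data, np.eye(4)), ref,
                                template_meta, ctx)
        seg_b = labelmap_to_seg(LabelMap(perm.reshape(8, 8, 4), np.eye(4)),
                                ref, template_meta, ctx)
        pairs = lambda s: [(int(x.SegmentNumber), str(x.SegmentDescription))
                           for x in s.SegmentSequence]
        assert pairs(seg_a) == pairs(seg_b)
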