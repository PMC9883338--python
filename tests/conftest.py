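import numpy as np
import pytest

from tract2dicom.fixtures import make_minimal_template_dicom
from tract2dicom.mr_series_writer import SeriesContext, load_template


@pytest.fixture
def template_meta(tmp_path):
    path = make_minimal_template_dicom(
        {
            "PatientID": "TEST01",
            "PatientName": "Phantom^Test",
            "PatientBirthDate": "20100101",
            "PatientSex": "O",
            "StudyDate": "20220101",
            "StudyTime": "101500",
            "StudyDescription": "synthetic workup",
            "InstitutionName": "Nowhere General",
        },
        tmp_path / "template.dcm",
    )
    return load_template(path)


@pytest.fixture
def ctx(template_meta):
    return SeriesContext.create(template_meta, rng_seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(20220907)
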