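import numpy as np
import pytest

from metafinger import CohortDesign, SampleRecord, Spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_design():
    """A miniature cohort: 4 patients, 40 ions, two spiked markers."""
    return CohortDesign(
        n_patients=4,
        points_per_tissue=2,
        n_tnbc_serum=6,
        n_hd_serum=6,
        n_ions=40,
        mz_range=(100.0, 200.0),
        marker_spec=((3, 4.0), (17, 0.25)),
        qc_every=5,
        seed=42,
    )


@pytest.fixture
def serum_records():
    """Hand-built serum records for matrix-level tests."""
    return [
        SampleRecord(f"s{i}", "serum", "TNBC" if i < 3 else "HD", "", i)
        for i in range(6)
    ]


def make_spectrum(mz, intensity, polarity="positive"):
    return Spectrum(np.asarray(mz, float), np.asarray(intensity, float), polarity)
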