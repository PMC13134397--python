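import numpy as np
import pytest

import glycopop as gp


@pytest.fixture
def table():
    return gp.DEFAULT_TABLE


@pytest.fixture
def igg1_backbone():
    return "EEQYNSTYR"


@pytest.fixture
def toy_spectrum():
    return gp.Spectrum(
        scan_id="toy",
        precursor_mz=800.0,
        precursor_charge=2,
        retention_time=10.0,
        mz=np.array([204.087, 366.14, 528.19, 1392.59]),
        intensity=np.array([100.0, 40.0, 10.0, 60.0]),
    )


@pytest.fixture
def sim_config():
    return gp.SimulationConfig(seed=42)


def make_spectrum(scan_id, precursor_mz, peaks, charge=2, rt=10.0):
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    return gp.Spectrum(
        scan_id=scan_id,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        retention_time=rt,
        mz=mz,
        intensity=inten,
    )
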