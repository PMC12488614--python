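import numpy as np
import pytest

from calres import build_single_compartment, default_registry, run_chirp
from calres.experiments import calibrate_cat_density


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def calibration():
    """CaT density calibrated against the printed (V-Q, Ca-Q) pair; shared by
    every test that works at the figure-level density."""
    return calibrate_cat_density()


@pytest.fixture(scope="session")
def cat_traces(calibration):
    """The reference single-compartment CaT-only chirp run."""
    model = build_single_compartment({"CaT": calibration.density})
    return run_chirp(model)


@pytest.fixture(scope="session")
def passive_traces():
    """Chirp response of the purely passive single compartment."""
    model = build_single_compartment()
    return run_chirp(model)
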