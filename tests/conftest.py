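import numpy as np
import pytest

from narloop import (CircuitVariant, Scenario, calibrate_all, nominal_params,
                     run_scenario)


@pytest.fixture(scope="session")
def params():
    """Shipped nominal (pre-calibrated) parameter set."""
    return nominal_params()


@pytest.fixture(scope="session")
def calibrated():
    """Parameters re-pinned by the full calibration pipeline."""
    return calibrate_all().params


@pytest.fixture(scope="session")
def nominal_trajs(calibrated):
    """Unperturbed 36 h trajectories for the three production architectures."""
    return {v: run_scenario(Scenario(variant=v, p=0.0), calibrated)
            for v in (CircuitVariant.ANTITHETIC, CircuitVariant.DIRECT,
                      CircuitVariant.OPEN_LOOP)}


@pytest.fixture(scope="session")
def perturbed_trajs(calibrated):
    """Perturbed trajectories per (variant, p) for the step experiments."""
    out = {}
    for v in (CircuitVariant.ANTITHETIC, CircuitVariant.DIRECT,
              CircuitVariant.OPEN_LOOP):
        for p in (0.2, 0.4, 0.6):
            out[(v, p)] = run_scenario(Scenario(variant=v, p=p), calibrated)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
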