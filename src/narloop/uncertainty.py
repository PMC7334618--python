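"""Parameter-uncertainty sampling shared by dose-response and titer ensembles."""

from __future__ import annotations

import numpy as np

from .params import CircuitParams

# kinetic, expression and binding constants of the sensing chain; Hill
# exponents and copy numbers are structural and stay fixed
BIOSENSOR_PARAMS = (
    "kcat_F3H", "Km_F3H", "alpha_aff", "alpha_cat", "kcat_FLS", "Km_FLS",
    "g_bio", "k_E", "d_E", "K_dK", "K_dQ", "beta_leak", "k_A", "d_A",
)


def perturbed_params(params: CircuitParams, rel_uncertainty: float,
                     rng: np.random.Generator,
                     names: tuple[str, ...] = BIOSENSOR_PARAMS,
                     distribution: str = "uniform") -> CircuitParams:
    """One random draw with every listed parameter scaled independently.

    ``uniform`` multiplies by a factor in [1-u, 1+u]; ``lognormal`` uses a
    log-normal factor with the same relative spread (sigma = u in log space).
    """
    if not 0.0 < rel_uncertainty <= 0.5:
        raise ValueError("rel_uncertainty must lie in (0, 0.5]")
    changes = {}
    for name in names:
        if distribution == "uniform":
            factor = rng.uniform(1.0 - rel_uncertainty, 1.0 + rel_uncertainty)
        elif distribution == "lognormal":
            factor = float(np.exp(rng.normal(0.0, rel_uncertainty)))
        else:
            raise ValueError(f"unknown uncertainty distribution {distribution!r}")
        value = getattr(params, name) * factor
        if name == "beta_leak":
            value = min(value, 0.999)
        if name in ("alpha_aff", "alpha_cat"):
            value = max(value, 1.0)
        changes[name] = value
    return params.copy(**changes)
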