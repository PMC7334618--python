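"""Steady-state input-output curves of the biosensor, controller and pathway.

All characterization curves are computed in the frozen-growth frame (biomass
held at the reference density ``OD_ref`` from :func:`narloop.params.char_density`),
where every species has a well-defined steady state; culture concentrations
use the same density, making curve anchors commensurate with 36 h batch titers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import model
from .params import (CircuitParams, char_density, gl_to_molecules, molecules_to_gl,
                     od_integral)
from .simulate import SolverError, controller_steady_chs, sensor_steady_state
from .uncertainty import perturbed_params

log = logging.getLogger(__name__)


@dataclass
class DoseResponseCurve:
    input_name: str
    input_units: str
    response_name: str
    response_units: str
    grid: np.ndarray
    response: np.ndarray
    ensemble: np.ndarray | None = None    # (n_samples, len(grid))
    flags: np.ndarray | None = None       # True where the solve failed

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("input grid must be strictly increasing")
        if self.response.shape != self.grid.shape:
            raise ValueError("response must match the grid length")
        if self.ensemble is not None and self.ensemble.shape[1] != len(self.grid):
            raise ValueError("ensemble rows must match the grid length")

    def to_frame(self):
        import pandas as pd

        base = pd.DataFrame({"input": self.grid, "response": self.response})
        if self.ensemble is None:
            return base
        rows = [base.assign(sample_id=-1)]
        for i, row in enumerate(self.ensemble):
            rows.append(pd.DataFrame({"input": self.grid, "response": row,
                                      "sample_id": i}))
        return pd.concat(rows, ignore_index=True)


def metabolic_dose_response(nar_grid, params: CircuitParams) -> DoseResponseCurve:
    """Steady-state kaempferol (g/L) versus clamped naringenin (g/L)."""
    od_ref, mu_ref = char_density(params)
    grid = np.asarray(nar_grid, dtype=float)
    out = np.empty_like(grid)
    flags = np.zeros(grid.shape, dtype=bool)
    for i, n_gl in enumerate(grid):
        try:
            n = gl_to_molecules(n_gl, params.MW_nar, od_ref, params) if n_gl > 0 else 0.0
            st = sensor_steady_state(n, params, mu=mu_ref)
            out[i] = molecules_to_gl(st.K, params.MW_kae, od_ref, params)
        except (ValueError, SolverError) as err:  # flagged, never silent NaN
            log.warning("metabolic dose-response failed at %.3g g/L: %s", n_gl, err)
            out[i], flags[i] = np.nan, True
    return DoseResponseCurve("naringenin", "g/L", "kaempferol", "g/L", grid, out,
                             flags=flags)


def tf_dose_response(nar_grid, params: CircuitParams) -> DoseResponseCurve:
    """Steady-state anti-sigma output versus clamped naringenin.

    The sigma/anti-sigma annihilation is disabled: this characterizes the
    sensor in isolation, anti-sigma being its output signal.
    """
    od_ref, mu_ref = char_density(params)
    grid = np.asarray(nar_grid, dtype=float)
    out = np.empty_like(grid)
    flags = np.zeros(grid.shape, dtype=bool)
    for i, n_gl in enumerate(grid):
        try:
            n = gl_to_molecules(n_gl, params.MW_nar, od_ref, params) if n_gl > 0 else 0.0
            st = sensor_steady_state(n, params, mu=mu_ref, annihilation=False)
            out[i] = st.A
        except (ValueError, SolverError) as err:
            log.warning("tf dose-response failed at %.3g g/L: %s", n_gl, err)
            out[i], flags[i] = np.nan, True
    return DoseResponseCurve("naringenin", "g/L", "anti_sigma", "molecules/cell",
                             grid, out, flags=flags)


def controller_dose_response(antisigma_grid, params: CircuitParams) -> DoseResponseCurve:
    """Steady-state CHS level versus clamped anti-sigma abundance."""
    _, mu_ref = char_density(params)
    grid = np.asarray(antisigma_grid, dtype=float)
    out = np.array([controller_steady_chs(a, params, mu=mu_ref) for a in grid])
    return DoseResponseCurve("anti_sigma", "molecules/cell", "CHS", "molecules/cell",
                             grid, out)


def production_curve(chs_grid, m_frac: float, params: CircuitParams) -> DoseResponseCurve:
    """36 h naringenin titer (g/L) for a fixed CHS level.

    For constant CHS the batch titer is the (supply-capped) flux times the
    logistic biomass integral; the curve flattens above the nominal operating
    point where the upstream p-coumaroyl supply becomes limiting.
    """
    grid = np.asarray(chs_grid, dtype=float)
    scale = params.rho_cells * params.MW_nar / params.N_A * od_integral(params)
    out = np.array([model.chs_flux(c, m_frac, params) for c in grid]) * scale
    return DoseResponseCurve("CHS", "molecules/cell", "naringenin_titer", "g/L",
                             grid, out)


def open_loop_equivalent_chs(params: CircuitParams, target_titer: float = 1.0) -> float:
    """Fixed CHS level whose constant flux reproduces ``target_titer`` in 36 h."""
    from scipy.optimize import brentq

    scale = params.rho_cells * params.MW_nar / params.N_A * od_integral(params)
    return brentq(lambda c: model.chs_flux(c, 1.0, params) * scale - target_titer,
                  0.0, 1e12, xtol=1e-6)


def feedback_curve(nar_grid, params: CircuitParams) -> DoseResponseCurve:
    """Combined closed-loop dose-response: steady CHS versus clamped naringenin
    through the full biosensor + antithetic controller chain."""
    od_ref, mu_ref = char_density(params)
    grid = np.asarray(nar_grid, dtype=float)
    out = np.empty_like(grid)
    for i, n_gl in enumerate(grid):
        n = gl_to_molecules(n_gl, params.MW_nar, od_ref, params) if n_gl > 0 else 0.0
        out[i] = sensor_steady_state(n, params, mu=mu_ref).CHS
    return DoseResponseCurve("naringenin", "g/L", "CHS", "molecules/cell", grid, out)


@dataclass
class Equilibrium:
    """Result of intersecting a feedback curve with a production curve."""

    crossings: list[tuple[float, float]] = field(default_factory=list)  # (CHS*, N*)

    @property
    def found(self) -> bool:
        return len(self.crossings) > 0

    @property
    def N_star(self) -> float:
        if not self.found:
            raise ValueError("no equilibrium crossing in range")
        return self.crossings[0][1]

    @property
    def CHS_star(self) -> float:
        if not self.found:
            raise ValueError("no equilibrium crossing in range")
        return self.crossings[0][0]


def find_equilibrium(fb: DoseResponseCurve, prod: DoseResponseCurve) -> Equilibrium:
    """Intersect a CHS-vs-naringenin feedback curve with a naringenin-vs-CHS
    production curve by bisection on the interpolated difference.

    The feedback curve maps naringenin (g/L) to CHS; the production curve maps
    CHS to naringenin (g/L). A fixed point satisfies
    prod(fb(N)) = N. All sign-change crossings on the grid are returned.
    """
    if fb.response_name != "CHS" or prod.response_name != "naringenin_titer":
        raise ValueError("expected a CHS feedback curve and a naringenin production curve")

    def g(n):
        chs = np.interp(n, fb.grid, fb.response)
        return np.interp(chs, prod.grid, prod.response) - n

    from scipy.optimize import brentq

    eq = Equilibrium()
    ns = fb.grid
    vals = np.array([g(n) for n in ns])
    for i in range(len(ns) - 1):
        if vals[i] == 0.0:
            eq.crossings.append((float(np.interp(ns[i], fb.grid, fb.response)), float(ns[i])))
        elif vals[i] * vals[i + 1] < 0:
            n_star = brentq(g, ns[i], ns[i + 1], xtol=1e-12)
            eq.crossings.append((float(np.interp(n_star, fb.grid, fb.response)), float(n_star)))
    if vals[-1] == 0.0:
        eq.crossings.append((float(fb.response[-1]), float(ns[-1])))
    return eq


def uncertainty_ensemble(curve_op, rel_uncertainty: float, n_samples: int, seed: int,
                         params: CircuitParams, force_copy_number: int | None = 10,
                         distribution: str = "uniform", **op_kw) -> DoseResponseCurve:
    """Monte-Carlo ensemble of a dose-response curve under biosensor-parameter
    uncertainty (independent uniform factors in [1-u, 1+u] per parameter).

    ``force_copy_number`` pins both plasmids (the study characterizes the
    uncertainty bands at ten copies). Deterministic for a given seed.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if force_copy_number is not None:
        params = params.copy(C_Ns=force_copy_number, C_Nh=force_copy_number)
    mean_curve = curve_op(params=params, **op_kw)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_samples):
        p_i = perturbed_params(params, rel_uncertainty, rng, distribution=distribution)
        rows.append(curve_op(params=p_i, **op_kw).response)
    return DoseResponseCurve(mean_curve.input_name, mean_curve.input_units,
                             mean_curve.response_name, mean_curve.response_units,
                             mean_curve.grid, mean_curve.response,
                             ensemble=np.vstack(rows))
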