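"""Pin the model's free constants to the study's production anchors.

Four anchors define the nominal operating point:

* a 40% malonyl-CoA decrease costs the unregulated pathway ~25% of its
  naringenin (fixes ``Km_M`` in closed form),
* the open-loop strain reaches 1 g/L of naringenin in a 36 h batch
  (fixes ``k_const`` and the upstream supply knee),
* sensing 1 g/L of naringenin converts only 5 ug/L of kaempferol
  (fixes the biosensor expression scale ``g_bio``),
* both controlled variants reach the same 1 g/L nominal titer
  (fixes the AHL set-point for the antithetic loop and ``K_cI`` for the
  direct cI controller).

All solves are deterministic bracketing bisections on a log scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from . import model
from .params import CircuitParams, CircuitVariant, char_density, gl_to_molecules
from .scenarios import Scenario
from .simulate import run_scenario, sensor_steady_state

log = logging.getLogger(__name__)

N_BISECT = 60

# default anchor values
TARGET_TITER = 1.0          # g/L at 36 h, all variants unperturbed
TARGET_KAE = 5.0e-6         # g/L kaempferol at 1 g/L clamped naringenin
TARGET_DROP = 0.25          # open-loop fractional naringenin loss ...
ANCHOR_P = 0.40             # ... under a 40% malonyl-CoA decrease


class CalibrationError(RuntimeError):
    pass


@dataclass
class FittedConstant:
    name: str
    value: float
    anchor: str
    residual: float


@dataclass
class CalibrationResult:
    params: CircuitParams
    fitted: list[FittedConstant] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {f.name: {"value": f.value, "anchor": f.anchor, "residual": f.residual}
                for f in self.fitted}


def _log_bisect(fun, lo: float, hi: float, n_iter: int = N_BISECT, what: str = "") -> float:
    """Bisection for a sign change of ``fun`` on the log10-scaled bracket."""
    flo, fhi = fun(lo), fun(hi)
    if flo == 0:
        return lo
    if fhi == 0:
        return hi
    if flo * fhi > 0:
        raise CalibrationError(
            f"no sign change for {what} in [{lo:.3g}, {hi:.3g}] "
            f"(f(lo)={flo:.3g}, f(hi)={fhi:.3g})")
    llo, lhi = math.log10(lo), math.log10(hi)
    for _ in range(n_iter):
        mid = 0.5 * (llo + lhi)
        fm = fun(10 ** mid)
        if fm == 0:
            return 10 ** mid
        if fm * flo < 0:
            lhi = mid
        else:
            llo, flo = mid, fm
    return 10 ** (0.5 * (llo + lhi))


def calibrate_km_malonyl(target_drop: float = TARGET_DROP, p: float = ANCHOR_P,
                         params: CircuitParams | None = None) -> float:
    """Closed-form Km_M such that a step of fraction ``p`` in malonyl-CoA
    reduces the CHS saturation term by ``target_drop``.

    Solving 1 - (1-p)(Km+M0)/(Km+(1-p)M0) = d gives Km = (1-p) d M0/(p - d).
    """
    if params is None:
        params = CircuitParams()
    if not 0.0 < target_drop < p < 1.0:
        raise CalibrationError(
            f"infeasible anchor: need 0 < target_drop < p < 1, got "
            f"target_drop={target_drop}, p={p}")
    return (1.0 - p) * target_drop * params.M0 / (p - target_drop)


def calibrate_open_loop(target_titer: float = TARGET_TITER,
                        params: CircuitParams | None = None,
                        tol: float = 5e-3) -> CircuitParams:
    """Fit ``k_const`` so the open-loop 36 h unperturbed titer hits the target,
    then set the upstream supply knee at the nominal peak pathway flux."""
    if params is None:
        params = CircuitParams()
    if target_titer == 0:
        return params.copy(k_const=1e-12)
    sc = Scenario(variant=CircuitVariant.OPEN_LOOP, p=0.0)
    # fit with the cap disabled: nominal operation must be supply-unlimited
    base = params.copy(supply_knee=None)

    def res(k):
        return run_scenario(sc, base.copy(k_const=k)).final_titer - target_titer

    k0 = base.k_const
    k_fit = _log_bisect(res, k0 * 1e-6, k0 * 1e6, what="k_const")
    fitted = base.copy(k_const=k_fit)
    traj = run_scenario(sc, fitted)
    resid = abs(traj.final_titer - target_titer) / target_titer
    if resid > tol:
        raise CalibrationError(f"open-loop calibration residual {resid:.2e} > {tol}")
    knee = max(model.raw_chs_flux(c, 1.0, fitted) for c in traj.series("CHS"))
    out = fitted.copy(supply_knee=knee)
    log.info("calibrate_open_loop: k_const=%.6g, supply_knee=%.6g, residual=%.2e",
             k_fit, knee, resid)
    return out


def calibrate_biosensor_gain(target_kaempferol: float = TARGET_KAE,
                             at_naringenin: float = TARGET_TITER,
                             params: CircuitParams | None = None,
                             tol: float = 1e-2) -> CircuitParams:
    """Fit the biosensor-enzyme expression scale ``g_bio`` so the steady-state
    kaempferol at clamped naringenin matches the anchor (both in culture g/L,
    frozen-growth characterization frame)."""
    if params is None:
        params = CircuitParams()
    od_ref, _ = char_density(params)
    n_clamp = gl_to_molecules(at_naringenin, params.MW_nar, od_ref, params)
    k_target = gl_to_molecules(target_kaempferol, params.MW_kae, od_ref, params)

    def res(g):
        return sensor_steady_state(n_clamp, params.copy(g_bio=g)).K - k_target

    g_fit = _log_bisect(res, 1e-6, 1e3, what="g_bio")
    out = params.copy(g_bio=g_fit)
    resid = abs(sensor_steady_state(n_clamp, out).K - k_target) / k_target
    if resid > tol:
        raise CalibrationError(f"biosensor gain residual {resid:.2e} > {tol}")
    log.info("calibrate_biosensor_gain: g_bio=%.6g, residual=%.2e", g_fit, resid)
    return out


def calibrate_setpoints(params: CircuitParams | None = None,
                        target_titer: float = TARGET_TITER,
                        tol: float = 1e-2) -> CircuitParams:
    """Fit the AHL set-point (antithetic) and K_cI (direct) so both controlled
    variants reach the open-loop nominal titer unperturbed."""
    if params is None:
        params = CircuitParams()
    sc_a = Scenario(variant=CircuitVariant.ANTITHETIC, p=0.0)

    def res_a(ahl):
        return run_scenario(sc_a, params.copy(AHL=ahl)).final_titer - target_titer

    ahl = _log_bisect(res_a, 1e-10, 1e-4, what="AHL set-point (antithetic)")
    params = params.copy(AHL=ahl)
    resid_a = abs(run_scenario(sc_a, params).final_titer - target_titer) / target_titer
    if resid_a > tol:
        raise CalibrationError(
            f"antithetic set-point residual {resid_a:.2e} > {tol}")

    sc_d = Scenario(variant=CircuitVariant.DIRECT, p=0.0)

    def res_d(kci):
        return run_scenario(sc_d, params.copy(K_cI=kci)).final_titer - target_titer

    kci = _log_bisect(res_d, 1e-2, 1e6, what="K_cI (direct)")
    params = params.copy(K_cI=kci)
    resid_d = abs(run_scenario(sc_d, params).final_titer - target_titer) / target_titer
    if resid_d > tol:
        raise CalibrationError(f"direct-controller set-point residual {resid_d:.2e} > {tol}")
    log.info("calibrate_setpoints: AHL=%.6g (res %.2e), K_cI=%.6g (res %.2e)",
             ahl, resid_a, kci, resid_d)
    return params


def calibrate_all(params: CircuitParams | None = None,
                  target_titer: float = TARGET_TITER,
                  target_kaempferol: float = TARGET_KAE,
                  target_drop: float = TARGET_DROP,
                  anchor_p: float = ANCHOR_P) -> CalibrationResult:
    """Run the full calibration pipeline and report every fitted constant."""
    if params is None:
        params = CircuitParams()
    km = calibrate_km_malonyl(target_drop, anchor_p, params)
    params = params.copy(Km_M=km)
    params = calibrate_biosensor_gain(target_kaempferol, target_titer, params)
    params = calibrate_open_loop(target_titer, params)
    params = calibrate_setpoints(params, target_titer)

    od_ref, _ = char_density(params)
    n_clamp = gl_to_molecules(target_titer, params.MW_nar, od_ref, params)
    k_target = gl_to_molecules(target_kaempferol, params.MW_kae, od_ref, params)
    fitted = [
        FittedConstant("Km_M", params.Km_M,
                       f"{target_drop:.0%} flux drop at p={anchor_p}", 0.0),
        FittedConstant("g_bio", params.g_bio,
                       f"{target_kaempferol} g/L kaempferol at {target_titer} g/L",
                       abs(sensor_steady_state(n_clamp, params).K - k_target) / k_target),
        FittedConstant("k_const", params.k_const, f"open-loop {target_titer} g/L at 36 h",
                       _titer_residual(params, CircuitVariant.OPEN_LOOP, target_titer)),
        FittedConstant("AHL", params.AHL, f"antithetic {target_titer} g/L at 36 h",
                       _titer_residual(params, CircuitVariant.ANTITHETIC, target_titer)),
        FittedConstant("K_cI", params.K_cI, f"direct {target_titer} g/L at 36 h",
                       _titer_residual(params, CircuitVariant.DIRECT, target_titer)),
    ]
    return CalibrationResult(params=params, fitted=fitted)


def _titer_residual(params: CircuitParams, variant: CircuitVariant, target: float) -> float:
    t = run_scenario(Scenario(variant=variant, p=0.0), params).final_titer
    return abs(t - target) / target
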