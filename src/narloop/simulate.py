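"""Time integration and frozen-growth steady-state solvers."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import model
from .params import S, N_STATES, CircuitParams, CircuitVariant, char_density
from .scenarios import Scenario, Trajectory

log = logging.getLogger(__name__)

RTOL = 1e-8
ATOL = 1e-10
DT_OUT = 0.05  # h, dense-output resolution


class SolverError(RuntimeError):
    """Integration failure; carries the last valid state for diagnostics."""

    def __init__(self, message: str, t_last: float | None = None,
                 y_last: np.ndarray | None = None):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


def initial_state(params: CircuitParams, scenario: Scenario) -> np.ndarray:
    y0 = np.zeros(N_STATES)
    y0[S.OD] = scenario.fixed_OD if scenario.fixed_OD is not None else params.OD0
    if scenario.variant is CircuitVariant.BIOSENSOR_CLAMPED:
        y0[S.N] = scenario.clamp_N
    return y0


def run_scenario(scenario: Scenario, params: CircuitParams,
                 y0: np.ndarray | None = None, rtol: float = RTOL,
                 atol: float = ATOL, dt_out: float = DT_OUT,
                 ideal_controller: bool = False) -> Trajectory:
    """Integrate one scenario and return a dense trajectory.

    The malonyl-CoA step at ``t_on`` is handled by integrating the two smooth
    legs separately so the solver never steps across the discontinuity.
    """
    if y0 is None:
        y0 = initial_state(params, scenario)
    legs = [(0.0, scenario.t_on), (scenario.t_on, scenario.horizon)] \
        if scenario.p > 0 else [(0.0, scenario.horizon)]

    ts, ys = [], []
    y = np.asarray(y0, dtype=float)
    for i, (t0, t1) in enumerate(legs):
        n_pts = max(int(round((t1 - t0) / dt_out)), 2) + 1
        t_eval = np.linspace(t0, t1, n_pts)
        sol = solve_ivp(
            model.rhs, (t0, t1), y, method="LSODA", t_eval=t_eval,
            rtol=rtol, atol=atol,
            args=(params, scenario.variant, scenario, ideal_controller),
        )
        if not sol.success:
            raise SolverError(
                f"integration failed on [{t0}, {t1}] h: {sol.message}",
                t_last=sol.t[-1] if sol.t.size else t0,
                y_last=sol.y[:, -1] if sol.t.size else y,
            )
        y = sol.y[:, -1]
        keep = slice(None) if i == 0 else slice(1, None)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])

    t = np.concatenate(ts)
    ymat = np.clip(np.concatenate(ys, axis=1), 0.0, None)
    return Trajectory(t=t, y=ymat, scenario=scenario, params=params)


# ---------------------------------------------------------------------------
# Frozen-growth (characterization) steady states
# ---------------------------------------------------------------------------

@dataclass
class SensorSteady:
    """Steady state of the biosensor chain for a clamped naringenin input."""

    N: float
    DHK: float
    K: float
    Q_tot: float
    Q_free: float
    pqdoI: float
    A: float
    SIG: float | None
    CHS: float | None
    v_F3H: float
    v_FLS: float
    mu: float


def _bio_enzyme_level(params: CircuitParams, mu: float) -> float:
    return params.g_bio * params.k_E * params.C_Ns / (params.d_E + mu)


def sensor_steady_state(n_clamp: float, params: CircuitParams, mu: float | None = None,
                        annihilation: bool = True) -> SensorSteady:
    """Solve the biosensor cascade at clamped naringenin, dilution ``mu``.

    With ``annihilation=False`` the anti-sigma level is the sensor output in
    isolation (its closed form k_A C_Ns a / (d_A + mu)); with annihilation the
    coupled sigma/anti-sigma balance is solved and the CHS level reported.
    """
    p = params
    if mu is None:
        _, mu = char_density(p)
    if mu <= 0:
        raise ValueError("characterization dilution mu must be positive "
                         "(kaempferol is removed only by dilution)")
    e_bio = _bio_enzyme_level(p, mu)
    q_tot = p.k_E * p.C_Ns / (p.d_E + mu)
    v_f3h, _ = model.biosensor_fluxes(n_clamp, 0.0, e_bio, e_bio, p)

    if v_f3h == 0.0:
        dhk = 0.0
    else:
        def dhk_res(dhk):
            v_fls = p.kcat_FLS * e_bio * dhk / (p.Km_FLS + dhk)
            return v_f3h - v_fls - mu * dhk
        hi = max(v_f3h / mu, 1.0)
        while dhk_res(hi) > 0:
            hi *= 10.0
        dhk = brentq(dhk_res, 0.0, hi, xtol=1e-12, rtol=1e-14)
    v_fls = p.kcat_FLS * e_bio * dhk / (p.Km_FLS + dhk)
    k = v_fls / mu
    q_free = model.free_qdoR(q_tot, k, p)
    act = model.pqdoI_activity(q_free, p)
    prod_a = p.k_A * p.C_Ns * act

    if not annihilation:
        a = prod_a / (p.d_A + mu)
        return SensorSteady(n_clamp, dhk, k, q_tot, q_free, act, a, None, None,
                            v_f3h, v_fls, mu)

    u = model.sigma_production(p)
    sig = _solve_sigma(u, prod_a, mu, p)
    a = prod_a / (p.gamma * sig + p.d_A + mu)
    chs = (p.k_b * p.C_Nh + p.k_c * p.C_Nh * model.sigma_activation(sig, p)) / (p.d_CHS + mu)
    return SensorSteady(n_clamp, dhk, k, q_tot, q_free, act, a, sig, chs,
                        v_f3h, v_fls, mu)


def _solve_sigma(u: float, prod_a: float, mu: float, p: CircuitParams) -> float:
    """Steady free sigma from the coupled annihilation balance."""
    if u <= 0:
        return 0.0

    def res(sig):
        a = prod_a / (p.gamma * sig + p.d_A + mu)
        return u - p.gamma * sig * a - (p.d_S + mu) * sig

    hi = u / (p.d_S + mu)
    return brentq(res, 0.0, hi * (1 + 1e-12), xtol=1e-14, rtol=1e-14)


def controller_steady_chs(a_clamp: float, params: CircuitParams,
                          mu: float | None = None) -> float:
    """Steady CHS for a clamped anti-sigma abundance (controller in isolation)."""
    p = params
    if mu is None:
        _, mu = char_density(p)
    u = model.sigma_production(p)
    sig = u / (p.gamma * a_clamp + p.d_S + mu)
    return (p.k_b * p.C_Nh + p.k_c * p.C_Nh * model.sigma_activation(sig, p)) / (p.d_CHS + mu)


def closed_loop_steady_state(params: CircuitParams, variant: CircuitVariant,
                             mu: float | None = None, m_frac: float = 1.0,
                             ideal_controller: bool = False) -> dict:
    """Algebraic steady state of the full loop at frozen growth.

    Returns a dict of species and fluxes.  For the ideal antithetic controller
    (no dilution of sigma/anti-sigma) the annihilation balance forces the
    sensed anti-sigma production to equal u exactly, which pins kaempferol.
    """
    p = params
    if mu is None:
        _, mu = char_density(p)

    if ideal_controller and variant is CircuitVariant.ANTITHETIC:
        return _ideal_closed_loop(p, mu, m_frac)

    def chs_of_n(n):
        if variant is CircuitVariant.OPEN_LOOP:
            return (p.k_b * p.C_Nh + p.k_const * p.C_Nh) / (p.d_CHS + mu)
        if variant is CircuitVariant.ANTITHETIC:
            return sensor_steady_state(n, p, mu=mu).CHS
        if variant is CircuitVariant.DIRECT:
            st = sensor_steady_state(n, p, mu=mu, annihilation=False)
            ci = p.k_cI * p.C_Ns * st.pqdoI / (p.d_E + mu)
            return (p.k_b * p.C_Nh
                    + p.k_c * p.C_Nh / (1.0 + (ci / p.K_cI) ** p.n_cI)) / (p.d_CHS + mu)
        raise ValueError(f"no closed-loop steady state for variant {variant}")

    e_bio = _bio_enzyme_level(p, mu)

    def res(n):
        v = model.chs_flux(chs_of_n(n), m_frac, p)
        v_f3h, _ = model.biosensor_fluxes(n, 0.0, e_bio, e_bio, p)
        return v - v_f3h - mu * n

    v_max = model.chs_flux(chs_of_n(0.0), m_frac, p)
    if v_max <= 0:
        n_star = 0.0
    else:
        hi = v_max / mu * 2.0
        n_star = brentq(res, 0.0, hi, xtol=1e-6, rtol=1e-12)

    st = sensor_steady_state(n_star, p, mu=mu)
    chs = chs_of_n(n_star)
    out = {"N": n_star, "DHK": st.DHK, "K": st.K, "Q_free": st.Q_free,
           "pqdoI": st.pqdoI, "A": st.A, "SIG": st.SIG, "CHS": chs,
           "v_CHS": model.chs_flux(chs, m_frac, p), "v_F3H": st.v_F3H,
           "v_FLS": st.v_FLS, "mu": mu}
    if variant is CircuitVariant.DIRECT:
        out["CI"] = p.k_cI * p.C_Ns * st.pqdoI / (p.d_E + mu)
        out["A"] = out["SIG"] = 0.0
    if variant is CircuitVariant.OPEN_LOOP:
        out["A"] = out["SIG"] = 0.0
    return out


def _ideal_closed_loop(p: CircuitParams, mu: float, m_frac: float) -> dict:
    u = model.sigma_production(p)
    cap = p.k_A * p.C_Ns
    a_req = u / cap
    q_tot = p.k_E * p.C_Ns / (p.d_E + mu)
    a_min = model.pqdoI_activity(q_tot, p)
    if not a_min < a_req < 1.0:
        raise ValueError(
            f"set-point infeasible for ideal controller: required PqdoI activity "
            f"{a_req:.3g} outside ({a_min:.3g}, 1)")
    # invert activity -> Q_free -> K
    b = p.beta_leak
    q_free = p.K_dQ * ((1.0 - b) / (a_req - b) - 1.0) ** (1.0 / p.n_Q)
    k = p.K_dK * (q_tot / q_free - 1.0) ** (1.0 / p.n_K)
    v_fls = mu * k
    e_bio = _bio_enzyme_level(p, mu)
    dhk = v_fls * p.Km_FLS / (p.kcat_FLS * e_bio - v_fls)
    v_f3h = v_fls + mu * dhk
    c_lin = (p.kcat_F3H / p.alpha_cat) * e_bio
    n = v_f3h * p.alpha_aff * p.Km_F3H / (c_lin - v_f3h)
    v_chs = v_f3h + mu * n
    # invert the (possibly capped) flux for CHS, then sigma
    v_raw = _invert_supply_cap(v_chs, p)
    cou_sat = p.Cou_ss / (p.Km_cou + p.Cou_ss)
    m = m_frac * p.M0
    m_sat = m / (p.Km_M + m)
    chs = v_raw / (p.kcat_CHS * cou_sat * m_sat)
    f_needed = (chs * (p.d_CHS + mu) - p.k_b * p.C_Nh) / (p.k_c * p.C_Nh)
    if not 0.0 < f_needed < 1.0:
        raise ValueError("required P20 activation outside (0, 1); actuator saturated")
    sig = p.K_sigma * (f_needed / (1.0 - f_needed)) ** (1.0 / p.n_sigma)
    a = u / (p.gamma * sig)
    return {"N": n, "DHK": dhk, "K": k, "Q_free": q_free, "pqdoI": a_req,
            "A": a, "SIG": sig, "CHS": chs, "v_CHS": v_chs, "v_F3H": v_f3h,
            "v_FLS": v_fls, "mu": mu}


def _invert_supply_cap(v_eff: float, p: CircuitParams) -> float:
    knee = p.supply_knee
    if knee is None or v_eff <= knee:
        return v_eff
    span = (p.supply_cap_ratio - 1.0) * knee
    if v_eff >= knee + span:
        raise ValueError("flux above the supply cap asymptote is unreachable")
    return knee - span * np.log1p(-(v_eff - knee) / span)
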