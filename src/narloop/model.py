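"""Rate laws and ODE right-hand side for the regulated naringenin circuit.

The circuit couples three blocks (see the methods note for the full model):

* a Michaelis-Menten production pathway where CHS converts p-coumaroyl-CoA and
  malonyl-CoA into naringenin,
* an extended metabolic biosensor in which deliberately detuned F3H/FLS enzymes
  convert a trace of naringenin into kaempferol, which sequesters the QdoR
  repressor and thereby de-represses anti-sigma expression from PqdoI,
* an antithetic integral controller in which sigma (produced at a constant,
  AHL-set rate u) and anti-sigma annihilate each other; free sigma activates
  CHS expression from the P20 promoter, closing the loop.

Comparison architectures: a direct cI repressor controller (proportional-like
feedback, no integrator) and an open loop with constitutive CHS.
"""

from __future__ import annotations

import math

import numpy as np

from .params import S, N_STATES, CircuitParams, CircuitVariant
from .scenarios import Scenario


def growth_rate(od: float, params: CircuitParams) -> float:
    """Logistic specific growth rate mu = mu_max (1 - OD/OD_max), 1/h."""
    if od < 0 or od > params.OD_max * (1 + 1e-9):
        raise ValueError(f"OD {od} outside [0, OD_max]")
    return params.mu_max * (1.0 - min(od, params.OD_max) / params.OD_max)


def raw_chs_flux(chs: float, m_frac: float, params: CircuitParams) -> float:
    """Uncapped CHS production flux (molecules/cell/h)."""
    if chs < 0 or not 0.0 <= m_frac <= 1.0:
        raise ValueError("chs_flux requires CHS >= 0 and m_frac in [0, 1]")
    cou_sat = params.Cou_ss / (params.Km_cou + params.Cou_ss)
    m = m_frac * params.M0
    m_sat = m / (params.Km_M + m) if m > 0 else 0.0
    return params.kcat_CHS * chs * cou_sat * m_sat


def supply_cap(v_raw: float, params: CircuitParams) -> float:
    """Upstream-supply saturation of the pathway flux.

    The p-coumaroyl pool is replenished at a finite rate: below the knee the
    pathway is CHS-limited and flux passes through unchanged; above it, flux
    saturates smoothly toward ``supply_cap_ratio * knee`` (C1 at the knee).
    The knee is set by calibration to the nominal operating flux, so nominal
    and sub-nominal behavior is exactly supply-unlimited.
    """
    knee = params.supply_knee
    if knee is None or v_raw <= knee:
        return v_raw
    span = (params.supply_cap_ratio - 1.0) * knee
    return knee + span * (1.0 - math.exp(-(v_raw - knee) / span))


def chs_flux(chs: float, m_frac: float, params: CircuitParams) -> float:
    """Naringenin production flux including the upstream supply cap."""
    return supply_cap(raw_chs_flux(chs, m_frac, params), params)


def biosensor_fluxes(n: float, dhk: float, f3h: float, fls: float,
                     params: CircuitParams) -> tuple[float, float]:
    """Detuned F3H and native FLS fluxes (molecules/cell/h)."""
    if min(n, dhk, f3h, fls) < 0:
        raise ValueError("biosensor_fluxes requires non-negative inputs")
    v_f3h = (params.kcat_F3H / params.alpha_cat) * f3h * n / (params.alpha_aff * params.Km_F3H + n)
    v_fls = params.kcat_FLS * fls * dhk / (params.Km_FLS + dhk)
    return v_f3h, v_fls


def free_qdoR(q_tot: float, k: float, params: CircuitParams) -> float:
    """Free QdoR after fast-equilibrium sequestration by kaempferol."""
    if q_tot < 0 or k < 0:
        raise ValueError("free_qdoR requires non-negative inputs")
    return q_tot / (1.0 + (k / params.K_dK) ** params.n_K)


def pqdoI_activity(q_free: float, params: CircuitParams) -> float:
    """Normalized PqdoI promoter activity in (0, 1], repressed by free QdoR."""
    if q_free < 0:
        raise ValueError("pqdoI_activity requires non-negative input")
    b = params.beta_leak
    return b + (1.0 - b) / (1.0 + (q_free / params.K_dQ) ** params.n_Q)


def luxr_occupancy(params: CircuitParams) -> float:
    """LuxR occupancy at its constitutive quasi-equilibrium level.

    LuxR is expressed from the single-copy genomic induction cassette, so its
    level (and hence u) is independent of the plasmid copy numbers.
    """
    luxr_ss = params.k_E / params.d_E
    return luxr_ss / (params.K_LuxR + luxr_ss)


def sigma_production(params: CircuitParams) -> float:
    """Constant sigma synthesis rate u (molecules/cell/h); the set-point knob."""
    if params.AHL < 0:
        raise ValueError("AHL must be non-negative")
    if params.AHL == 0:
        return 0.0
    ahl_n = params.AHL ** params.n_AHL
    act = ahl_n / (params.K_AHL ** params.n_AHL + ahl_n)
    return params.k_S * act * luxr_occupancy(params)


def sigma_activation(sig: float, params: CircuitParams) -> float:
    """Fractional activation of the sigma-dependent P20 promoter."""
    s_n = sig ** params.n_sigma
    return s_n / (params.K_sigma ** params.n_sigma + s_n)


def rhs(t: float, state: np.ndarray, params: CircuitParams, variant: CircuitVariant,
        scenario: Scenario, ideal_controller: bool = False) -> np.ndarray:
    """Full derivative of the 13-dimensional circuit state.

    ``ideal_controller`` drops dilution/degradation of the sigma/anti-sigma
    pair, the textbook condition under which their annihilation implements a
    perfect integrator.
    """
    if not isinstance(variant, CircuitVariant):
        raise ValueError(f"unknown circuit variant: {variant!r}")
    y = np.maximum(state, 0.0)  # solver may probe slightly negative values
    p = params
    dy = np.zeros(N_STATES)

    od = y[S.OD]
    if scenario.fixed_OD is not None:
        od = scenario.fixed_OD
        mu = growth_rate(od, p)
        dy[S.OD] = 0.0
    else:
        mu = growth_rate(od, p)
        dy[S.OD] = mu * od

    n = scenario.clamp_N if variant is CircuitVariant.BIOSENSOR_CLAMPED else y[S.N]
    m_frac = scenario.m_frac(t)

    # constitutive proteins (per-copy expression minus degradation + dilution)
    dy[S.F3H] = p.g_bio * p.k_E * p.C_Ns - (p.d_E + mu) * y[S.F3H]
    dy[S.FLS] = p.g_bio * p.k_E * p.C_Ns - (p.d_E + mu) * y[S.FLS]
    dy[S.QDOR] = p.k_E * p.C_Ns - (p.d_E + mu) * y[S.QDOR]
    dy[S.LUXR] = p.k_E - (p.d_E + mu) * y[S.LUXR]

    # metabolic fluxes
    v_chs = chs_flux(y[S.CHS], m_frac, p)
    v_f3h, v_fls = biosensor_fluxes(n, y[S.DHK], y[S.F3H], y[S.FLS], p)

    dy[S.N] = 0.0 if variant is CircuitVariant.BIOSENSOR_CLAMPED \
        else v_chs - v_f3h - mu * y[S.N]
    dy[S.DHK] = v_f3h - v_fls - mu * y[S.DHK]
    dy[S.K] = v_fls - mu * y[S.K]  # dilution by growth is kaempferol's only sink

    # sensing
    a_pqdoI = pqdoI_activity(free_qdoR(y[S.QDOR], y[S.K], p), p)

    controlled = 0.0
    if variant in (CircuitVariant.ANTITHETIC, CircuitVariant.BIOSENSOR_CLAMPED):
        u = sigma_production(p)
        annihilation = p.gamma * y[S.SIG] * y[S.A]
        rem_A = 0.0 if ideal_controller else (p.d_A + mu) * y[S.A]
        rem_S = 0.0 if ideal_controller else (p.d_S + mu) * y[S.SIG]
        dy[S.A] = p.k_A * p.C_Ns * a_pqdoI - annihilation - rem_A
        dy[S.SIG] = u - annihilation - rem_S
        controlled = p.k_c * p.C_Nh * sigma_activation(y[S.SIG], p)
    elif variant is CircuitVariant.DIRECT:
        dy[S.CI] = p.k_cI * p.C_Ns * a_pqdoI - (p.d_E + mu) * y[S.CI]
        controlled = p.k_c * p.C_Nh / (1.0 + (y[S.CI] / p.K_cI) ** p.n_cI)
    elif variant is CircuitVariant.OPEN_LOOP:
        controlled = p.k_const * p.C_Nh

    dy[S.CHS] = p.k_b * p.C_Nh + controlled - (p.d_CHS + mu) * y[S.CHS]

    # culture titer: net per-cell production times cell density
    dy[S.T] = max(v_chs - v_f3h, 0.0) * p.rho_cells * od * p.MW_nar / p.N_A
    return dy
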