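"""Parameters, state layout and unit conversions for the regulated naringenin circuit.

All dynamic species are tracked as molecules per cell, time is in hours, and
culture-level quantities (biomass, titer) carry their own units (OD, g/L).
Per-cell counts are a bookkeeping abstraction for the cell's share of the
culture-level pool; they are converted to g/L only at the reporting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum, IntEnum


class CircuitVariant(str, Enum):
    """The four circuit architectures that share one pathway model."""

    ANTITHETIC = "antithetic"
    DIRECT = "direct"
    OPEN_LOOP = "open_loop"
    BIOSENSOR_CLAMPED = "biosensor_clamped"


class S(IntEnum):
    """State-vector index map."""

    N = 0       # naringenin (molecules/cell)
    DHK = 1     # dihydrokaempferol (molecules/cell)
    K = 2       # kaempferol (molecules/cell)
    A = 3       # anti-sigma factor (molecules/cell)
    SIG = 4     # sigma factor (molecules/cell)
    CHS = 5     # naringenin chalcone synthase (molecules/cell)
    F3H = 6     # flavanone 3-hydroxylase (molecules/cell)
    FLS = 7     # flavonol synthase (molecules/cell)
    QDOR = 8    # QdoR repressor, total (molecules/cell)
    LUXR = 9    # LuxR activator (molecules/cell)
    CI = 10     # cI repressor, direct-controller variant (molecules/cell)
    OD = 11     # biomass (OD units)
    T = 12      # cumulative culture naringenin titer (g/L)


N_STATES = len(S)

STATE_NAMES = [s.name for s in S]


@dataclass
class CircuitParams:
    """Kinetic, expression, binding, copy-number and host constants.

    Defaults are the package's nominal operating point; the calibration module
    pins ``Km_M``, ``g_bio``, ``k_const``, ``AHL`` and ``K_cI`` to the nominal
    production anchors (1 g/L titer at 36 h, 5 ug/L kaempferol at 1 g/L
    naringenin).
    """

    # --- naringenin pathway (CHS step) ---
    kcat_CHS: float = 200.0          # 1/h
    Km_cou: float = 6020.0           # molecules/cell (~10 uM at 1 fL)
    Cou_ss: float = 6020.0           # quasi-steady p-coumaroyl pool (molecules/cell)
    M0: float = 20.0                 # nominal malonyl-CoA (uM; 4-40 uM range midpoint)
    Km_M: float = 20.0               # uM, calibrated (default = M0)
    supply_knee: float | None = 6.16526e7  # upstream supply capacity knee (molecules/cell/h)
    supply_cap_ratio: float = 1.4    # max flux as multiple of the knee

    # --- biosensor metabolic branch (F3H, FLS) ---
    kcat_F3H: float = 3600.0         # 1/h native
    Km_F3H: float = 60200.0          # molecules/cell (~100 uM)
    alpha_aff: float = 1.0e6         # affinity detuning factor (>= 1)
    alpha_cat: float = 60.0          # catalytic detuning factor (>= 1)
    kcat_FLS: float = 3600.0         # 1/h
    Km_FLS: float = 60200.0          # molecules/cell
    g_bio: float = 0.8198989579195254               # biosensor-enzyme expression scale, calibrated

    # --- constitutive expression (F3H, FLS, QdoR; LuxR genomic, same rate) ---
    k_E: float = 10.0                # molecules/(copy h)
    d_E: float = 0.3                 # 1/h

    # --- CHS expression ---
    k_b: float = 5.17e4               # basal, molecules/(copy h)
    k_c: float = 1.92e5               # controlled, molecules/(copy h)
    d_CHS: float = 1.0               # 1/h (tagged for active degradation)

    # --- kaempferol sensing (QdoR sequestration, PqdoI repression) ---
    K_dK: float = 300.0              # molecules/cell
    n_K: float = 2.0
    K_dQ: float = 30.0               # molecules/cell
    n_Q: float = 2.0
    beta_leak: float = 0.005          # PqdoI leakiness in [0, 1)

    # --- antithetic controller ---
    k_A: float = 10.0                # anti-sigma, molecules/(copy h)
    k_S: float = 400.0               # sigma, molecules/h (genomic cassette)
    K_AHL: float = 1.0e-7            # M
    n_AHL: float = 2.0
    AHL: float = 6.359136841648794e-08            # external inducer (M); calibrated set-point knob
    K_LuxR: float = 25.0            # LuxR occupancy constant (molecules/cell)
    gamma: float = 1.0              # annihilation rate, 1/(molecules h)
    d_A: float = 0.3                # 1/h
    d_S: float = 0.3                # 1/h
    K_sigma: float = 60.0           # molecules/cell
    n_sigma: float = 1.0

    # --- direct controller (cI) ---
    k_cI: float = 10.0               # molecules/(copy h)
    K_cI: float = 115.1692132584632              # molecules/cell, calibrated
    n_cI: float = 4.0

    # --- open loop ---
    k_const: float = 72884.30976179529           # molecules/(copy h), calibrated

    # --- plasmid copy numbers ---
    C_Ns: int = 10                   # biosensor plasmid
    C_Nh: int = 10                   # actuator plasmid

    # --- host / reporting ---
    mu_max: float = 0.2              # 1/h
    OD_max: float = 3.0              # carrying capacity
    OD0: float = 0.05                # inoculum
    rho_cells: float = 8.0e11        # cells/(L OD)
    MW_nar: float = 272.25           # g/mol
    MW_kae: float = 286.24           # g/mol
    N_A: float = 6.02214076e23       # 1/mol

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [f.name for f in fields(self)
                    if f.name not in ("beta_leak", "supply_knee", "AHL")]
        for name in positive:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value}")
        if not 0 <= self.beta_leak < 1:
            raise ValueError(f"beta_leak must lie in [0, 1), got {self.beta_leak}")
        if self.AHL < 0:
            raise ValueError("AHL must be non-negative")
        if self.supply_knee is not None and not self.supply_knee > 0:
            raise ValueError("supply_knee must be positive or None")
        if self.supply_cap_ratio <= 1:
            raise ValueError("supply_cap_ratio must exceed 1")
        if self.alpha_aff < 1 or self.alpha_cat < 1:
            raise ValueError("detuning factors alpha_aff/alpha_cat must be >= 1")
        for name in ("C_Ns", "C_Nh"):
            cn = getattr(self, name)
            if int(cn) != cn or cn < 1:
                raise ValueError(f"{name} must be a positive integer, got {cn}")
        if not 0 < self.OD0 < self.OD_max:
            raise ValueError("OD0 must lie in (0, OD_max)")

    # -- convenience ----------------------------------------------------

    def copy(self, **changes) -> "CircuitParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


def nominal_params() -> CircuitParams:
    """The shipped nominal parameter set (calibrated fields at their pinned values)."""
    return CircuitParams()


# ---------------------------------------------------------------------------
# Culture-frame conversions
# ---------------------------------------------------------------------------

def od_integral(params: CircuitParams, horizon: float = 36.0) -> float:
    """Analytic integral of logistic biomass OD(t) over [0, horizon] (OD*h)."""
    r, K, x0 = params.mu_max, params.OD_max, params.OD0
    return (K / r) * math.log(1.0 + x0 * (math.exp(r * horizon) - 1.0) / K)


def char_density(params: CircuitParams, horizon: float = 36.0) -> tuple[float, float]:
    """Reference (OD_ref, mu_ref) for frozen-growth characterization.

    OD_ref is chosen so that a constant per-cell flux yields the same culture
    concentration whether accumulated over the batch (flux * int OD dt) or read
    at the frozen steady state (flux/mu_ref * OD_ref), i.e.
    OD_ref = mu(OD_ref) * int_0^H OD dt.
    """
    I = od_integral(params, horizon)
    od_ref = params.mu_max * I / (1.0 + params.mu_max * I / params.OD_max)
    mu_ref = params.mu_max * (1.0 - od_ref / params.OD_max)
    return od_ref, mu_ref


def molecules_to_gl(x: float, mw: float, od: float, params: CircuitParams) -> float:
    """Per-cell molecule count -> culture concentration in g/L at density ``od``."""
    return x * mw * params.rho_cells * od / params.N_A


def gl_to_molecules(c: float, mw: float, od: float, params: CircuitParams) -> float:
    """Culture g/L -> per-cell molecule count at density ``od``."""
    return c * params.N_A / (mw * params.rho_cells * od)
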