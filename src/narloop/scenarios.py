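"""Perturbation-scenario and trajectory containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import S, STATE_NAMES, CircuitParams, CircuitVariant, molecules_to_gl


@dataclass
class Scenario:
    """One simulation experiment.

    A step decrease of fraction ``p`` in malonyl-CoA availability is applied at
    ``t_on`` hours; the batch runs to ``horizon`` hours.  ``clamp_N`` pins the
    naringenin input (required for the BIOSENSOR_CLAMPED variant).  When
    ``fixed_OD`` is set, biomass is frozen at that density (characterization
    runs) instead of growing logistically.
    """

    variant: CircuitVariant = CircuitVariant.ANTITHETIC
    p: float = 0.0
    t_on: float = 1.0
    horizon: float = 36.0
    seed: int = 0
    clamp_N: float | None = None
    fixed_OD: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.variant, str):
            self.variant = CircuitVariant(self.variant)
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"perturbation fraction p must lie in [0, 1), got {self.p}")
        if not 0.0 < self.t_on < self.horizon:
            raise ValueError("t_on must lie in (0, horizon)")
        if self.variant is CircuitVariant.BIOSENSOR_CLAMPED and self.clamp_N is None:
            raise ValueError("BIOSENSOR_CLAMPED requires clamp_N")

    def m_frac(self, t: float) -> float:
        """Malonyl-CoA availability as a fraction of nominal at time ``t``."""
        return 1.0 if t < self.t_on else 1.0 - self.p


@dataclass
class Trajectory:
    """Time-resolved state plus derived observables of one run."""

    t: np.ndarray                    # h
    y: np.ndarray                    # (n_states, n_t), clipped to >= 0
    scenario: Scenario
    params: CircuitParams

    def series(self, name: str) -> np.ndarray:
        return self.y[S[name]]

    @property
    def titer(self) -> np.ndarray:
        """Cumulative culture naringenin titer (g/L)."""
        return self.y[S.T]

    @property
    def od(self) -> np.ndarray:
        return self.y[S.OD]

    @property
    def final_titer(self) -> float:
        return float(self.y[S.T, -1])

    def naringenin_gl(self) -> np.ndarray:
        """Instantaneous per-cell naringenin expressed as culture g/L."""
        return molecules_to_gl(self.y[S.N], self.params.MW_nar, 1.0, self.params) * self.y[S.OD]

    def kaempferol_gl(self) -> np.ndarray:
        return molecules_to_gl(self.y[S.K], self.params.MW_kae, 1.0, self.params) * self.y[S.OD]

    def to_frame(self):
        import pandas as pd

        data = {"time_h": self.t}
        for name in STATE_NAMES:
            data[name] = self.y[S[name]]
        data["titer_gL"] = self.titer
        data["naringenin_gL"] = self.naringenin_gl()
        data["kaempferol_gL"] = self.kaempferol_gl()
        return pd.DataFrame(data)
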