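"""Parameter-robustness scans of the two controllers.

Reproduces the study's sensitivity campaign: vary controller gains, binding
constants and plasmid copy numbers over one to two orders of magnitude around
the calibrated nominal point, simulate the unperturbed 36 h batch for every
combination, and classify the final titer into production bands
(nominal 1 +/- 0.05 g/L, intermediate 0.4-0.9 g/L, low < 0.4 g/L).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import CircuitParams, CircuitVariant
from .scenarios import Scenario
from .simulate import SolverError, run_scenario

log = logging.getLogger(__name__)

BANDS = ("NOMINAL", "MID", "LOW", "OTHER", "FAILED")


@dataclass
class GridConfig:
    """Declarative description of a robustness grid.

    ``spans`` maps parameter names to (lo_factor, hi_factor, n_points);
    factors multiply the nominal value and are log-spaced.  ``copy_sets``
    lists the candidate plasmid copy numbers.  ``subsample`` (with ``seed``)
    deterministically thins the full Cartesian product to a target count.
    """

    spans: dict[str, tuple[float, float, int]]
    copy_sets: dict[str, tuple[int, ...]] = field(default_factory=lambda: {
        "C_Ns": (1, 5, 10, 20), "C_Nh": (1, 5, 10, 20)})
    subsample: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi, n) in self.spans.items():
            if n < 1 or lo <= 0 or hi < lo:
                raise ValueError(f"invalid span for {name}: {(lo, hi, n)}")
        for name, values in self.copy_sets.items():
            if len(values) == 0:
                raise ValueError(f"empty copy-number set for {name}")


def default_grid_config(variant: CircuitVariant, subsample: int | None = None,
                        seed: int = 0) -> GridConfig:
    """The package's default scan: controller gains, the PqdoI repression
    constant and both copy numbers over x0.1-x10."""
    if variant is CircuitVariant.ANTITHETIC:
        spans = {name: (0.1, 10.0, 3) for name in ("k_A", "k_S", "gamma", "k_c", "K_dQ")}
        if subsample is None:
            subsample = 2500
    elif variant is CircuitVariant.DIRECT:
        spans = {"k_cI": (0.1, 10.0, 4), "K_cI": (0.1, 10.0, 4),
                 "k_c": (0.1, 10.0, 3), "K_dQ": (0.1, 10.0, 3)}
    else:
        raise ValueError(f"no default robustness grid for variant {variant}")
    return GridConfig(spans=spans, subsample=subsample, seed=seed)


@dataclass
class ParameterGrid:
    """Deterministic enumeration of parameter-factor combinations."""

    names: list[str]
    combos: list[dict]
    config: GridConfig

    @property
    def size(self) -> int:
        return len(self.combos)


def generate_grid(config: GridConfig) -> ParameterGrid:
    axes: dict[str, np.ndarray] = {}
    for name in sorted(config.spans):
        lo, hi, n = config.spans[name]
        axes[name] = np.logspace(np.log10(lo), np.log10(hi), n) if n > 1 \
            else np.array([lo])
    copy_names = sorted(config.copy_sets)
    values = [axes[n] for n in sorted(axes)] + [config.copy_sets[n] for n in copy_names]
    names = sorted(axes) + copy_names
    combos = [dict(zip(names, combo)) for combo in itertools.product(*values)]
    if config.subsample is not None and config.subsample < len(combos):
        rng = np.random.default_rng(config.seed)
        idx = np.sort(rng.choice(len(combos), size=config.subsample, replace=False))
        combos = [combos[i] for i in idx]
    log.info("generated grid with %d combinations over %s", len(combos), names)
    return ParameterGrid(names=names, combos=combos, config=config)


def classify_band(titer: float) -> str:
    """Production band of a final titer (g/L).

    The study's bands leave gaps (0.9-0.95 and > 1.05 g/L); anything in a gap
    is labelled OTHER.
    """
    if titer < 0:
        raise ValueError(f"titer must be non-negative, got {titer}")
    if abs(titer - 1.0) <= 0.05 + 1e-12:  # inclusive band edge
        return "NOMINAL"
    if 0.4 <= titer <= 0.9:
        return "MID"
    if titer < 0.4:
        return "LOW"
    return "OTHER"


def apply_combo(params: CircuitParams, combo: dict) -> CircuitParams:
    changes = {}
    for name, value in combo.items():
        if name in ("C_Ns", "C_Nh"):
            changes[name] = int(value)
        else:
            changes[name] = getattr(params, name) * value
    return params.copy(**changes)


def scan(grid: ParameterGrid, variant: CircuitVariant, params: CircuitParams,
         horizon: float = 36.0, rtol: float = 1e-7, atol: float = 1e-8,
         progress: bool = False) -> tuple[pd.DataFrame, dict]:
    """Unperturbed 36 h titer and band for every grid combination.

    Returns the per-combination records and a summary with band counts, the
    fraction of (non-failed) combinations at or above 0.4 g/L, and the number
    of solver failures (always reported, excluded from fractions).
    """
    scenario = Scenario(variant=variant, p=0.0, horizon=horizon)
    rows = []
    for i, combo in enumerate(grid.combos):
        p_i = apply_combo(params, combo)
        row = {"combo_id": i, "variant": variant.value, **combo}
        try:
            traj = run_scenario(scenario, p_i, rtol=rtol, atol=atol, dt_out=0.5)
            row["titer_gL"] = traj.final_titer
            row["band"] = classify_band(traj.final_titer)
        except (SolverError, ValueError) as err:
            log.warning("combination %d failed: %s", i, err)
            row["titer_gL"] = np.nan
            row["band"] = "FAILED"
        rows.append(row)
        if progress and (i + 1) % 250 == 0:
            log.info("scan progress: %d/%d", i + 1, grid.size)
    records = pd.DataFrame(rows)
    summary = summarize(records)
    return records, summary


def summarize(records: pd.DataFrame) -> dict:
    counts = {band: int((records["band"] == band).sum()) for band in BANDS}
    ok = records[records["band"] != "FAILED"]
    n_ok = len(ok)
    frac_ge = float((ok["titer_gL"] >= 0.4).sum() / n_ok) if n_ok else float("nan")
    return {
        "n_total": int(len(records)),
        "n_failed": counts["FAILED"],
        "band_counts": counts,
        "band_fractions": {b: (counts[b] / n_ok if n_ok else float("nan"))
                           for b in BANDS if b != "FAILED"},
        "fraction_ge_0.4": frac_ge,
    }


def copy_number_marginals(records: pd.DataFrame, band: str = "NOMINAL") -> dict:
    """Counts of band members per plasmid copy-number value, sorted descending.

    Also reports each axis's cumulative share covered by its top values.
    """
    out = {}
    sel = records[records["band"] == band]
    total = len(sel)
    for axis in ("C_Ns", "C_Nh"):
        if axis not in records.columns:
            continue
        counts = sel.groupby(axis).size().sort_values(ascending=False)
        marg = {int(k): int(v) for k, v in counts.items()}
        cum = {}
        run = 0
        for k, v in marg.items():
            run += v
            cum[k] = run / total if total else float("nan")
        out[axis] = {"counts": marg, "cumulative_share": cum, "total": total}
    return out


def best_case_search(p: float, grid: ParameterGrid, params: CircuitParams,
                     rtol: float = 1e-7, atol: float = 1e-8) -> dict:
    """Maximum retained production under a perturbation, over the grid.

    For each combination the unperturbed and perturbed 36 h titers are
    simulated with that combination's own parameters; the retained fraction is
    their ratio.  Returns the best combination and the full table.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("perturbation fraction p must lie in (0, 1)")
    rows = []
    for i, combo in enumerate(grid.combos):
        p_i = apply_combo(params, combo)
        try:
            nom = run_scenario(Scenario(variant=CircuitVariant.ANTITHETIC, p=0.0),
                               p_i, rtol=rtol, atol=atol, dt_out=0.5)
            pert = run_scenario(Scenario(variant=CircuitVariant.ANTITHETIC, p=p),
                                p_i, rtol=rtol, atol=atol, dt_out=0.5)
        except (SolverError, ValueError) as err:
            log.warning("best-case combination %d failed: %s", i, err)
            continue
        if nom.final_titer <= 0:
            continue
        rows.append({"combo_id": i, **combo,
                     "nominal_gL": nom.final_titer,
                     "perturbed_gL": pert.final_titer,
                     "retained_pct": 100.0 * pert.final_titer / nom.final_titer})
    table = pd.DataFrame(rows)
    if table.empty:
        raise SolverError("every combination in the best-case search failed")
    best = table.loc[table["retained_pct"].idxmax()]
    return {"retained_pct": float(best["retained_pct"]),
            "best_combo": {k: best[k] for k in grid.names},
            "table": table}
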