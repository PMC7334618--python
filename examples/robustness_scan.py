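"""Scan controller parameters over orders of magnitude and classify production.

Builds reduced default grids (controller gains, binding constants and plasmid
copy numbers, x0.1-x10), simulates the unperturbed 36 h batch per combination
for both controllers, classifies final titers into the production bands
(nominal 1 +/- 0.05, intermediate 0.4-0.9, low < 0.4 g/L), and searches for
the best-tuned antithetic variant under a 60% malonyl-CoA step.

A reduced subsample keeps this demonstration quick; drop `subsample` for the
full default grids.
"""

from narloop import CircuitVariant, nominal_params
from narloop.robustness import (GridConfig, best_case_search, copy_number_marginals,
                                default_grid_config, generate_grid, scan)

params = nominal_params()

for variant in (CircuitVariant.ANTITHETIC, CircuitVariant.DIRECT):
    cfg = default_grid_config(variant, subsample=300, seed=1)
    records, summary = scan(generate_grid(cfg), variant, params)
    print(f"{variant.value}: {summary['n_total']} combinations, bands "
          f"{summary['band_counts']}, {100 * summary['fraction_ge_0.4']:.1f}% "
          f">= 0.4 g/L")
    if variant is CircuitVariant.ANTITHETIC:
        marg = copy_number_marginals(records)
        print(f"  nominal-band solutions per copy number: C_Ns "
              f"{marg['C_Ns']['counts']}, C_Nh {marg['C_Nh']['counts']}")

cfg = GridConfig(spans={n: (0.1, 10.0, 3) for n in ("k_A", "k_S", "gamma", "k_c")},
                 subsample=100, seed=1)
best = best_case_search(0.6, generate_grid(cfg), params)
print(f"best-tuned antithetic retains {best['retained_pct']:.1f}% of nominal "
      f"production under a 60% malonyl-CoA decrease")
print("(tuned variants saturate the upstream supply, making production nearly "
      "insensitive to the perturbation)")
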