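# narloop

In-silico analysis of dynamic pathway regulation in a naringenin-producing
*E. coli* cell factory: an **extended metabolic biosensor** (naringenin →
kaempferol → QdoR → anti-σ) wired into an **antithetic σ/anti-σ integral
feedback controller** that actuates expression of naringenin chalcone
synthase (CHS), compared against a direct cI-repressor controller and an
open-loop constitutive design.

The package is for systems/synthetic-biology modelers who want to reproduce
and probe this control architecture: it provides the full ODE circuit model,
anchor-based calibration, steady-state dose-response characterization,
malonyl-CoA step-perturbation experiments, and order-of-magnitude parameter
robustness scans.

## Model in brief

Per-cell species **x** (molecules/cell) in a logistically growing batch
(OD(t), μ = μ_max(1 − OD/OD_max)) over 36 h:

- pathway: v_CHS = k_cat·CHS·[Cou/(K_cou+Cou)]·[mM₀/(K_M+mM₀)], where the
  malonyl-CoA availability m steps from 1 to 1−p at t = 1 h; an upstream
  supply cap saturates flux above the nominal operating point,
- biosensor: deliberately detuned F3H (affinity ÷10⁶, k_cat ÷60) and FLS
  convert a trace of naringenin to kaempferol, which sequesters QdoR
  (Hill n=2), de-repressing anti-σ expression from PqdoI,
- controller: dA/dt = k_A·C_Ns·a(Q_free) − γSA − (d_A+μ)A,
  dS/dt = u − γSA − (d_S+μ)S, with u set externally by AHL; free σ activates
  CHS from the P20 promoter. With d_A = d_S = μ = 0 the annihilation forces
  the sensed anti-σ production onto the set-point u exactly (integral
  action); the shipped nominal uses a leaky integrator,
- titer: dT/dt = (v_CHS − v_F3H)·ρ_cells·OD·MW/N_A, in g/L.

All constants live in `CircuitParams`; calibration pins K_M (closed form from
the 40%-perturbation anchor), the biosensor gain (5 μg/L kaempferol at 1 g/L
naringenin), the open-loop promoter (1 g/L at 36 h) and both controller
set-points (same 1 g/L nominal). See `docs/methods.md` for the full model,
units and design rationale.

## Worked example

```python
from narloop import (CircuitVariant, Scenario, compare_variants,
                     nominal_params, run_scenario, settling_time)

params = nominal_params()              # shipped, pre-calibrated operating point
print(compare_variants([0.4, 0.6], params).to_string(index=False))
```

prints

```
   variant   p  final_titer_gL  drop_pct
antithetic 0.4        0.885315 11.468421
antithetic 0.6        0.765446 23.455344
    direct 0.4        0.891587 10.840847
    direct 0.6        0.793800 20.620210
 open_loop 0.4        0.750111 24.988874
 open_loop 0.6        0.571618 42.838066
```

i.e. a 40% malonyl-CoA decrease costs the unregulated strain ~25% of its
1 g/L batch titer (a 60% decrease ~43%, following the Michaelis–Menten
saturation algebra), while the antithetic closed loop holds the loss to
~11% and ~23% respectively. The closed-loop recovery settles about 29 h
after the step (5% band on the perturbed/nominal naringenin ratio):

```python
nom  = run_scenario(Scenario(variant=CircuitVariant.ANTITHETIC, p=0.0), params)
pert = run_scenario(Scenario(variant=CircuitVariant.ANTITHETIC, p=0.4), params)
print(settling_time(pert, band=0.05, reference=nom))   # -> 29.1 (hours)
```

The `examples/` directory holds one short narrative script per capability
(calibration anchors, dose-response curves, perturbation rejection,
robustness scan); each prints the numbers it computes and what they mean.
A thin CLI mirrors the same stages
(`narloop calibrate|dose-response|perturb|robustness|fixtures|report`), each
reading one YAML config (see `src/narloop/data/default_config.yaml`) and
writing CSV/JSON outputs plus a reproducibility manifest.

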