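# Methods

## Scope and state

`narloop` models a naringenin-producing *E. coli* strain whose CHS expression
is dynamically regulated by an antithetic σ/anti-σ integral controller fed by
an extended metabolic biosensor, and the two comparison architectures (direct
cI repression; open loop). The deterministic ODE state has 13 components:
per-cell metabolites (naringenin N, dihydrokaempferol DHK, kaempferol K),
controller species (anti-σ A, σ S), proteins (CHS, F3H, FLS, QdoR, LuxR, cI),
biomass OD and cumulative culture titer T (g/L).

Per-cell counts are a bookkeeping abstraction for the cell's share of the
culture-level pool (naringenin is freely exchanged with the medium); they are
converted to g/L only at the reporting boundary via
`x · MW · ρ_cells · OD / N_A`. Time is in hours.

## Rate laws

**Pathway.** CHS flux is bi-substrate Michaelis–Menten,
`v_CHS = kcat_CHS · CHS · Cou/(Km_cou+Cou) · mM0/(Km_M+mM0)`, with
p-coumaroyl held at a quasi-steady pool (the upstream TAL/4CL steps are
lumped) and the CHI step treated as fast. The malonyl-CoA availability
`m(t)` steps from 1 to 1−p at t_on = 1 h — the study's model of bioreactor
environmental fluctuation. Flux above the nominal operating point saturates
smoothly toward `supply_cap_ratio × supply_knee` (finite upstream
replenishment); the cap is exactly inert at and below the calibrated nominal
flux, so all sub-nominal behavior is cap-free.

**Biosensor.** F3H is detuned by `alpha_aff = 1e6` (affinity) and
`alpha_cat = 60` (turnover), so `v_F3H = (kcat/α_cat)·F3H·N/(α_aff·Km + N)`
is linear in N over the whole g/L range; FLS is native. Kaempferol's only
sink is growth dilution. Kaempferol sequesters QdoR at fast equilibrium
(`Q_free = Q_tot/(1+(K/K_dK)^2)`, dimeric TF) and free QdoR represses PqdoI
(`a = β + (1−β)/(1+(Q_free/K_dQ)^2)`), which drives anti-σ (and, in the
direct variant, cI).

**Controller.** σ is produced at a constant rate `u` set by the external AHL
inducer through LuxR; σ and anti-σ annihilate bilinearly (rate γ); free σ
activates CHS expression from P20. With no removal of the pair other than
annihilation, subtracting the two balances shows the sensed anti-σ production
is pinned to `u` — the antithetic integral motif. The shipped controller is
deliberately leaky (`d_A = d_S = 0.3/h`, degradation-tagged species): a
quasi-integral controller whose finite DC gain and slow kaempferol reporter
reproduce the partial, 20–30 h rejection observed for this circuit rather
than textbook perfect adaptation.

**Host.** Logistic growth, `μ = μ_max(1−OD/OD_max)`, `μ_max = 0.2/h`,
`OD_max = 3`, inoculum 0.05. The batch therefore spans the full growth curve
within the 36 h horizon, and dilution — the only sink for kaempferol and
(effectively) naringenin — decays over the run. This slow-growth default is
deliberate: with a fast-growth default the culture reaches stationary phase
by ~12 h, dilution vanishes, and the biosensor chain has no quasi-steady
operating regime for the remaining two thirds of the experiment.

## Architectural choices

- **Induction cassette is genomic.** LuxR and the σ gene are expressed from a
  single-copy genomic cassette, so the set-point `u = k_S·hill(AHL)·f_LuxR`
  is independent of both plasmid copy numbers. Placing it on either plasmid
  couples the set-point to that plasmid's copy number and starves the
  controller over large parts of the copy-number grid, contradicting the
  observation that single-copy biosensor plasmids are among the best
  performers. Anti-σ, QdoR and the biosensor enzymes ride the sensor plasmid
  (C_Ns); CHS (basal + controlled) rides the actuator plasmid (C_Nh).
- **Cooperativities.** QdoR sequestration and PqdoI repression are dimeric
  (n = 2). σ-P20 activation is non-cooperative (n_σ = 1; a single σ–RNAP
  recruitment event), so the antithetic actuator degrades gracefully when σ
  supply shifts. cI repression is strongly cooperative (n_cI = 4,
  λ-repressor-like), so over-expressed cI strangles the direct controller
  sharply. These shapes also set the two controllers' contrasting failure
  modes in the robustness scan.
- **Basal CHS share.** The P20/constitutive promoters carry a substantial
  basal term (~40% of nominal flux at the operating point), leaving the
  controlled term a ~2.5× dynamic range upward — enough to compensate a 60%
  malonyl-CoA decrease (which requires a 1.75× flux boost).

## Calibration (deterministic, bracketing bisection on a log scale)

1. `Km_M = (1−p)·d·M0/(p−d)` in closed form from the anchor "a 40% malonyl-CoA
   decrease costs ~25% of production"; with d = 0.25, p = 0.4 this gives
   `Km_M = M0` (nominal M0 = 20 μM, midpoint of the physiological 4–40 μM
   range). The 60% response is **not** used anywhere in calibration and is a
   genuine prediction (flux algebra gives 42.9%; the batch integral reports
   42.8%).
2. Biosensor gain `g_bio` (expression scale of F3H/FLS): steady-state
   kaempferol equals 5 μg/L while sensing 1 g/L clamped naringenin.
3. Open-loop promoter `k_const`: unperturbed 36 h titer of 1 g/L; the supply
   knee is then set at the nominal peak flux.
4. Set-points: AHL (antithetic) and K_cI (direct) such that both closed
   loops reach the same 1 g/L nominal — all three architectures share one
   operating point.

Calibration is idempotent (<0.1% movement on re-run) and order-insensitive
(gain/open-loop within 1%). The shipped `CircuitParams` defaults *are* the
calibrated snapshot.

## Characterization frame

Dose-response curves and algebraic steady states are computed with growth
frozen at a reference density OD_ref with dilution
`μ_ref = μ_max(1−OD_ref/OD_max) > 0` (kaempferol has no steady state at
μ = 0). OD_ref is chosen so that `OD_ref = μ_ref · ∫₀³⁶ OD dt`, which makes a
constant per-cell flux map to the same culture g/L in the frozen frame as in
the batch: clamped-curve anchors and batch titer anchors are therefore
commensurate, and the open-loop production line intersects the nominal
production curve at 1 g/L by construction. Long-time integration (500 h,
frozen growth) agrees with the root-solved steady states to 1e-6 relative;
the curve-intersection equilibrium finder agrees with the full ODE steady
state to 2% across random ±15% parameter draws.

## Synthetic scenarios

- **Perturbations:** step decreases of 20/40/60% at t_on = 1 h, horizon 36 h.
- **Uncertainty ensembles:** every biosensor-chain constant (kinetics,
  expression, binding, leak) multiplied by an independent uniform factor in
  [1−u, 1+u], default u = 0.15, copy numbers pinned at 10 for
  characterization ensembles; log-normal factors available. Deterministic
  given the seed (`numpy.random.default_rng`).
- **Robustness grids:** log-spaced factors ×0.1–×10 (3–4 points per axis)
  on {k_A, k_S, γ, k_c, K_dQ} (antithetic; 3888 raw combinations,
  deterministically subsampled to 2500) and {k_cI, K_cI, k_c, K_dQ}
  (direct; 2304), each crossed with C_Ns, C_Nh ∈ {1, 5, 10, 20}. Bands:
  nominal |T−1| ≤ 0.05, intermediate 0.4–0.9, low < 0.4 g/L, OTHER for the
  gaps (0.9–0.95 and >1.05); solver failures are reported and excluded from
  fractions.
- **Best-case search:** the same controller-gain spans (400 subsampled
  combinations), each simulated unperturbed and under the 60% step with its
  own parameters; reports the maximum retained fraction.

## Numerical choices

LSODA with rtol 1e-8, atol 1e-10 and 0.05 h output resolution for single
trajectories; the step perturbation is integrated as two smooth legs. Scans
use rtol 1e-7, atol 1e-8 and 0.5 h output (halving tolerances moves reported
drops by ≪0.1 pp). Negative solver excursions are clipped at the RHS inputs
and on output. Settling time supports two modes: within-band of the final
value on the raw per-cell naringenin trace (meaningful for stationary
characterization runs), or on the perturbed/nominal ratio when a reference
trajectory is supplied — the batch's shared growth-phase drift cancels in
the ratio, which is the mode used for the recovery-time results.

## Problem sizes used in the shipped analyses

Acceptance-scale runs use the full default grids (2500 + 2304 + 400
combinations, ~5 min single-CPU); the test suite uses 800-point subsamples
of the same grids and 150-point best-case grids (~2 min). Monte-Carlo
ensembles default to 200 samples for curves and 30–50 for titer error bars.

## Known limitations

- Deterministic ODEs only; no stochastic kinetics, no resource/burden
  coupling, no plasmid-loss or bioreactor hydrodynamics.
- The sensed variable is a metabolite proxy whose only sink is dilution, so
  late in the batch (μ → 0) kaempferol integrates rather than tracks; the
  controller's authority fades in deep stationary phase, and per-cell traces
  drift with 1/μ. Results are therefore reported on the 36 h batch integral.
- Integral pinning regulates the *proxy* (kaempferol); production remains
  proportional to the pinned proxy level, so set-point-scale parameter
  changes (k_S, k_A, K_dQ over ×0.1–×10) shift the regulated titer roughly
  decade-for-decade through the sensor's inverse characteristic. On the
  symmetric default grids this keeps the antithetic fraction producing
  ≥0.4 g/L near two thirds rather than above 80%, and the basal floor plus
  the supply cap prop the direct controller's fraction to a similar value:
  the two controllers' headline fraction ordering is a statistical tie here,
  unlike the clear separation reported for the original (unrecoverable)
  grid ranges. The mechanistic asymmetry is still visible in the band
  composition: the direct controller fails by hard cI strangling while the
  antithetic degrades gracefully, and tuned antithetic variants fully reject
  a 60% perturbation (≥96% retained) while the nominal direct controller
  cannot.
- Tuned best-case variants can retain slightly above 100% of nominal: the
  leaky integrator overcompensates and the supply cap makes overdriven
  operating points perturbation-insensitive.
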