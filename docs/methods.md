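# Methods

## The reaction network

The model tracks 28 species in one well-mixed mitochondrion, coupled by 30
reactions (`mitoh2o2.model_core`). Concentrations are μM
(monomer-equivalents for all protein forms), time is seconds. The reactions,
in the package's canonical order:

| id | reaction | rate law |
|----|----------|----------|
| R1 | ∅ → H2O2 (OxPhos) | k1 |
| R2–R4 | Gpx1 cycle (oxidation by H2O2, glutathionylation, reduction by GSH) | k2[Gpx1red][H2O2]; k3[Gpx1ox][GSH]; k4[Gpx1-SSG][GSH] |
| R5 | NADP⁺ → NADPH | k20[NADP⁺]/(k5+[NADP⁺]) |
| R6–R10 | Prx3 cycle incl. hyperoxidation and Srx repair | k6[Prx3-SH][H2O2]; k7[Prx3-SOH][H2O2]; k8[Prx3-SOOH][Srx]; k9[Prx3-SOH]; k10[Prx3-SS][Trx2-SH] |
| R11 | GSH autoxidation (½ GSSG per GSH) | k11[GSH] |
| R12–R17 | generic protein thiol/dithiol oxidation and recycling | mass action |
| R18–R19 | GSSG and Trx2-SS reduction by NADPH | mass action |
| R20 | Gpx4-SSG + GSH → Gpx4red + GSSG | k4 (shared with Gpx1; see below) |
| R21–R22 | GSH import/efflux | k21; k22[GSH] |
| R23–R25 | Prx5 cycle | mass action |
| R26–R27 | Gpx4 oxidation/glutathionylation | mass action |
| R28 | ∅ → H2O2 (DAAO perturbation) | kDAAO |
| R29 | ∅ → Srx (import) | k29 |
| R30 | H2O2 efflux | see below |

Decisions taken where the published material left the network
under-determined:

* **Srx is consumed stoichiometrically** in R8 and replenished by the
  zeroth-order import R29. At the derived basal abundances the repair flux
  k8·[Prx3-SOOH]·[Srx] numerically equals k29 (1.23×10⁻⁵ μM/s), which is the
  flux balance that makes this closure self-consistent; a purely catalytic
  Srx would accumulate without bound.
* **R11 stoichiometry** produces ½ GSSG per GSH consumed, conserving
  glutathione atoms under the first-order rate law.
* **Gpx4-SSG reduction (R20)** shares the Gpx1 constant k4; no
  mitochondria-specific value exists and the two glutathionylated
  peroxidases are chemically analogous. Total glutathione
  (GSH + 2·GSSG + protein-SSG) is conserved up to import/efflux; over a 1-h
  baseline run it drifts by ~0.02 % (the tests enforce < 5 %).
* **H2O2 efflux (R30)** has two implemented forms behind
  `RateParameters.efflux_mode`. The default `first_order` uses
  kefflux·[H2O2] with kefflux in s⁻¹: an efflux proportional to the H2O2
  concentration is the only form under which a high-efflux regime can hold
  H2O2 nanomolar *while* sustaining dimer fractions above 0.4, the behavior
  the efflux analysis is meant to exhibit. The alternative `zeroth_order`
  (kefflux in μM/s, throttled linearly below `efflux_eps` = 10⁻³ μM to
  preserve nonnegativity) makes a constant source/sink pair cancel exactly,
  which the paired-cancellation test exercises. No headline quantity
  depends on the switch.

## Numerics

Species span ~10⁻⁸–10³ μM and rate constants ~10⁻⁵–375, so the system is
stiff. Integration uses `scipy.integrate.solve_ivp` (LSODA by default) with
the analytically assembled Jacobian S·(∂v/∂C), rtol 10⁻⁸ and atol 10⁻¹² μM.
The stoichiometry matrix makes the seven protein/cofactor pools (Prx3, Prx5,
Gpx1, Gpx4, Trx2, Grx2, NADP(H)) exact invariants; observed numerical drift
over 3600 s is ~10⁻¹⁵ relative.

**Steady state** is defined over the fast subsystem (H2O2 and the
peroxidase/thioredoxin/glutaredoxin redox forms; sub-second turnover at
baseline). `find_steady_state` integrates 5 s — the baseline reporting
convention, comfortably past the < 1 s settling time — then Newton-refines
the fast species to a fixed point (full steps from the integrated state,
best-iterate fallback; general-purpose root finders mis-scale this system).
For each conserved pool wholly inside the fast set, one rate equation is
replaced by the pool-conservation constraint, otherwise the restricted
Jacobian is singular. Prx3-SOOH is carried in the refined set so the Prx3
pool closes; its refined value is the quasi-equilibrium of hyperoxidation
against Srx repair at the frozen Srx level (0.35 μM at the 62 μM pool,
inside the derived 0.19–0.42 μM basal range). Residuals reach < 10⁻¹² μM/s;
slow open species (GSH, Srx, generic protein thiols) keep their drift rates
and are reported as drifts, not failures. Srx itself has no finite fixed
point (import exceeds basal consumption by ~3×10⁻⁶ μM/s), which is why the
initialization-policy agreement test compares fast species other than
Prx3-SOOH after a 2×10⁵ s relaxation.

**Initialization policies.** Default: the whole Prx3 pool starts reduced and
every derived oxidized species at zero. Alternative (`policy="table"`): the
derived basal oxidized forms start at their range midpoints, carved out of
the same totals so both policies relax to the same steady state.

**time_to_steady** returns the earliest time after which a trace stays
within a relative band (default 1 %) of its terminal value; a trace counts
as settled only if it dwells inside the band for ≥ 3 % of the window,
otherwise an `inf` sentinel is returned (a still-drifting trace trivially
matches its own endpoint).

**Collapse threshold**: bisection (12 iterations on [0, 100] μM/s) on the
indicator "Prx3 hyperoxidized fraction > 0.5 at 3600 s". The indicator and
horizon are configurable; the printed sweep pins the transition between 47
and 54 μM/s and the bisected default lands at 51.4 μM/s.

**Sensitivities**: forward finite differences with a +10 % parameter step
(central differences available for verification), normalized to
(ΔC/C)/(Δk/k), evaluated at the 5-s basal state, ranked by |s̄| descending
with ties broken by parameter index and entries below 10⁻⁵ dropped.
Zero-valued parameters (kDAAO, kefflux at baseline) admit no relative
perturbation and are skipped.

**Monte Carlo**: one root seed; sample *i* draws from
`SeedSequence(seed, spawn_key=(i,))`, so enlarging n extends rather than
reshuffles a sample set. The 10,000-sample basal run uses warm-started
Newton refinement per sample (equivalent to per-sample integration to
rtol 10⁻⁶, verified in the tests; ~25× faster). The efflux Monte Carlo
integrates every sample for the full hour; the bundled analysis driver
defaults to 200 pairs per regime, which pins the median bands well (the
medians move by < 2 % between 200 and 1000 samples), and exposes `--n`.

## Unit bridges

Copies/cell convert to per-mitochondrion μM via equal partitioning over
383–882 mitochondria of 0.29 μm³ — equal partitioning is the implicit
assumption behind using a count *range* to produce a concentration range.
Volumetric rates convert to protein-specific rates through a cellular
protein density of 2×10⁵ mg/L, assumed organelle-invariant (50 μM/s ↔
0.25 nmol/mg-protein/s).

## Synthetic redox-Western generator

The generator emulates the densitometry of a non-reducing redox Western of
Prx3, *not* the blot images: per (D-alanine dose, time, replicate) it
produces monomer, dimer and loading-control band intensities. The dimer
band carries the simulated Prx3-SS share; reduced, sulfenic and
hyperoxidized forms migrate as monomer, so a collapsing pool shows a
*fading* dimer band — the signature that distinguishes hyperoxidation from
simple dose saturation. Noise is multiplicative log-normal per band
(σ = 0.15) under a per-lane log-normal loading factor (σ = 0.20), typical
densitometry variability; three biological replicates per condition is the
experimental design the statistics stage assumes.

The dose → kDAAO map is *synthetic*: no quantitative calibration of
intramitochondrial DAAO flux versus D-alanine exists, so the default is a
Michaelis-type curve (vmax 60 μM/s, Km 10 mM over doses 0–25 mM) placing the
top dose near but below the collapse threshold. Consequences: recovered
fractions rise monotonically with dose and the ANOVA/Tukey stage has ≥ 95 %
power at n = 3 under default noise — but nothing about the real dose scale
should be read off these outputs.

What passing these tests shows: the estimator pipeline (band generation →
loading normalization → fraction → ANOVA/Tukey) is unbiased and adequately
powered *given the model's own trajectories*. What it does not show:
agreement with real blots, which involve transfer/antibody nonlinearities,
saturation, and H2O2 efflux physiology outside the generator.

## Known limitations

* The compartment is homogeneous; no spatial gradients, membrane potential,
  permeability transition or aquaporin transport.
* The legacy zeroth-order-in-Srx repair rate law (khyperox[Prx3-SOH][H2O2] −
  kcat[Prx3-SOOH]) is documented here for completeness but deliberately not
  implemented as an executable mode; the first-order-in-Srx law supersedes
  it.
* Near the collapse threshold, 1-h endpoints are extremely sensitive to the
  hyperoxidation/repair balance: a ~2 μM/s shift in the effective threshold
  moves the 1-h H2O2 at kDAAO = 47 μM/s by tens of percent and decides
  whether a mid-crash dimer transient is still visible at 3600 s. Quantities
  reported near criticality should be read with that sensitivity in mind.
* Gpx oxidized fractions follow k_ox[H2O2]/k_red[GSH] closed forms and are
  therefore only as good as the H2O2 trajectory and the assumed constant
  GSH pool.
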