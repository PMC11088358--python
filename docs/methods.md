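# Methods

## Constitutive model

The model idealizes bone tissue under uniaxial engineering strain as two
parallel layers. The Prandtl layer (spring `E_pr`, frictional slider)
carries the rate-independent elasto-plastic equilibrium response; the
Maxwell layer (spring `E_mx`, dashpot `η`) carries the visco-elastic
overstress that builds during loading (bounded by `η·ε̇`) and relaxes
during holds. Plastic flow starts when the Prandtl stress reaches the flow
stress

σ_flow(κ) = σ_u + (σ_Y − σ_u)·exp(−p·κ),

an exponential hardening law in the accumulated equivalent plastic strain κ
that starts at the yield stress and saturates at the ultimate stress; the
hardening exponent `p` sets how quickly saturation is approached (printed
group means of 39–188 imply saturation over roughly 1–5% plastic strain).
Damage degrades both spring stiffnesses equally through

D(κ) = 1 − exp(−k_D·κ),

the simplest saturating law driven by equivalent plastic strain that keeps
D in [0, 1) and non-decreasing. The dashpot itself is undamaged; since the
Maxwell spring is damaged, the relaxation time becomes `η/((1−D)·E_mx)`.
These two functional forms are this package's modelling choices: the
qualitative roles (exponential hardening; plastic-strain-driven damage
acting on both stiffnesses) are fixed by the framework it implements, the
exact algebra is not published with it.

Total stress: `σ = (1−D)·E_pr·(ε − ε_pl) + σ_mx`, with
`|σ_prandtl| ≤ (1−D)·σ_flow(κ)` enforced at every step.

### Time integration

Per sample: (1) elastic predictor for the Prandtl layer; if it exceeds the
flow surface, an implicit radial-return update solves
`E_pr·(|ε − ε_pl| − Δκ) = σ_flow(κ + Δκ)` (the `(1−D)` factors cancel) with
a safeguarded Newton iteration — the equation is monotone with a unique
root in `(0, |ε − ε_pl|)`; (2) the Maxwell overstress is advanced with the
exact exponential integrator for piecewise-constant strain rate and damage
frozen at its end-of-step value. The stepper is therefore stable for the
stiff combination of 10 s holds and relaxation times of order seconds, and
exact for ramps and holds of undamaged material (verified against the
closed-form Zener ramp and relaxation solutions to <0.1%, and against an
explicit fine-step integrator to <0.5% on cyclic elasto-plastic runs). The
hot loop is JIT-compiled with numba.

### Fracture

The model has no intrinsic rupture event. A simulated specimen is truncated
where its equilibrium envelope saturates: flow stress reaching `0.99·σ_u`,
i.e. κ reaching `κ* = ln((σ_u − σ_Y)/(0.01·σ_u))/p`. The criterion is
applied to the rate-independent envelope, not to the total stress: the
viscous overstress (`η·ε̇` ≈ 20–30 MPa at the default rate) would otherwise
trigger "fracture" in the very first cycle of a cortical specimen, which
contradicts the multi-cycle records the protocol is built to produce. With
the calibrated damage rates this places cortical failure near 2.2% strain
and lets trabecular records complete the full protocol — mirroring the
observed contrast between the two tissues.

## Loading protocol

Displacement-controlled cycles with increasing peak strain: ramp at a fixed
strain rate, hold 10 s, unload at the same rate, proceed to the next peak;
the final cycle ramps to the last peak and holds there (fracture usually
intervenes for cortical parameters). Defaults: 7 cycles, peaks linearly
spaced from 20% to 100% of the last peak; last peak 2.6% strain (cortical)
or 5% (trabecular), echoing the reported apparent ultimate strains. The
strain rate (0.002 s⁻¹) and sampling rate (10 Hz) are not printed anywhere
and are set to quasi-static testing conventions; both are configurable but
must be identical between generation and fitting. Holds after unloading are
off by default (flag `hold_after_unload`). With this design a 7-cycle
record contains 7 loading and 6 unloading branches, matching how per-cycle
tangent moduli are usually reported (loading through cycle 7, unloading
through cycle 6).

In the synthetic generator the protocol is co-simulated with the model:
each unloading ramp stops where the simulated stress crosses zero
(experimental unloading is to near-zero force, not zero strain), floored at
zero strain.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Group distributions** — packaged presets (`table2_trab_ctrl` etc.) carry
  the per-tissue, per-group means and SDs of all seven parameters.
  `E_mx` is not reported directly; its mean is `E_0 − E_∞` (consistent by
  construction) and its SD is `sqrt(sd(E_0)² − sd(E_∞)²)`, treating the two
  spring moduli as independent.
* **Damage rate** — `k_D` is likewise not reported. Group defaults are
  calibrated once so that the group-mean specimen's damage at the end of the
  simulated record equals the reported group `D_end` (0.60 trabecular /
  0.75 cortical control; fracture-group values analogous) under the default
  protocols: 26.4 / 25.7 / 82.3 / 62.2 for trabecular CTRL/FRAC and
  cortical CTRL/FRAC. SDs follow by first-order propagation from the
  reported `D_end` SDs.
* **Hierarchy** — donors receive a normal shift carrying half the
  between-specimen variance (`donor_effect_frac = 0.5`; the true split is
  unknowable from printed summaries and is exposed in the spec); specimens
  add the remaining deviation. Draws are truncated at zero (means and SDs
  are all that is printed; a truncated normal adds the weakest further
  assumption) and re-drawn until `σ_u > σ_Y`.
* **Noise** — i.i.d. Gaussian stress noise with SD equal to the reported
  mean fit RMSE (3.2 MPa trabecular, 4.2 MPa cortical).
* **Metadata** — donor BMD from the reported T-scores via the standard
  young-adult femoral-neck reference (`BMD = 0.849 + 0.111·T` g/cm²); ages
  and sex ratios from the reported cohort margins; they drive no mechanics.
  Specimen TMD is drawn with correlation 0.6 to the specimen's `E_pr`
  deviation so that mineralization–stiffness correlations are recoverable.

What the generator does **not** emulate: optical strain-tracking artefacts,
force-channel drift, localized deformation outside the gauge region (the
dominant real-world rejection cause), two-timescale visco-elasticity, and
any 3-D or anisotropic behaviour. Passing recovery tests therefore shows
the identification machinery is correct and well-conditioned under the
assumed noise model — not that the model captures every feature of real
records.

## Parameter identification

Bounded least squares (scipy TRF) on the stress residual in MPa, driving
the model with the recorded strain history. The optimizer works in
log-parameter space with `σ_u = σ_Y + Δ` (Δ > 0), which enforces positivity
and the yield/ultimate ordering by construction. Bounds: `E_pr`, `E_mx`
0.1–50 GPa; `σ_Y` 5–200 MPa; Δ 0.1–295 MPa; `p` 1–1000; `η` 0.1–100 GPa·s;
`k_D` 0.1–500. Five starts: one from signal heuristics (first-branch
tangent → total stiffness; first-hold relaxation amplitude and time
constant → η and E_mx; relaxed hold stress → E_pr; envelope offset-yield →
σ_Y; envelope maximum → σ_u), the rest jittered log-normally (SD 0.35,
seeded). Residual weighting is uniform over samples, so hold phases
dominate by sample count — a documented consequence of the protocol, not a
choice of emphasis. Records with no measurable stress are flagged rather
than fitted; cohort fitting isolates per-specimen failures.

Identifiability: on noise-free records every parameter is recovered to
optimizer precision across the plausible parameter range. Under realistic
noise, `p` and `σ_u` are weakly identified for specimens whose records
never approach flow-stress saturation (low `p`, or `σ_u` far above the
stress actually reached): the fit then trades `p` against `σ_u` with no
cost change, and single fits can land at a bound. This is intrinsic to the
experiment, not the optimizer, and is exactly what the outlier regimen
(below) screens; cohort-level summaries are reported after it.

## Envelope evaluation

The envelope keeps samples whose strain strictly exceeds the running
maximum. Apparent modulus Ê: regression over the 10–40% stress window of
the first loading branch. Yield: intersection with the offset line
`σ = Ê(ε − offset)`; printed apparent yield strains (~0.25%) are close to
`σ_Y/Ê`, implying a small offset rather than the engineering 0.2%
convention, so the default offset is 0.02% and a linearity-deviation
criterion is selectable. Work densities are trapezoidal integrals of the
envelope split exactly at the interpolated yield point, so
`Ŵ_el + Ŵ_py` equals the total envelope area identically. `ε̂_u` is the
strain of the last envelope sample (the truncation/fracture point), with
the strain at maximum stress reported separately. Per-cycle tangent moduli:
branches segmented at strain-direction reversals, linear fit over the
20–80% stress span of each branch, NaN for branches with fewer than 4
window samples.

## Morphometry

Gaussian filter (σ = 1 voxel, kernel radius 1), single-level threshold at
550 mgHA/cm³, largest 26-connected component retained (pore space is
6-connected — the convention pair most common for bone voxel data). Bone
volume = voxel count × voxel volume; mean cross-sectional area = bone
volume / axial mask extent; engineering stress = force / mean area.
Porosity counts only enclosed cavities (background components not reaching
the image border); open channels reduce mean area but are not pores.
Images are assumed already calibrated to mgHA/cm³; the known
calibration-range caveat of HA phantoms limited to 800 mgHA/cm³ is
documented, not modelled. Phantoms: rectangular rods with fully interior
spherical pores and a spatially correlated TMD field, with planted
porosity/TMD ground truth recorded for recovery tests.

## QC and statistics

Two-stage IQR regimen with multiplier 1.5 and interpolated quartiles:
stage 1 on the fit RMSE; stage 2 computes per-parameter fences on stage-1
survivors and removes a specimen if any parameter falls outside. Fences are
frozen once computed (no iterative re-fencing), making the pipeline
deterministic and idempotent on its own output. Constant vectors remove
nothing (closed fence interval); fewer than 4 values is a warned no-op.

Coefficient of variation is sample SD over mean. Donor-level Pearson
correlations use per-donor parameter medians against donor BMD; tiers by
|r|: ≤ 0.29 weak, 0.30–0.49 moderate, ≥ 0.5 strong (the printed tier
sentence has an obvious typo on the weak bound; it is implemented as
|r| ≤ 0.29). Specimen-level associations use Spearman's rho with average
ranks on ties. Mixed-effects hypothesis testing is deliberately exported,
not implemented: `mixed_model_table` emits a tidy long-format table with
donor id (random effect), fixed-effect columns and a heteroscedasticity
grouping label for use in any statistics package.

## Problem sizes and determinism

Default records hold 700–1500 samples (7 cycles at 10 Hz); one noise-free
fit takes well under a second and the noisy-cohort recovery study uses
30-specimen cohorts, replicated three times in the test suite because the
post-QC cohort mean of the weakly identified parameters (σ_u, p) carries a
Monte-Carlo spread of several percent per cohort. All randomness flows
through seeded `numpy` generators; fixed seeds reproduce cohorts
byte-identically.

## Known limitations

* One visco-elastic timescale; real cortical tissue shows fast and slow
  components.
* The damage variable scales model stiffness; measured per-cycle tangent
  moduli also contain viscous contributions, so `1 − D` does not map 1:1
  onto tangent-modulus ratios.
* Uniaxial, isotropic, engineering-stress formulation; no geometric or
  material nonlinearity beyond the constitutive law.
* The offset-yield default (0.02%) is a convention; apparent yield strain
  depends visibly on it for strongly curved trabecular records.
* The generator's truncated-normal parameter draws can produce
  near-degenerate specimens (σ_u ≈ σ_Y) that fracture immediately; they are
  flagged `rejected`, mimicking discarded tests.
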