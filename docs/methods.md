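# Methods

## Pool partitioning model

The two-stage extraction is modelled as two sequential dilutions of a
well-mixed slice. The porewater pool equilibrates with the added NaCl
solution, so the first extract concentration c₁ relates to the
sediment-basis porewater pool by PWNO₃ = c₁·V₁/V_sed with
V₁ = V_pw + V_added. The freeze–thaw step releases the cellular pool
into the liquid remaining after 0.5 mL of supernatant was removed, so
the excess concentration (c₂ − c₁) is scaled by V₂ = V₁ − V_removed.
A `naive_v2` compatibility flag reproduces the variant that ignores the
removed volume (V₂ = V₁); the two differ by the factor V₂/V₁ (about 7 %
for typical slices), and which accounting the original campaign used is
not documented — both are therefore available.

Assumptions: extraction is complete, nitrate does not adsorb to the
solid phase, no microbial turnover during processing, nitrite is
counted with nitrate. Extraction kinetics and advective transport are
out of scope.

Numerical conventions:

* **Porewater density** defaults to 1.0 g mL⁻¹. At salinity 22 the true
  value is ≈1.016, a <2 % volume bias; the parameter is exposed in the
  config for users who want the salinity-corrected value.
* **Negative ICNO₃** (second extract weaker than the first) is
  measurement noise around a negligible cellular pool. It is clamped to
  zero for reporting *before* depth integration, a warning is logged and
  counted, and the signed value is retained in `icno3_raw` so that
  averaging across replicates stays unbiased (the parameter-recovery
  check uses the signed value for exactly this reason).
* **Slice geometry**: depth intervals are half-open [top, bottom) in cm
  with the surface at 0; the default slice volume is π(3.6/2)²·1 ≈
  10.18 cm³ (a 1-cm slice of a 3.6-cm core), overridable per row.
* **Depth integration** is the rectangle rule, because slices are
  homogenized volumes, not point samples. Profiles must tile the
  integration range contiguously; `allow_gaps` treats missing slices as
  zero instead of failing.
* A **dry slice** (wet = dry mass) has no defined porewater-basis
  concentration (NaN) but still yields a sediment-basis pool, since the
  added solution extracts whatever nitrate the slice carries.

## Diatom metrics

Undefined ratios (chlorophyll a = 0, or fucoxanthin at/below the
threshold) are NaN, never zero, and are excluded from downstream means;
summaries report the count of defined values. The ICNO₃/Fuco threshold
comparison is strict (>), with the 1.5 µmol dm⁻³ default exposed in the
config.

Replicate summaries report **both** the ratio of replicate means and the
mean of replicate ratios. The two conventions differ whenever replicates
are heterogeneous; published tables often print input means alongside
ratio means computed replicate-wise, so showing both makes small
discrepancies (e.g. 46.5 vs 46.7 mmol L⁻¹ for the 0.1 pL cell
concentration) attributable rather than mysterious.

The NH₄⁺-production envelope converts areal fucoxanthin to areal cell
numbers with a fucoxanthin-per-cell factor (default: the mat-derived
27.8 µmol dm⁻³ / 1.40×10¹⁰ cells dm⁻³ ≈ 1.99 fmol cell⁻¹) and multiplies
by a user-supplied per-cell ammonium production rate range. The default
rate bounds (0.1–2.0 fmol cell⁻¹ h⁻¹) are placeholders spanning the
order of magnitude reported for cultured benthic diatoms; they should be
set from the culture study relevant to the site, and the envelope is
linear in both the pigment content and the rates.

## Chao1 richness

Only the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) is implemented;
it is defined when no doubletons exist and reduces to S_obs when F₁ ≤ 1.
No variance or confidence interval is computed. Counts must be
non-negative integers (integral floats from CSV round-trips are
accepted); clustering, denoising and chimera removal happen upstream.

## Correlation screen

Spearman's rho is the Pearson correlation of average-ranked values.
Significance comes from a permutation test rather than the large-sample
t approximation: with 36 cores and tied ranks the approximation is
questionable, and a permutation null needs no distributional assumption.
For n ≤ 7 the null is enumerated exactly and the p-value is the plain
fraction of permutations with |ρ*| ≥ |ρ|; for larger n, 9999 seeded
Monte-Carlo permutations are drawn and the p-value uses the
add-one form (1 + hits)/(1 + n_perm), which never reports zero. A
constant vector makes rho undefined (NaN), which propagates. Replicate
cores within a month are treated as independent observations (n = 36),
matching the screen's design; no autocorrelation handling is attempted.
Per-pair 0.05/0.01 flags are uncorrected; a Holm-adjusted column is
emitted alongside for transparency.

## Synthetic-core generator

The generator emulates the study design the analysis assumes: 12 monthly
samplings × 3 replicate cores × 10 one-cm slices. Functional forms are
the simplest shapes consistent with the qualitative seasonal structure:

* temperature T(m) = 10 + 8·cos(2π(m − 8)/12) °C (peak in August);
* overlying-water nitrate OWNO₃(m) = 40 − 35·cos(2π(m − 8)/12) µmol L⁻¹,
  floored at zero — anti-phase with temperature via the shared phase, so
  the winter nitrate maximum is hard-wired;
* surface PWNO₃ = 0.4·OWNO₃ µmol dm⁻³ with e-folding depth 2 cm. The
  factor equals the default porosity (0.4), i.e. surface porewater is in
  equilibrium with the overlying water; peak surface values ≈30 µmol dm⁻³;
* fucoxanthin = 6·(1 − 0.5·cos(…))·exp(−z/3 cm) µmol dm⁻³, anti-phase
  with temperature; chlorophyll a follows from a Fuco/Chl a ratio that
  declines linearly from 0.8 at the surface to 0.2 at 10 cm;
* ICNO₃ assumes cells in equilibrium with local porewater at a fixed
  enrichment factor E (default 500, admissible 10²–10³):
  cell-internal concentration = E·(PWNO₃/φ), converted to a
  sediment-volume pool via cell density × biovolume × 10⁻¹². Cell
  density defaults to 1.2×10⁹ cells dm⁻³ at the surface with a 10 cm
  e-folding depth — deliberately slower than the pigment decay, so the
  intracellular pool penetrates deeper than fucoxanthin alone would
  suggest and the depth-integrated total pool is comfortably ≥1.5× the
  porewater-only pool, the qualitative "total inventory roughly doubles"
  structure. Peak surface ICNO₃ ≈22 µmol dm⁻³.

Noise is multiplicative lognormal with unit mean (concentrations are
positive and replicate scatter scales with the mean), applied
independently per field: once as replicate-to-replicate variability on
the latent pools and pigments, once as measurement error on the extract
concentrations and pigment measurements. The default relative s.d. is
0.05 per source; no replicate-dispersion estimate was available to
calibrate against, so this is a choice, not a measured value. One global
seed drives everything through deterministically spawned substreams, so
identical seeds give bitwise-identical datasets.

The forward measurement model derives slice geometry from porosity
(V_pw = φ·V_sed, dry mass from a 2.65 g cm⁻³ grain density) and inverts
the partition mass balance exactly, so partition ∘ forward is the
identity at zero noise — the round-trip is tested to 10⁻⁹ relative
error.

**What the generator does not emulate**, and hence what passing tests do
not show about field data: subsurface concentration maxima (spring
porewater, early-autumn intracellular), spring/fall double blooms in the
pigments (a single anti-phase sinusoid is used), nitrate uptake
dynamics decoupling cells from porewater, bioturbation, advection and
migration, and any sequencing-read structure. Recovery and
sign-structure results demonstrate the pipeline's correctness under the
stated statistical model, not the field system's behaviour.

## Parameter recovery check

For each of 20 seeds a full default year is generated, measured, and
partitioned; monthly means of the recovered pools (3 replicates) are
compared to the noise-free truth. The tolerance band is ±2 standard
errors propagated from the known noise model: for the porewater pool
var ≈ 2cv²·pw₀²/3, and for the intracellular pool — whose estimator
subtracts two noisy extracts — var ≈ cv²·((ic₀+b)² + b² + ic₀²)/3 with
b = pw₀·V₂/V₁, so the porewater cross-term correctly dominates in deep
slices where ic₀ → 0. Coverage of a 2-SE band is ~95.4 % by
construction; the check requires ≥95 % of pool values (porewater and
intracellular counted separately) inside the band.

## Problem sizes

The test suite and the acceptance script run the full default study
design (360 slices per year), 20 simulated years for the recovery check,
1000 random slices for the round-trip identity, 200 multinomial draws
for the Chao1 sampling property, and 100 random vectors for the Spearman
oracle; the whole suite completes in a few seconds on one core.
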