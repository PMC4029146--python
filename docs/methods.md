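# Methods

## Problem setting

Re-irradiation of recurrent malignant glioma delivers a second radiation
course (typically 36 Gy in 2 Gy fractions) years after a ~60 Gy primary
course. The cranial organs at risk (OARs) — optic chiasm, brainstem, optic
nerves, whole brain — accumulate dose across both courses, but the two
plans often come from different planning systems and cannot be fused into a
single voxel-wise dose map. The package therefore works entirely on
per-structure dose-volume histograms (DVHs) and scalar reductions of them.

## DVH model

A DVH is stored with a strictly increasing dose-edge grid starting at 0 Gy
and relative (fractional) volumes; the absolute structure volume in cc is
metadata. Cumulative and differential forms convert exactly into each other
on a shared grid, with the bin representative dose taken as the edge
midpoint — the standard unbiased choice for EUD power sums. Conversions are
inverse to one another only when the grid covers the full dose support
(cumulative value 0 at the last edge); a truncated curve's residual volume
is folded into the last bin to keep fractions summing to one.

Near-minimum and near-maximum doses use a volume threshold of 1e-6 of the
structure volume: `d_max` is the right edge of the highest bin holding more
than that fraction, `d_min` the left edge of the lowest. The default
resampling grid uses 0.1 Gy bins from 0 to one bin past the maximum dose;
the underlying planning-system resolution is unknown, and at 0.1 Gy the
binning error on EUD is below 0.5% (verified against per-voxel sums).

Curves digitised from printed hardcopies arrive as sparse, jittery point
lists. Ingestion sorts by dose, averages duplicated doses, clips volumes to
[0, 1], prepends (0, 1.0) when absent, and restores monotonicity with a
running minimum — the simplest deterministic order-preserving projection.
Isotonic least-squares regression would also work; the running minimum was
chosen because it never raises a digitised value, keeping the cleaned curve
conservative (never above the drawn one).

## EUD forms

Two classical DVH reductions sit behind one dispatch interface:

* power-law generalised EUD, `gEUD = (Σ v_i D_i^k)^(1/k)` — whole brain
  `k = 5`, serial OARs `k = 12`. Evaluated in log space (log-sum-exp) so
  `k = 200` does not overflow. `k = 1` returns the mean exactly; the value
  is non-decreasing in `k` and bounded by `[d_mean, d_max]`.
* log-cell-kill EUD for targets, `EUD = −(1/α)·ln(Σ v_i e^(−α D_i))` with
  `α = 0.4 Gy⁻¹`, bounded by `[d_min, d_mean]` and non-increasing in α.

The parameter set (k per structure class, α, recovery r) is one registry
object, so sensitivity analyses can swap values per run. The α-parameterised
continuous form is used for targets rather than the SF2-based 2-Gy-normalised
variant; the two differ only in parameterisation, and the continuous form
keeps α in physical units. The brain exponent is applied as a power-law
volume-effect exponent. No fractionation (EQD2/NTD) correction is applied
anywhere: accumulation operates on physical-dose-based EUDs.

## Cumulative dose and recovery

For each structure and metric the two course values are summed per patient:
the plain sum is an upper bound of the accumulated EUD (Minkowski's
inequality for the power-law form with k ≥ 1; exact for the mean; overly
conservative for the maximum, since hot spots of the two plans usually lie
in different regions — maxima are still summed because that is the
convention for conservative reporting). The recovery-corrected estimate
`r·v₁ + v₂` credits repair of normal CNS tissue between courses with a
uniform `r = 0.5` applied to the first course only; per-structure values
are configurable but default to the single uniform factor, an acknowledged
simplification (the optical pathway and the remaining CNS differ in repair
capacity).

The superadditive upper bound does **not** hold for the log-cell-kill
target form (a structure split between a cold region in one course and a
cold region in the other is a counterexample), so the bound is asserted and
tested only for the power-law OAR forms — which are the forms the
accumulation is used for; target EUD sums are reported as descriptive
quantities, not bounds.

Cohort tables are built patient-wise: per-patient sums first, then the
cohort median and maximum of those sums (median of sums, not sum of
medians; the two differ and a regression test pins the distinction).
Patients missing either course's DVH for a structure drop out of that row
only, so each row carries its own N. An exclusion list (default empty)
allows dropping, e.g., patients with interstitial brachytherapy between the
courses whose seed dose cannot be accumulated.

## Geometry

`V = (4/3)πr³` converts tumour volumes (cc) to equivalent-sphere radii
(cm). Cohort dichotomisation at a radius cut-off puts a volume exactly on
the boundary into the "large" group (documented, configurable by choosing
the cut). Display rounding is half-up to one decimal, matching clinical
table conventions.

## Survival analysis

Endpoints: post-recurrence survival (PRS) from the first day of
re-irradiation to death or last follow-up; PFS from re-irradiation to
progression, death or censoring; OS from the start of the initial
radiotherapy; and the inter-course interval as a covariate. Durations are
calendar-day differences; months are days/30 rounded half-up to one decimal
(the only convention consistent with 642 d = 21.4 mo and 173 d = 5.8 mo).

Estimation uses lifelines: Kaplan-Meier product-limit curves with the
median defined as the smallest time at which S(t) ≤ 0.5 ("not reached" when
the curve stays above 0.5); the one-degree-of-freedom log-rank test; and
univariate Cox proportional-hazards fits with Efron tie handling, which is
preferable for the heavy ties of day-resolution data. Mann-Whitney U,
paired Wilcoxon (identical pairs return the degenerate statistic 0 with
p = 1) and Fisher's exact test cover the non-survival comparisons. All
p-values are two-sided; no multiple-testing correction is applied across
the univariate battery, matching common retrospective reporting — a known
limitation when reading the univariate table.

## Synthetic cohort

The generator emulates the statistical structure the analysis expects, not
any real plan data:

* **Demographics** follow configurable marginals (62.1% male, median age 52
  in 18-68, 34.5/48.3/17.2% MGMT methylated/unmethylated/unknown, 81%
  surgery, 79.3% grade IV, 75.9% KPS ≥ 70), each drawn independently.
* **DVH shapes** come from a three-parameter logistic family for the
  cumulative curve — `v(D) = (1−s)·logistic((d50−D)/spread)` with `v(0)=1`,
  truncated at a hard per-structure dose cap (~105% of the course
  prescription) because planned distributions end steeply near the plan
  maximum. Per-structure defaults put the cohort medians in the range
  clinically reported for two-course glioma treatment (primary-course OAR
  EUDs of tens of Gy, re-irradiation chiasm/nerve EUDs of a few Gy); they
  are illustrative, not fitted. Patient-to-patient variation is lognormal
  on d50 (15% for OARs, 3% for targets, whose coverage follows the
  prescription) and on spread, with additive jitter on the spared fraction
  for OARs only — targets never acquire a spared (zero-dose) volume.
* **Missingness**: each primary-course structure DVH is independently
  unavailable with a per-structure probability (0.53-0.79), emulating
  plans from outside institutions and uncontoured organs; re-irradiation
  data are always present. Two patients are flagged with distant, distinct
  lesions and excluded from the volume dichotomy.
* **Survival** is Weibull proportional hazards (shape 1.2, scale 418 days;
  exponential available as a switch): KPS ≥ 70 patients follow the
  baseline (median ≈ 308 days) and KPS < 70 multiplies the hazard by 1.96
  (median ≈ 176 days). Censoring is an independent exponential
  loss-to-follow-up time calibrated to censor ~20% of patients —
  independence is required for the Kaplan-Meier estimate to be unbiased,
  and a parameter-recovery test confirms the configured medians come back
  out of the pipeline at large n. Progression times are a Beta(2,1)
  fraction of the survival time.
* **Hardcopy emulation** samples a curve at evenly spaced doses with
  Gaussian jitter on both axes (defaults 0.3 Gy / 0.005 volume fraction,
  30 points), deterministic per seed.

What passing tests on this substrate do **not** show: anatomical realism of
dose distributions, correlations between demographics and dose, or any
statement about real patients' dose-outcome relationships. The generator
validates the *machinery* — invariants, estimator consistency, table
construction — not clinical effect sizes.

## Numerical choices

* EUD sums in log space; volumes below 1e-12 treated as empty.
* Cumulative-DVH validation tolerances: 1e-9 on v(0)=1, monotonicity and
  differential normalisation.
* Monotonicity repair of digitised points by running minimum (deterministic,
  conservative).
* Boundary volume at a dichotomy cut goes to the large group.
* Display rounding half-up (banker's rounding would map 2.05 → 2.0).
* Problem sizes in the test and acceptance suites (1000 random DVHs for the
  ordering property, 500 voxel-map pairs for the superadditive bound, 100
  digitisation seeds, 50 Cox replicates at n = 200, synthetic cohorts of
  1000-3000 for marginals and KM medians) were chosen so that Monte-Carlo
  noise is well below the asserted tolerances.

## Known limitations

* No DICOM-RT input; DVHs arrive via the CSV dialect or the generator.
* No voxel-wise dose accumulation or deformable registration; the EUD sum
  is a bound, not an estimate of the true accumulated EUD.
* No fractionation correction (EQD2), no NTCP/TCP modelling, no
  time-dependent recovery — `r` is a single empirical constant.
* Univariate statistics only; no multivariable Cox model.
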