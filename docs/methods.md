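# Methods

## Measurement chain and decomposition

A frameless 6D image-guided SRS/SRT setup proceeds in stages: mask
immobilization, stereotactic localization at CT simulation, infrared (IR)
setup to isocenter, stereoscopic kV imaging registered to DRRs (XC), a
robotic 6D couch correction, and kV verification (XV). Treating the stages
as independent, each contributes a systematic uncertainty Σ (the mean of its
shift distribution, a reproducible bias) and/or a random uncertainty σ (its
SD, session-to-session scatter). Shift distributions are characterized by
moments of fitted normals — no robust or mixture fits; outliers are part of
the clinical reality the moments summarize.

The estimator mapping is:

* **mask Σ_M** (per treatment): mean of that treatment's XC shifts. The XC
  shift measures where the anatomy actually is after IR setup, so its
  per-treatment mean isolates the static bias of that patient's mask (plus
  the frame term common to everyone — the estimator deliberately does not
  subtract Σ_F, and parameter-recovery tests compare against m_t + Σ_F).
* **setup σ_S** (per treatment): sample SD of the same shifts; a
  single-fraction treatment contributes exactly zero SD rather than being
  dropped.
* **frame Σ_F**: mean over all XC setups, pooled over fractions (so it
  equals the fraction-count-weighted mean of the per-treatment means — an
  exact identity used as a test). Mask biases average out across the cohort;
  what survives is the bias of the IR frame/marker-detection chain.
* **localizer Σ_L** and **X-ray σ_XR**: mean and SD of all XV shifts. After
  a correct couch move the only signal left in XV is the localization bias
  of the stereotactic reference plus fresh registration noise. σ_XR is the
  pooled SD of all XV shifts; the SD of per-treatment XV means is exposed as
  an alternative convention (`xray_sd_convention`) but shrinks with the
  per-treatment fraction count and is not the default.
* **couch sag Σ_C**: a deterministic phantom lookup — per-axis deflection
  versus load (0/10/50/70 kg) and couch angle (0–315°). The budget takes the
  worst-case row by radial sag; ties break toward larger load, then larger
  angle. At 90°/270° the imaging view is blocked by the couch, so sag there
  genuinely survives the correction loop.
* **isocentricities**: per-axis Winston–Lutz means. The MV term composes
  gantry + collimator + couch-rotation means per axis; offsets not
  measurable for a given rotation ("n/a", e.g. vertical for collimator and
  couch) are stored as an explicit absent value, contribute zero to sums,
  and raise a flag in the component row — never silently zero-filled.

Per-axis significance is a two-sided one-sample t-test against zero. A
sample with zero variance has no t statistic: all-zero samples report no
p-value (flag `degenerate-zero`), constant nonzero samples report p = 0.0
with flag `degenerate-variance`. The t-test is validated against a sign-flip
resampling oracle: because the sum of squares is invariant under sign flips,
|mean| is a monotone function of |t| over the flip orbit, making the flip
test exact under the symmetric null.

## Radial magnitudes

The radial of one shift is √(lat² + long² + vert²); rotations never enter
it. For a component estimated from a record stream the canonical radial is
the **mean of per-record radials** (SD of radials for random components),
which is what clinical shift tables report; the quadrature of the per-axis
means is smaller whenever shifts change sign and is carried separately as
`radial_of_means`. Components that *are* mean vectors (isocentricities,
couch sag) use the vector norm.

## Combination rules

With component magnitudes on the radial basis:

* model rule: `CU_model = Σ_systematics |Σ_i| + sqrt(Σ_randoms σ_j²)`.
  Systematic magnitudes enter as absolute values — signed cancellation
  between independent devices is physically unjustified.
* GUM rule: `CU_GUM = sqrt(Σ_all c²)`, expanded `k·CU_GUM` with k = 2
  (≈95% coverage).

`CU_model ≥ CU_GUM` always (ℓ1 vs ℓ2 norm); both rules are homogeneous of
degree one and strictly monotone in every component — these are asserted as
property tests on randomized budgets. The random term of the model rule is
exactly `sqrt(σ_S² + σ_XR²)`; only those two scatter sources enter it, per
treatment (σ_S could alternatively enter as a cohort average; per-treatment
was chosen and is what `per_treatment_cu` implements).

The **before-XC** budget per treatment is {that treatment's Σ_M and σ_S} ∪
{Σ_F, Σ_L, Σ_C, Σ_ISO,MV, Σ_ISO,kV, Σ_ISO,IR, σ_XR}. The **after-XC**
budget drops everything the X-ray loop corrects (mask, setup) and keeps the
device systematics plus σ_XR; its membership is configurable
(`after_xc_components`). Because nothing patient-specific remains, the
after-XC CU is identical for all treatments — asserted exactly. The PTV
margin recommendation is the after-XC model CU rounded to 0.1 mm.

An alternative `per_axis` basis (combine per translational axis first, then
take the radial of the per-axis results) is implemented because published
cumulative values cannot always be attributed to one basis; the radial basis
is canonical. Published cohort CU figures for this workflow are not exactly
reproducible from component tables under any single convention, so the
acceptance of the combination stage rests on its algebraic properties
rather than on matching a printed cumulative number.

## Synthetic cohort generator

`generate_cohort` draws, per treatment t, a static mask bias
m_t ~ N(0, mask_sd) per axis; each fraction's XC shift is
`m_t + frame_systematic + N(0, setup_sd) + N(0, xray_sd)`. When XC fails
the 0.7 mm / 1.0° gate an XV record is emitted:
`localizer_systematic + N(0, xray_sd)` — the same registration spread enters
XC and XV, matching the single X-ray random term of the model. A
`force_xv` flag emits XV for every fraction (estimator unit tests at full
n). All draws come from one `numpy` generator seeded by `CohortTruth.seed`;
Winston–Lutz draws use an independent child stream so changing the number of
QA sessions never perturbs the cohort.

Default study conditions: 49 treatments over 35 patients (first 14 patients
carry two isocenters), fractions 5×30 + 3×17 + 1×2 = 203 XC setups;
frame systematic (0.18, 0.25, −1.27) mm / (−0.32, 0.18, 0.47)°; localizer
(−0.03, −0.01, 0.03) mm / (−0.03, 0.00, −0.01)°; mask spread
(1.2, 2.2, 1.9) mm and (0.8, 0.9, 0.9)° — chosen to reproduce the observed
range of per-treatment mean shifts (up to ≈ ±5 mm longitudinally, ≈ ±2.5°);
setup noise (0.42, 0.46, 0.20) mm / (0.30, 0.33, 0.32)°; registration noise
(0.25, 0.26, 0.21) mm / (0.25, 0.24, 0.24)°. Winston–Lutz means/SDs default
to typical monthly-QA values per rotation axis, and the couch-sag table is
the measured phantom grid. Under these conditions nearly every XC fails the
6-axis gate (the vertical frame bias alone is −1.27 mm), so ~200 XV records
accompany the 203 XC records.

What the generator does **not** emulate: intra-fraction motion, time trends
(mask loosening over a course appears only as a larger static spread, not
drift), correlated axes, non-normal tails, or repeat verifications (XV2
records are accepted by the data model but never generated). Passing
recovery tests therefore demonstrate estimator correctness under the stated
generative model, not robustness to those real-data features.

## Numerical choices

* Sample SDs use ddof = 1 (`ddof` configurable to 0); SD of a single
  observation is defined as 0.
* Tolerance comparison is inclusive (≤) on every axis.
* Histogram bins are half-open `[lo, lo + w)` with edges anchored at integer
  multiples of the width, so zero is always an edge and counts conserve n.
* CSV round-trips write floats with `repr` (shortest exact form) and absent
  values as `n/a`; reading accepts `n/a`, `na`, `nan`, `none`, empty.
* A global sign flip of all shifts leaves every budget output unchanged
  except the signed systematic means (radials and SDs are flip-invariant).
* Reports round to 2 decimals; machine-readable CSVs keep full precision;
  no timestamps inside data files, so re-runs are byte-identical.

## Problem sizes

The test suite runs the full study-scale cohort (203 fractions) throughout,
uses 10⁴ fractions for moment-consistency checks, 20 seeds × study scale
for parameter recovery, 10³ randomized budgets for the norm-inequality
property, and 10⁵ resamples for the sign-flip oracle; the whole suite
completes in well under a minute.

## Known limitations

* The decomposition assumes stage independence; uncertainties that act at
  several stages (e.g. CT slice thickness affecting both localization and
  DRR quality) cannot be separated by these estimators.
* The frame estimator relies on mask biases being zero-mean across the
  cohort; a fleet-wide mask manufacturing bias would be absorbed into Σ_F.
* The worst-case couch-sag policy is conservative by construction;
  `at_angle` lets users budget for a specific treatment geometry instead.
* Margin output follows the model rule only; van Herk-style recipes
  (2.5Σ + 0.7σ) are related work and intentionally out of scope.
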