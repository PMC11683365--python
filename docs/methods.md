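# Methods

`cortbs` implements a cortical backscatter (CortBS) quantitative-ultrasound
analysis chain end to end: forward simulation of pulse-echo RF from
intracortical pore ensembles, spectral estimation of frequency-dependent
attenuation and backscatter, inversion of the pore-diameter distribution
with its derived morphology metrics, and the statistical layer used to
compare fracture discrimination against DXA densitometry.  Because no raw
patient data are available, every stage is exercised on synthetic inputs
with known ground truth; this note records the models, the parameters that
matter, and what the passing tests do and do not demonstrate.

## Single-pore scattering kernel

A pore (Haversian canal) is modelled as a weak fluid-like quasi-cylinder at
perpendicular incidence.  Its backscatter cross-section is

    sigma_b(f, d) = G · d_mm^4 · f_MHz^3 · exp(−(k · β·d/2)^2),

a Rayleigh law (`d^4 f^3`) with a Gaussian form-factor roll-off, where
`k = 2πf/c_bone`.  The effective-radius factor `β = 4` (configurable in
`cortbs.kernels`) widens the scatterer's acoustic footprint relative to its
geometric radius.  This is the package's central phenomenological choice:
with a purely geometric radius, a 28 µm pore has `k·a ≈ 0.15–0.22` across
the 3–9 MHz band and its diameter changes the spectral shape by ~0.01 dB —
unmeasurable under any realistic averaging, which would make the stated
20–200 µm inversion range unidentifiable.  With `β = 4` the roll-off of
20–200 µm pores falls inside the analysis band, the backscatter peak of
large-pore distributions shifts toward lower frequencies (the qualitative
signature of "trabecularized" bone), and the grid is invertible.  The same
kernel object is used by the simulator and the inversion, so forward/inverse
self-consistency — not absolute device equivalence — is the testable
contract.  `G = 5` fixes the arbitrary relative amplitude scale; the kernel
is swappable behind `cortbs.kernels.backscatter_cross_section`.

## Forward RF model

Each A-line is synthesized in the frequency domain as (i) a specular
periosteal surface echo at a known depth with amplitude `cos(inclination)`,
(ii) one echo per pore, spectrally filtered by `sqrt(sigma_b)` and
attenuated round-trip by `alpha(f) = alpha0 + alphaf·f` [dB/mm one-way],
and (iii) white Gaussian noise at a configurable level relative to the
surface-echo peak.  The pulse is a Gaussian-modulated sinusoid, nominal
center 6 MHz, fractional bandwidth 1.2 (FWHM of the amplitude spectrum);
the broad bandwidth keeps the pulse spectrum nearly flat over 3–9 MHz,
which matters for unbiased attenuation slopes (below).  Propagation speeds
default to 1540 m/s (soft tissue) and 3565 m/s (cortical bone).  RF
synthesis is per-beam 1-D — no diffraction, beam inclination enters only as
the specular amplitude factor — because the analysis chain consumes only
depth spectra.  Pores are assigned uniformly to A-lines and depths; pore
density is a free parameter (no published magnitudes exist) with defaults
of 150–250 pores/mm³ chosen so simulated porosities land in the observed
single-digit-percent range.

## Spectral estimation

1. **Surface detection**: envelope maximum per A-line inside a depth gate;
   inclination from a local plane fit (±2 beams, ±1 sweep) to neighboring
   surface depths.  Quality gates: reference-echo SNR ≥ 20 dB and
   |inclination| ≤ 15°; a frame with fewer than 25 % quality lines raises a
   "no valid surface" error.  All gates are configurable and logged.
2. **Reference spectrum**: Hann-windowed power spectrum of the surface echo
   per quality beam, amplitude-corrected by `1/cos(inclination)`, averaged
   in dB across beams.  Whether a device would normalize per beam or with a
   pooled reference is an open design point; the pooled-in-dB convention is
   implemented because it is the more robust choice at low per-beam SNR.
3. **Normalized spectrogram**: sliding Hann windows below the surface
   (default 2.0 mm of bone depth, 75 % overlap, starting 1 mm deep to avoid
   surface ring-down), power averaged across quality lines in the linear
   domain, expressed in dB relative to the reference.  Depth is 0 at the
   periosteal surface, mm, two-way mapped with the bone sound speed.
   Window spectra are energy-normalized (`|X|²/Σw²`), so halving the
   spectrogram window (with the reference fixed) leaves band averages
   unchanged for speckle-like signals.
4. **Attenuation**: per-frequency linear regression of dB power on depth;
   the round-trip slope is `−2·alpha(f)`; `alpha0`/`alphaf` from a linear
   fit of `alpha(f)` over the band; `alpha_6MHz = alpha0 + 6·alphaf` by
   definition.  Short analysis windows spectrally smear the measured
   spectra, which flattens `alpha(f)` toward the band center (biasing
   `alphaf` low and `alpha0` high while preserving `alpha_6MHz`); the
   2.0 mm window and the flat (broadband) pulse keep this bias within the
   ±0.02 dB/MHz/mm recovery tolerance.
5. **Backscatter**: `BSC(f)` is the depth average of the spectrogram
   compensated by `+2·alpha(f)·depth`; `BSC_Mean` its band mean;
   `AIB_Average` the uncompensated band-and-depth average (apparent
   integrated backscatter), so `AIB ≤ BSC_Mean` whenever `alpha(f) ≥ 0`.

## Pore-diameter inversion

The measured linear-power BSC is modelled as `A n` with `A[f, bin] =
sigma_b(f, d_bin)` on a 20–200 µm grid of 2 µm half-open bins (floor = the
method's 20 µm resolution limit) and `n` the areal pore density per bin
[pores/mm²].  The solver is non-negative least squares with a
second-difference smoothness penalty.  Numerical choices that proved
load-bearing:

* rows are weighted by `1/BSC(f)` — dB-domain noise is constant *relative*
  error in linear power, and unweighted fits let the low-frequency end
  dominate;
* columns are normalized to unit norm (the raw kernel spans ~10⁴ in scale);
* the penalty operator is zero-extended beyond the grid — with free
  boundaries, NNLS parks spurious mass in the unpenalized floor bin;
* the smoothing weight defaults to 0 for exact (noiseless) data; for
  RF-derived spectra the default is a fixed dimensionless weight of 0.3 in
  the weighted, normalized system.  A discrepancy-principle option
  (`noise_db`) is provided, but when the residual is dominated by
  systematic window-resolution error rather than iid noise it
  over-smooths, which biases the recovered peak toward larger diameters;
  the fixed weight sits on the stability plateau observed across seeds.
  Heavy ill-conditioning with zero smoothing is flagged, not hidden.

Derived metrics: peak = center of the maximal bin; Q10/Q90 =
count-weighted percentiles with linear interpolation inside bins (number
distribution, not area-weighted); FWHM crossing points by linear
interpolation at half the peak height, the left crossing clamped to exactly
20 µm when the distribution is cut at the floor (reproducing the
`FWHM,min = 20.00 ± 0.00` pile-up of floor-limited subjects);
`FWHM_max = FWHM_min + FWHM` holds exactly by construction.  Cortical
porosity is `Ct.Po = 100 · Σ n(bin)·(π/4)·d_bin²` (areal convention for
quasi-cylindrical canals); because the inversion explains the *absolute*
reference-normalized amplitude, the recovered total density carries the
`BSC_Mean` adjustment.  The absolute porosity scale from RF data contains
an O(1) geometry factor that no published constant pins down; shape
metrics (peak, percentiles, FWHM, index) are scale-free and are what the
tests assert.

The pore-diameter index `Ct.Po.Dm.I` matches the amplitude-normalized BSC
shape (dB) against an ordered family of 12 template distributions
interpolating tail mass 0→0.6 and mode 26→36 µm (narrow-unimodal to
"trabecularized"); the subject value is the mean of per-sub-region best
indices, so fractional values arise naturally.  Whether the index should be
matched in the BSC domain or on the inverted distribution is genuinely
open; BSC-domain matching is implemented because it avoids compounding the
inversion's regularization bias into the index.

## Synthetic cohorts

`synthesize_cohort` draws per-subject parameter vectors (13 CortBS + 6 DXA
parameters + age, height, weight, BMI) cell-wise — (control, T1DM, T2DM) ×
(Fx, nFx) with n = (16/55, 8/23, 17/18) — from multivariate normals whose
means and SDs are the published group summaries of an aged
diabetes/control cohort, with a block-structured correlation matrix
(DXA block 0.7; pore-geometry block 0.55; attenuation/backscatter blocks;
verified positive definite) and post-hoc clipping to plausible ranges
(clipping is logged, preserving seed determinism).  Two designs ship:

* `default_cohort_design` — every published cell mean as-is;
* `headline_effect_design` — CortBS means fracture-specific, DXA means
  pooled over fracture within each diabetes group, so DXA carries only the
  diabetes signal.  Any apparent DXA fracture discrimination then arises
  only through the higher fracture prevalence of the (higher-aBMD) T2DM
  group — the "diabetic paradox" — and the CortBS-vs-DXA AUC ordering can
  be asserted as a qualitative headline without pretending to reproduce
  printed AUCs.

What the generator does *not* emulate: non-normal marginals, measurement
dropouts/exclusions, site- and device-specific covariances, and any real
coupling between the RF simulation layer and the cohort tables (they are
calibrated to the same summaries but sampled independently).  Passing tests
therefore demonstrate correctness of the machinery under the stated
statistical structure, not clinical performance.

## Discrimination statistics

* **PLS-LDA LOOCV**: labels Fx = 1, nFx = 0; per fold, features are
  z-scored on the training subjects and a PLS regression fitted with the
  component count chosen as the smallest whose training fitted-response
  RMSE is within 0.1 % of the minimum, capped at `floor(n/10)` (training
  RMSE is monotone in components, so an exact "smallest minimizer" would
  always return the cap).  The held-out subject receives the continuous
  predictor; scores are deterministic and order-invariant.
* **SPA variable selection**: each Monte-Carlo sampling (default 2000)
  draws 80 % of subjects and half the variables, fits a small PLS-LDA
  sub-model, and records held-out misclassification error with each
  included variable intact vs. permuted; variables whose permuted errors
  are stochastically larger (one-sided rank test, p < 0.05) are selected.
  The analysis repeats until the selected set is identical on two
  consecutive repetitions (max 10; non-stable sets are flagged).  Selection
  runs once on the full data set, outside the LOOCV loop, mirroring the
  common workflow in this field; the optimism this induces in the
  cross-validated AUC is acknowledged and affects both compared modalities
  symmetrically.  Risk scores are standardized PLS predictors throughout
  (the alternative of a logistic-regression predictor is a near-equivalent
  monotone re-mapping that rank statistics such as the AUC cannot
  distinguish, so only the PLS backend is implemented).
* **Risk scores**: the LOOCV predictor standardized by the mean and SD of
  the non-fractured controls, oriented so that lower scores mean higher
  risk (T-score convention); the reference population has mean 0 / SD 1 by
  construction in every run.
* **ROC**: rank (Mann–Whitney) AUC with ties at half credit; SE by the
  Hanley–McNeil (1982) closed form; operating point at the Youden-optimal
  threshold.  The correlated-AUC comparison uses the Hanley–McNeil (1983)
  z-test with `r` approximated by the mean of the within-class Pearson
  correlations between the two score sets (the published lookup table that
  maps this average to `r` is not reproduced anywhere accessible; the
  approximation is standard, and a seeded simulation shows its rejection
  rate tracks a paired-permutation oracle within 5 percentage points).
* **PLS regression of aBMD**: three-fold seeded CV with out-of-fold
  predictions, summarized by Spearman ρ and RMSE.

## Cohort statistics

N-way ANOVA uses type-II sums of squares (type III reachable through
statsmodels directly) on categorical factors with optional named
interactions; rank-deficient designs are rejected naming the aliased
terms.  A summary-statistics one-way ANOVA (`anova_from_summaries`) is
algebraically identical to the raw-data F, which is what licenses checking
published per-cell tables without raw observations.  Two-group screening
combines a Lilliefors normality decision (α = 0.05, both groups) with a
two-sided rank-sum test and the sign of the median difference.  Raw
p-values are reported without multiplicity correction (exploratory
convention).  The DXA femur-side rule retains the side with the lower
total-area aBMD (ties resolve to the left, recorded as a tie).

## Problem sizes and determinism

Recovery-grade simulations use 96 × 48 A-lines over a 7 mm analysis depth
with 250 pores/mm³ in 450 mm³ (the dense 3-D scan of a real measurement is
the physical analogue of this averaging); unit tests use 16 × 4 to 48 × 12
lines.  Null calibration uses 200 label permutations at n = 140 and SPA
null runs at 200–300 Monte-Carlo samplings (the SPA default elsewhere is
2000); the headline ordering uses 50 seeded cohort replicates.  Every
stochastic step takes an explicit seed; spawned child seeds keep all seeds
below 2³¹.  Known limitations: no diffraction or refraction modelling, no
soft-tissue overburden, no cortical-thickness estimation, absolute porosity
only defined up to the documented calibration constant, and LOOCV null AUCs
sit slightly below 0.5 (a known artifact of leave-one-out discrimination),
which the calibration tests accommodate by testing band coverage rather
than a point value.
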