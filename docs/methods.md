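# Methods

This note documents the models, numerical choices and limitations behind
the package, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The grading score

The score maps per-eye morphometry to three ordinal subscores (ICsc 0–3,
NDsc 0–1, NMsc 0–2) and their sum T-IVCM (0–6); see the README for the
bins. Two reading conventions had to be fixed:

* **Half-open density bins.** The printed inflammatory-cell bands
  ("10–49", "50–99", ">100") leave (49, 50), (99, 100) and the point 100
  unassigned, yet measured densities are real-valued averages over five
  frames. We score with half-open bins [0,10), [10,50), [50,100), [100,∞),
  so every nonnegative density is gradable and 100 cells/mm² grades IC-3.
  This is a deliberate, documented deviation from a literal reading of the
  printed integer bands.
* **Morphology thresholds.** Clinically, reflectivity and tortuosity are
  graded qualitatively. We operationalise them with configurable cutoffs:
  tortuosity flag at arc/chord > 1.2 (sub-basal fibers are nearly straight;
  1.2 is far outside rendering/tracing noise but well inside the range the
  generator's "abnormal" tail occupies) and reflectivity flag at
  nerve/background > 2.5 (between the ≈2 of dim fibers and the ≈3–4 of
  bright ones under the default rendering contrasts). Both live in config,
  never at call sites.

Worst-eye selection (one eye per patient) uses the Oxford grade, then the
pain score, then a seeded uniform tie-break, making the choice reproducible
while unbiased across seeds.

## 2. Synthetic cohort generator

### What it emulates

One draw = one patient's worst eye, with group label (autoimmune vs
non-autoimmune DED), sex, nine clinical scales, four morphometric traits
(cell density, nerve density, tortuosity, reflectivity), HLA-DR in AUF, and
the computed grading score. Group sizes default to 63/151 (total 214).

### Marginals

Each variable is a monotone transform of a standard-normal latent, so that
a Gaussian copula carries rank structure through it. Families are chosen so
the *realised* moments match the published group means ± SDs:

* **Truncated normal**, moment-matched by root-finding, for age (≥18),
  OSDI subscales (≥0), OSDI total ([0,100]) and pain ([0,10]).
* **Lognormal**, closed-form moment match, for Schirmer, TBUT and HLA-DR.
  The published coefficients of variation (Schirmer 9.7±9.8 in the
  autoimmune group; HLA-DR 70,000±65,000) are at or above 1, which no
  nonnegative truncated normal can reach; the lognormal reproduces them
  with a realistic right skew. OSDI subscales are truncated at 0 only —
  their printed scales are taken as given rather than reconciled against
  the standard OSDI item ranges (the published subscale SDs exceed what a
  doubly-bounded distribution could carry).
* **Discretised normal** on the 0–5 grid for the Oxford grade (cutpoints
  at half-integers; location/scale solved so the discretised mean and SD
  match).
* **Latent morphometry.** Cell density is lognormal with (µ, σ) solved so
  that the *binned* ICsc has the published mean and SD (probabilities
  evaluated exactly through the normal CDF — no Monte Carlo, so the score
  moments are unbiased). Nerve density is lognormal (shape 0.5) pinned by
  P(≤15) = published NDsc mean. Tortuosity is 1 + lognormal (shape 0.5)
  and reflectivity lognormal (shape 0.3), each pinned so its flag fires
  with probability NMsc-mean/2; the two flags are conditionally
  independent, which reproduces the published NMsc SD to within ~0.05.
  Nerve fiber length is derived as NFD × 0.4 mm × tortuosity (one traced
  crossing of the 0.4 mm frame per counted nerve).

### Correlation calibration

Published rank correlations involve coarse ordinal scores, which attenuate
Spearman's rho; pasting the published values into the latent correlation
matrix would systematically under-recover them. Instead:

* **Continuous–continuous pairs** use the exact bivariate-normal identity
  ρ_latent = 2 sin(π ρ_S / 6).
* **Pairs involving a discretised margin** are calibrated by bisection on
  the latent ρ: at each candidate, a fixed common-random-number sample
  (default 50,000 pairs) is pushed through both margin transforms and the
  achieved Spearman compared to the target (tolerance 0.02). Common random
  numbers make the achieved value monotone and smooth in the latent ρ, so
  bisection is safe; unreachable targets (attenuation ceilings) raise an
  error naming the achievable range.
* **Composite scores.** T-IVCM is a deterministic sum, so it cannot carry
  an independent planted correlation. Its association with HLA-DR is
  reached jointly: the cell-density/HLA-DR latent is calibrated first
  (against the ICsc target), then a shared tortuosity/reflectivity–HLA-DR
  latent parameter is bisected until the *total* score's Spearman with
  HLA-DR hits its target. The nerve-morphology subscore's associations
  (with Oxford, with age) are calibrated the same way through a shared
  two-flag parameter.

Only correlations reported as significant are planted; all other latent
pairs are left at zero (the source reports no full matrix). Group-level
targets differ where the subgroup analyses differ: the total-score/HLA-DR
target is 0.32 in the non-autoimmune group (as reported) and 0.25 in the
autoimmune group — chosen so the pooled cohort reproduces the population
value ≈0.30 while the autoimmune subgroup stays below its n=63
significance threshold, matching the reported significance pattern. The
assembled matrix is repaired to the nearest unit-diagonal PSD matrix
(Higham alternating projections); with the default targets the repair is
numerically a no-op (shift < 1e-12).

Calibration depends only on the configuration, uses its own fixed seed,
and is cached; replicate cohorts at different seeds share it. Identical
(config, seed) pairs yield byte-identical cohort tables.

### What it does not emulate

No treatment effects or longitudinal structure; no missing data (real
cohorts have plenty); unreported variable pairs are independent by
construction, so e.g. OSDI total is uncorrelated with its own subscales;
per-patient bilateral structure is not modelled (the generator emits worst
eyes directly); morphometric within-eye frame-to-frame variance is
collapsed into the per-eye mean. Passing recovery tests therefore shows the
pipeline is correct and calibrated — not that real DED data look like this.

## 3. Synthetic imaging and morphometry

Frames are 8-bit, 384×384 px over 400×400 µm; origin top-left, x
rightward, y downward, 0-based pixel coordinates everywhere. Nerves are
random chords plus sinusoidal perpendicular displacement (3–8 periods,
amplitude = the tortuosity dial), stroked ≈5 px wide via a
distance-transform profile (full intensity within 1.5 px of the
centerline, 1 px soft shoulder) — the visible caliber of a sub-basal
bundle with its reflective halo at ≈1 µm/px. Cells are isotropic Gaussians
(σ = 3 px) with 2–4 short radial processes (maturity is not modelled).
Rendering order: objects → Gaussian blur (σ = 0.7 px) → additive Gaussian
noise → clip to 8 bits. Ground-truth reflectivity is defined as
(background + nerve contrast)/background, the quantity the measured index
estimates.

Morphometry counts **one annotated polyline = one nerve** (no
branch-merging rule is defined for the manual counts being mirrored, so
none is invented). Tortuosity is arc/chord per polyline, averaged;
degenerate (closed-chord) polylines are excluded with a warning and still
count for density. The focus measure is the variance of the 3×3 Laplacian;
frame selection takes the top five with a stable tie-break (input order).
Per-frame metrics are averaged per eye — the threshold-then-average order
for nerve density (average NFD, then one ND subscore per eye) follows the
per-eye reading of the grading table. The automated cell detector
(Laplacian-of-Gaussian, σ 2–5 px, threshold relative to the
background-subtracted peak) is optional plumbing: the canonical path
consumes annotation files, mirroring manual counting. On clean frames the
detector recovers planted counts exactly; at the default noise level its
recall is ≈0.95, and it is not guaranteed against false positives on
nerve ridges.

## 4. Cytometry calibration

QIFI-style: ordinary least squares of log10(ABC) on log10(MFI) over ≥3
bead populations (r² < 0.98 warns), then
AUF = 10^(intercept + slope·log10(MFI − background)). The exact AUF
definition in the source is unstated; this bead-regression convention is
adopted and documented. Background defaults to 0 when no isotype control
is supplied; samples at or below background convert to 0 AUF with a flag.
Weighted fits are out of scope.

## 5. Statistics

* **Spearman**: Pearson on midranks (tie-corrected). p values: exact
  permutation by full enumeration for n ≤ 10 (chunked; feasible to 10! =
  3.6M), otherwise the t approximation with n−2 df. At n = 214 the
  approximation's size is indistinguishable from nominal (the acceptance
  suite verifies a masked fraction ≈ α over 28,000 null pairs).
* **Mann-Whitney U**: midrank ties; exact enumeration when n₁+n₂ ≤ 12
  with no ties, else normal approximation with tie and continuity
  correction; two-sided throughout.
* **Masking**: raw p < 0.05, mirroring how such cohorts are reported; a
  Benjamini–Hochberg option exists but is off by default. Missing values:
  pairwise-complete deletion with per-cell n reported. Constant variables
  yield missing (not zero) correlations.
* **Stratifications**: low ICsc = IC-0…IC-2 vs high = IC-3 (the source
  figure's "IC-3 to IC-4" caption conflicts with the score's maximum of 3;
  high = IC-3 is the only consistent reading). Extreme total-score groups:
  T-IVCM ≤ 2 vs ≥ 5, intermediates excluded.

## 6. Problem sizes and runtime

Recovery statistics use 20 replicate cohorts of 214 eyes (grand means and
replicate-averaged correlations); the null-calibration check uses 1,000
independent 214×8 tables; detector benchmarks use 20 frames; bead recovery
uses 100 replicates. These sizes put Monte-Carlo error well inside each
stated tolerance (e.g. SE of the replicate-averaged Spearman ≈ 0.015
against a ±0.05 band) while keeping the full suite around half a minute.

## 7. Known limitations

The renderer is a geometric phantom, not a photorealistic corneal texture
model (no epithelial background, no axial stack structure); real-frame
intensity statistics were not available to match. The generator's
independence defaults understate the dense correlation structure of real
clinical variables. The asymptotic Mann-Whitney path deviates from exact
enumeration by up to ≈0.04 in p at the smallest sizes where it can fire
(tied samples, n₁+n₂ ≤ 12); the exact path covers untied samples there.
Inter-rater reliability of the grading cannot be reproduced without human
regrading and is out of scope.
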