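# Methods

## Scope and model

`nmrlogd` implements a fully computational logD-prediction workflow:
structure → predicted per-hydrogen ¹H chemical shifts → fixed-length
spectral feature vector → Gradient-Boosting regression of
chromatographic logD (CHI / Chrom logD at pH 2.6, 7.4, 10.5), evaluated
by seeded 10-fold cross-validation, plus the benchmarking machinery
needed to compare spectrum sources (assignment-free spectral RMSE,
dataset mixing, negative controls, normalized error metrics,
applicability-domain and similarity analysis).

## HOSE-code shift prediction

The predictor is a nearest-environment lookup. For every
hydrogen-bearing heavy atom we build a canonical spherical-environment
string: breadth-first shells from the anchor; within a shell, branches
sorted by (element priority C > O > N > halogens > others, bond symbol,
recursive sub-code); atom tokens carry element, attached-hydrogen count
and formal charge; edges that do not increase the BFS distance are ring
closures, emitted as `&` and not expanded. Spheres are `/`-separated, so
truncating a depth-6 code to *s* spheres equals encoding at depth *s*
directly — the property that makes sphere-by-sphere fallback cheap.
This is a self-contained canonical dialect: it guarantees that
graph-identical environments produce identical codes (the contract the
predictor needs), and makes no attempt at string compatibility with any
external HOSE database.

Training registers every mapped hydrogen at all depths 1..`max_spheres`
(default 6, the common choice for ¹H work; configurable). Prediction
looks up the deepest available code and falls back shallower; a proton
matching no sphere at all receives the table's global mean, with the
fallback count logged. Aggregation per code is the unweighted mean
(median available via `ShiftTable(aggregate="median")`).

Consequences tested: automorphic protons always get identical
predictions; re-predicting the training set at full depth reproduces
per-code means exactly; enlarging the table never increases fallbacks.

## Featurization

Two routes converge on a length-500 vector:

* **Bucket integration of shift lists** — 500 equal half-open bins
  [left, right) over [−1, 14) ppm; each in-range shift increments one
  bin by 1; a shift exactly at the upper edge is dropped (logged).
  Half-open binning is the standard histogram contract; the range and
  bin count are configuration, applied uniformly within one feature
  matrix. Counts preserve relative integration (methyl → 3,
  methylene → 2) and need no normalization.
* **Trace reduction** — dense traces are linearly interpolated onto a
  uniform 16,384-point grid over [−1, 12] ppm (points outside the input
  support set to 0), then reduced by summing intensity per bin, which
  conserves total in-range intensity exactly, and min–max normalized per
  spectrum to [0, 1000]. Min–max (min → 0, max → 1000) is the simplest
  reading of a fixed 0–1000 normalization range and is exposed as a
  policy switch (`minmax_0_1000` / `none`); a constant vector collapses
  to zeros with a warning.

Solvent masking zeroes bins whose centers fall in caller-supplied ppm
windows (union semantics); a preset lists typical DMSO-d6 / CDCl₃ /
water / TMS regions. The default mask is empty because generated
spectra contain no solvent signals; the exact windows to remove from
experimental data are an acquisition-dependent choice.

## Assignment-free spectral comparison

Computed and reference shift lists are compared without assigning
signals to nuclei: both lists are sorted (descending ppm, ties broken by
input index) and paired rank by rank; the RMSE over pairs is symmetric,
permutation-invariant, zero iff the sorted lists coincide, and never
exceeds the largest pairwise shift difference. Lists of unequal length
are refused — with one shift per hydrogen on both sides, unequal lengths
signal a data problem (e.g. exchangeable protons missing from one list),
and silently guessing a pairing would bias the statistic. Method
benchmarking averages per-molecule RMSEs per solvent group, ranks
methods within each solvent (ties share the minimum rank), and sums the
per-solvent ranks into a combined score. Paired two-sided t-tests
compare per-molecule error distributions; a zero-variance difference
vector cannot support the test and returns p = 1 with a warning.

## Regression and evaluation

The estimator is scikit-learn's `GradientBoostingRegressor` with its
standard defaults; every report records the parameters and seed actually
used. 10CV uses a seeded shuffled `KFold`; each compound is predicted
exactly once out-of-fold. The headline RMSE pools all out-of-fold
predictions (equivalent to applying the RMSE formula to the concatenated
prediction vector; per-fold values are also reported) because pooling
uses every row exactly once and is reproducible regardless of fold-size
imbalance. NRMSE divides by the label mean (as |ȳ| — a scale has no
sign), range, or standard deviation. Absolute-error summaries (median,
mean, quartiles, 1.5·IQR outlier count) mirror standard boxplot
statistics.

The **hashed-label negative control** replaces each compound's feature
vector with a deterministic pseudo-random vector obtained by seeding a
generator from a BLAKE2 hash of (compound id, seed), rescaled to the
original matrix's value range, labels untouched. By construction the
features carry no label information, so cross-validated RMSE must
approach the label SD; a model that still "predicts" well on the control
reveals leakage. The hash construction (id + seed → 500 uniform values)
is this package's concrete choice for an information-free stand-in.

## Study orchestration

* **Source comparison** runs one 10CV per spectrum source on identical
  compounds and labels (enforced), appends the control, and flags
  best/worst.
* **Mixing** swaps the feature vectors of a seeded random subset of
  round(fraction·n) compounds (half rounded away from zero) from the
  experimental to the generated source — compound identity and labels
  fixed, so RMSEs stay comparable across fractions. The trend reports
  mean ± SD of pooled RMSE per fraction over seeded repeats, with the
  0% and 100% endpoints always included; repeat *r* uses seed
  base + r for both the mix and the fold shuffle, which makes the
  endpoints bit-identical to pure-source runs at the same seeds.
* **Applicability domain**: out-of-fold |error| vs true label value,
  with compounds in the extreme 5% label tails flagged — models tend to
  fail near the boundaries of the covered property range, where training
  examples are sparse.
* **Similarity**: Morgan fingerprints of radius 2 folded to 2048 bits
  (the standard reading of ECFP4) and Tanimoto |A∩B| / |A∪B| between
  every external and training compound, with per-compound and set-level
  summaries.

## Synthetic data generator

The generator stands in for a measured compound library and defines the
conditions under which the pipeline is exercised:

* **Compounds** are multisets of proton-environment groups drawn from an
  11-class palette placed at standard ¹H correlation-chart positions
  (methyl 0.90, aromatic 7.30, aldehyde 9.80 ppm, ...), group sizes 1–3
  (methyl-heavy), proton budgets uniform on 6–30 — drug-like ¹H counts.
  The default library size is 300 compounds: large enough for stable
  10CV statistics at desk scale.
* **Class SDs default to 0** because the library emulates
  *predictor-generated* pseudo-spectra: a lookup-table shift predictor
  returns its tabulated value for every occurrence of an environment, so
  shift positions are reproducible across compounds. Setting the SDs
  > 0 emulates DFT-style lists (distinct per-proton values) or
  experimental assignment scatter; several tests use this to build
  degraded feature sources.
* **Labels**: for each (parameter, pH) slice, a linear read-out of the
  bucketized features with piecewise-per-class weights (each bin carries
  the coefficient of its nearest environment class — lipophilicity as a
  function of proton-class composition), standardized over the library
  and rescaled to the slice's target mean/SD, plus Gaussian noise with
  SD = 0.3 × signal SD by default. The target means/SDs are the
  observed statistics of real CHI/Chrom logD distributions at the three
  pH values (e.g. CHI pH 7.4: ȳ = 2.21, σ = 1.03; Chrom labels roughly
  twice as dispersed), so the NRMSE machinery operates on realistic
  scales. The implied total label SD is σ_target·√(1 + noise²).
* **Traces** are sums of unit-area Lorentzians (FWHM 0.01 ppm, a typical
  solution linewidth at the 500-bin resolution) on the 16,384-point grid
  plus Gaussian baseline noise (SD 0.02 of a unit-area peak scale).
  Lineshape detail is immaterial downstream of bucketing.
* The **HOSE world** is separate: small real molecular graphs (alkanes,
  aromatics, ethers, carbonyls) with rule-based correlation-chart
  shifts, split into training templates and held-out molecules whose
  environments only partially overlap training — exercising
  sphere-by-sphere fallback on real graphs.

What passing tests on this generator do *not* show: real spectra have
solvent and impurity signals, baseline drift, multiplet structure and
instrument variability, and real logD depends on structure nonlinearly;
the generator's planted linear dependence verifies the pipeline's
mechanics (featurization fidelity, CV hygiene, control separation,
metric identities), not chemical accuracy on laboratory data.

## Numerical choices and degenerate inputs

* Bin edges are `linspace` endpoints; bin membership is half-open.
* Normalization computes `(x − min)/(max − min) · 1000` with the
  division first so the maximum lands on exactly 1000.0.
* CSV round trips use `%.17g` on write and `float_precision="round_trip"`
  on read, keeping shift lists and labels bit-exact.
* All random streams are `numpy` `default_rng` seeded from explicit
  integers (or integer tuples / BLAKE2 id hashes), so outputs are
  reproducible across platforms.
* Degenerate cases: empty shift list → zero vector; constant labels →
  constant predictor with warning; < 10 rows → explicit error suggesting
  fold reduction; zero-variance paired differences → p = 1; empty
  training table → error on prediction, warning on build.

## Problem sizes

Default study sizes are chosen for interactive desk-scale runs: 300
compounds for model-level experiments (source comparison, control
separation, recovery), 150 for the repeated mixing grid, 1000 for
Monte-Carlo checks of the label statistics. The acceptance script uses
10CV with feature subsampling (`max_features="sqrt"`) for the dense
trace/control matrices and a high-capacity configuration (2000 trees,
depth 2) for the zero-noise recovery run.

## Known limitations

* The HOSE dialect is internally canonical but not interoperable with
  external HOSE-code databases; stereochemistry is ignored after 2D
  flattening (stereo-augmented codes are out of scope).
* The built-in shift predictor is only as good as its training table;
  with the synthetic HOSE world it reproduces class shifts, not real
  chemical-shift physics.
* `nrmse(mean)` is unstable when the label mean is near zero — the
  range- and SD-normalized variants are the robust choices.
* Mixing assumes both sources cover identical compounds; mixing by
  resampling compounds (rather than swapping features) is intentionally
  not implemented.
* Leave-one-out CV is not implemented; the fold count is configurable
  but the protocol is k-fold only.
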