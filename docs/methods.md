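# Methods

## Input model and assumptions

A *sample* is a marked point pattern: cell centers (x, y) in µm in an
arbitrary slide frame, each carrying the membrane mean optical density
(OD) of one IHC marker on a 0–255 scale. Coordinates are taken as final —
no pixel/µm conversion is attempted, which keeps the scores independent of
the imaging modality. OD is accepted as already scaled; values above 255
are clamped with a warning, negative values are rejected. Everything
upstream (segmentation, stain quantification) is out of scope; the `od`
column is treated as final, with no assumptions about background
subtraction.

## Co-occurrence scores

The neighborhood graph connects cells at Euclidean distance ≤ r (closed
ball, so ties at exactly r are edges; coincident cells are neighbors at any
r > 0; isolated cells keep degree 0). Construction uses a k-d tree but is
contractually identical to the all-pairs definition, which the tests
enforce by brute force.

Continuous OD is mapped to integer levels 0..254 by round-half-up followed
by clamping — the minimal-assumption binning consistent with a 255×255
matrix on a 0–255 stain scale. Each undirected edge contributes both
ordered level pairs, so the matrix is exactly symmetric before
normalization (the symmetric-matrix convention of classical Haralick
texture analysis); consequently the row and column marginals coincide. Four
features (homogeneity, contrast, correlation, angular second moment) are
evaluated exactly per their formulas. When every counted pair shares one
level the marginal variance is 0 and correlation is reported as missing
(NaN), not an error, so cohort tables stay rectangular; a radius with no
edges yields all four features missing with a warning. Radii default to
10/25/50/75 µm → 16 scores.

## Tessellation scores

Tiles are axis-aligned squares (default 250 µm) anchored at the minimum
corner of the cell bounding box plus a grid offset; a cell belongs to the
half-open interval tile containing it, so membership is a partition. The
convex hull only motivates the region — tiles are not clipped to the hull
polygon, since the ≥ 5-cells filter already removes background tiles.
Tiles with fewer than `min_cells` (default 5) members are dropped.

Per OD threshold θ (defaults 8/10/15/20/25), a cell is positive iff
OD ≥ θ (ties positive). Tile entropy is Shannon entropy of the
positive/negative proportions **in nats** — the heterogeneity threshold
0.61 corresponds to a 70/30 split only in natural log (in bits it would be
0.881). The tile-typing scheme: entropy > 0.61 → *heterogenous*; otherwise
*homogenous-high*/*-low* by **tile mean OD** against θ (mean OD rather
than majority cell class; the two dimensions of the decision scheme are
deliberately decoupled so a mostly-positive but weakly-stained tile can be
homogenous-low). Note the asymmetry at the boundary: a tile at exactly 70 %
positive has entropy 0.6109 > 0.61 and is heterogenous; the flip happens at
the (0.3, 0.7) band edges up to cell-count resolution.

Grid-shift averaging evaluates a score on the four grids offset by ±25 µm
(1/10 tile size) in x and y and averages them — the origin grid is not
included by default (configurable), matching the reading that the final
readout is the average over the shifts. Offsets where no tile survives are
skipped with a warning.

The EDI of a list of per-tile values is the component count of the
BIC-best Gaussian mixture among 1–5 components (EM, 10 restarts, tolerance
1e-4, ≤ 500 iterations, fixed seed; regularized covariance 1e-6). BIC ties
break toward fewer components; a constant vector has EDI 1 by definition;
with fewer than 10 values the component range is reduced to floor(n/2),
minimum 1.

**Composition of the 37-score battery.** The tessellation battery is
pinned as: per θ (×5) — shift-averaged high-expression tile ratio, mean
tile entropy, EDI of tile entropies, three tile-class fractions, and the
global marker-positive cell fraction (7 scores × 5 thresholds = 35); plus
the EDI of tile mean ODs and the EDI of tile OD standard deviations.
This enumeration contains every named tessellation score (binary-map
ratio, mean entropy, the 7 EDI scores, the class fractions) and totals
exactly 37; the global positive fraction closes the count. The exact
composition of the original 37 is not fully specified anywhere we could
pin it down, so this is a documented design choice. The three class
fractions and the mean entropy are computed on the unshifted grid; only
the binary class ratio is shift-averaged.

## Score selection

Correlation pruning is greedy: scores ordered by (univariate Cox p, name)
— the name tiebreak makes the kept set independent of column order — and
accepted unless |Pearson r| > 0.9 (absolute value; sign conventions differ
across score families) against an already-accepted score. Columns with
more than 20 % missing values are dropped; remaining missing values are
median-imputed with an audit entry; constant columns are excluded
(correlation undefined).

Stability selection fits an L1-penalized Cox model on B = 100 subsamples
(without replacement, half the cohort) over a 25-point log-spaced penalty
path computed once on the full data. A score counts as selected in a
subsample if it is active at any penalty before more than q = ⌈√p⌉
features have entered the path — the active-set cap standing in for the
per-family error bound of stability selection. Scores with selection
frequency ≥ 0.20 are kept. B, the subsample fraction, the path length and
q are not dictated by anything stronger than common stability-selection
practice and are all configurable.

## Survival evaluation

Univariate Cox fits z-score the score, so hazard ratios are per SD.
Non-identifiable or non-convergent fits return a flagged result rather
than raising. The multiple Cox model forces the clinical base covariates
(age, dummy-coded gender/grade/pathologist score, average expression),
screens candidates at |Spearman ρ| < 0.9 against average expression, and
runs forward–backward stepwise search minimizing partial-likelihood AIC
(criterion choice ours; a tiny L2 penalty, 1e-6, stabilizes small-cohort
fits). The LR test uses 2·(llᶠⁱⁿᵃˡ − llᵇᵃˢᵉ) against χ² with df = number
of added scores.

Quantile stratification tests the 25/50/75 % score quantiles as cutoffs
("high" = score ≥ cutoff), skips cutoffs that empty a group, and reports
all valid cutoffs plus the best by logrank p. Survival fits use lifelines
(Efron ties in Cox; standard hypergeometric-variance logrank).

The repeated CV permutation scheme (defaults n = 20 repeats, k = 10 folds,
m = 1000 permutations): per repeat, a random k-fold partition (redrawn
until every training set contains ≥ 2 events); per fold, the cutoff with
the best training-fold logrank among the quantile candidates recomputed on
training scores (quantiles only — no finer grid) labels the held-out
samples; the pooled labels give one logrank statistic. The identical
procedure — same folds, same candidate machinery — is applied to m joint
permutations of the (time, event) pairs; empirical p =
(1 + #{null ≥ observed})/(m + 1), so p ≥ 1/(m+1) > 0. Fold assignments are
positional and all randomness flows from one seed, so identical inputs and
seed reproduce results exactly. The inner logrank statistic is a
vectorized/numba implementation verified against lifelines to machine
precision; candidate cutoffs and group masks are precomputed per fold
because they do not depend on the permuted survival data.

## Synthetic tissue generator

The generator emulates the study conditions: cohorts of ~30 samples,
10³–10⁵ cells each, 2000×2000 µm default window with 10⁴ cells (a tile
count comparable to mapped resections). Cell positions are uniform-Poisson
or Matérn-clustered (parents in the dilated window, offspring uniform in
disks, conditioned on the target cell count). OD fields: constant
(homogeneous expression), two-level patchy — a white-noise grid smoothed
at a patch length-scale (default 500 µm), thresholded at a quantile so the
high-expression region covers a designed area fraction — a deterministic
blob layout for exactly-controllable tests, and a linear gradient. Noise
is Gaussian (σ ≈ 1.5–2 OD), OD clamped to [0, 255]. High/low levels
(≈ 22 / ≈ 5) bracket the OD thresholds 8–25 the scores use.

Cohort survival follows a proportional-hazards model: exponential baseline
(rate 0.02/month, median ≈ 35 months untreated), log-hazard β·z with z the
standardized driver score; censoring is independent exponential with its
rate solved so the expected censored fraction meets the target (default
30 %). The true β is recorded for recovery tests.

What the generator does *not* emulate: staining artifacts, segmentation
errors, tissue folds, non-convex tissue masks, cell-density/expression
coupling, or competing risks. Passing tests therefore demonstrate the
correctness and statistical behavior of the scoring machinery under
controlled spatial structure, not clinical performance on real cohorts.

## Experiment problem sizes

The packaged experiments (`spathet.experiments`) use desk-scale settings:
tile-size robustness uses 30 patchy samples of 10⁴ cells on a 3000 µm
window (patch scale 500 µm = 2× the reference tile, grid shift 1/10 of
each tile size) — the window is chosen so even 375 µm tiles number ~60+
per sample, as in mapped resections, keeping the class ratio away from
quantization noise. Statistical calibration runs 200 null cohorts of 60
samples with a reduced CV (5 repeats × 5 folds, 200 permutations); power
and driver-recovery checks plant a hazard ratio of 3 per SD. These sizes
are the package's validation defaults; all are parameters.

## Known limitations

- The 37-score composition question above; one score family (global
  positive fraction) is a closure choice.
- Whether the original co-occurrence counting was one- or two-sided per
  edge is unknowable from the description; symmetric counting is fixed
  here and affects no feature except degenerate correlation sign cases.
- No edge-effect correction for boundary cells in degree statistics or
  boundary tiles.
- Stepwise model selection and best-of-quantiles cutoffs are known to be
  optimistic in-sample; the CV permutation scheme exists precisely to
  price that in, and the calibration suite checks its type-I error.
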