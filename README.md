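# spathet — spatial heterogeneity scores for cell-level marker expression

Pathologist scoring and plain averaging of per-cell immunohistochemistry
(IHC) readouts discard how a marker's expression is *arranged* in the
tissue, even though intra-tumoral heterogeneity carries prognostic
information. `spathet` turns a per-cell table of a tissue sample — cell
center coordinates in µm and membrane mean optical density (OD, 0–255) per
segmented tumor cell — into per-sample spatial heterogeneity scores, and
evaluates their prognostic value against overall survival. It is aimed at
computational-pathology researchers working downstream of a cell
segmentation pipeline.

## The scores

**Co-occurrence scores.** A cell neighborhood graph connects every pair of
cells within a radius *r* ∈ {10, 25, 50, 75} µm. The OD values of the two
endpoints of each edge are accumulated (symmetrically) into a 255×255 joint
histogram, normalized to a distribution *p(i, j)*. Four Haralick-type
texture features summarize it:

- Homogeneity = Σᵢⱼ p(i,j) / (1 + (i−j)²)
- Contrast = Σᵢⱼ (i−j)² p(i,j)
- Correlation = (Σᵢⱼ i·j·p(i,j) − μₓμᵧ) / (σₓσᵧ)
- Angular second moment = Σᵢⱼ p(i,j)²

with μ, σ the marginal mean and standard deviation — 16 scores per sample.

**Tessellation scores.** The tissue (bounding box of the convex hull of all
cells) is tiled with a 250 µm grid; tiles with fewer than 5 cells are
discarded. At each OD threshold θ ∈ {8, 10, 15, 20, 25}, cells are
marker-positive iff OD ≥ θ, and each tile gets the Shannon entropy (nats)
of its positive/negative proportions. Tiles are typed *heterogenous*
(entropy > 0.61, i.e. less than 70 % majority), else *homogenous-high* or
*-low* by tile mean OD. Per-sample aggregates — high-expression tile ratio
(averaged over four 25 µm grid shifts), mean tile entropy, three class
fractions, global positive fraction, and the Ecosystem Diversity Index
(EDI: the BIC-best component count among 1–5-component Gaussian mixtures
fitted to per-tile entropies, means, or SDs) — give 37 scores per sample,
53 in total.

**Survival machinery.** The battery is reduced by correlation pruning
(|Pearson r| > 0.9; the member with the best univariate Cox p survives) and
Cox-lasso stability selection (scores selected in ≥ 20 % of subsample
fits). Retained scores are evaluated by univariate Cox regression (HR per
SD), multiple Cox models with forced clinical covariates plus
forward–backward stepwise selection and a likelihood-ratio test,
quantile-cutoff (25/50/75 %) logrank stratification, bivariate grouping
against average expression, and an *n*×*k*-fold cross-validation scheme
whose pooled test-fold logrank statistic is judged against *m* permutations
of the survival data (empirical p, never 0).

A synthetic-tissue generator (uniform or Matérn-clustered cell positions;
constant, patchy, blob, or gradient OD fields; proportional-hazards
survival linked to any chosen driver score) makes every stage testable
end to end without patient data.

## Worked example

```bash
python examples/01_score_single_sample.py
```

scores a 10⁴-cell patchy synthetic sample (high patches OD≈22, low
regions OD≈5) and prints, among others:

```
homogeneity_r10=0.345  contrast_r10=10.361  correlation_r10=0.932  asm_r10=0.010
homogeneity_r75=0.328  contrast_r75=21.099  correlation_r75=0.861  asm_r75=0.009
ratio_high_od10 = 0.594
frac_hetero_od10 = 0.125
```

Homogeneity and correlation shrink from r=10 to r=75 because distant
neighbors more often straddle a patch boundary; the heterogenous tile
fraction (0.125) counts boundary tiles that mix positive and negative
cells; `ratio_high_od10` is the shift-averaged fraction of high-expression
tiles, matching the designed ~50–60 % high area. `examples/02` renders a
tile-class map of a gradient sample; `examples/03` runs the full
selection + stratification + CV-permutation chain on a simulated cohort
with a planted hazard driver (HR 2.5 per SD) and prints, e.g.,
`univariate Cox: HR 2.03 per SD ..., p=0.00162` and
`CV permutation: median empirical p=0.0398` for selected scores.

A thin CLI mirrors the pipeline: `spathet simulate`, `spathet score`,
`spathet survival`, `spathet all` (see `spathet --help`).

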