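# Methods

This note documents the models, defaults and design choices behind
`mcprogram`, stage by stage, and what the synthetic study conditions do and
do not establish about real data.

## Pseudobulk construction and quality control

Pseudobulk profiles are raw-count sums over the cells of one type in one
sample. Sample QC keeps a (cell type, sample) profile when it aggregates at
least 10 cells **and** at least 1,000 counts; both thresholds are inclusive
and applied per view, so different cell types may retain different sample
subsets. Gene QC keeps genes reaching 10 counts in some sample and 15 in
total (the differential-expression variant uses 5/10). Model features are
the intersection of QC-passed genes with batch-aware highly variable genes,
minus the top 25 cell-identity markers per cell type, which otherwise
dominate the latent space. The HVG criterion — standardized dispersion of
log1p counts within mean-quantile bins, computed per batch, qualifying a
gene that ranks top-n in any batch — is one common convention among several;
it is isolated behind `highly_variable_genes` and pluggable.

Cell-type compositions are closed to proportions and centred-log-ratio
transformed; zeros are handled by multiplicative replacement with
δ = 10⁻⁶ × the row's smallest nonzero proportion, a value small enough that
CLR scale-invariance holds to numerical precision on zero-free rows.

## Multi-group, multi-view factor model

A Bayesian multi-group factor model with ARD sparsity is the natural fully
probabilistic tool for this task. This package instead uses a deterministic
factorization with the same contract — shared loadings per view, group-wise scores, per-(group,
view, factor) variance explained, factors dropped below 0.1% incremental
explained variance — because desk-scale testing needs exact reproducibility
and the object of interest here is recovery of planted structure, not
posterior inference. Concretely: genes are centred per group and scaled to
unit variance, each view is scaled to unit total variance, the concatenated
matrix is SVD-truncated, and per-sample scores are re-solved by least
squares against the shared loadings using only the views in which the
sample was observed (missing rows are mean-imputed for the SVD step only).
Loadings are reported on the per-gene standardized scale, so w² is
approximately the fraction of that gene's variance the factor explains and
the coordinated-signature threshold |w| ≥ 0.5 has its intended meaning.
Factor sign is canonicalized (largest-|loading| gene positive).
`factorize.from_external` adapts an externally fitted model (imported
loadings/scores) to the same interface.

Caveat: an SVD factorization orthogonalizes scores, so when two true
programs share cell types and their sample scores are correlated by
sampling noise, the fitted factors are slightly rotated mixtures; at the
default study size (60 samples) this costs a few percent of score
correlation, visible in the restricted factor's recovery (~0.95 typical).

## Program activities, signatures, communication

Activity scoring is the univariate linear model: the profile is regressed
on the weight vector over the full gene universe (non-members weighted 0),
and the slope t-statistic — identically r√(m−2)/√(1−r²) — is the score,
capped at 10⁶ in the degenerate perfect-fit limit. Coordinated signatures
select cell types with network CV R² ≥ 0.8 or factor variance explained
> 10% (a single-cell-type program keeps only that cell type), retain genes
with |w| ≥ 0.5 in a selected cell type, and average only the retained
loadings. Bulk mapping scores each (factor, cell type) loading set per
sample and takes the variance-explained-weighted mean across cell types.

Ligand-receptor communication uses a transparent magnitude score rather
than a consensus rank aggregate over multiple external inference tools:
√(mean ligand expression in sender × mean receptor expression in receiver),
gated at ≥ 10% detection in both populations. The selection logic around it
is: LR rows nonzero in ≥ 30% of samples; views with ≥ 20 interactions
(measured in the view's median sample; the cutoff and its interpretation
are configurable), ≥ 20 LR pairs and ≥ 100 covered samples; zero-fill;
restriction to dependency-network edges; and Pearson r > 0.3, p < 0.05
(strict) against the program score.

## Dependency networks

One ridge model per target cell type, penalty chosen per target by
generalized cross-validation over {10⁻², 10⁻¹, 1, 10, 10²}; CV R² is the
mean held-out R² over 5 shuffled folds (fold assignment seeded; samples are
sorted by index first so row order is irrelevant); β comes from a full-data
refit at the chosen penalty. Edge classes: shared when signs disagree or
|β_SLE − β_HC| < 0.1 (the boundary |Δ| = 0.1 is classified; a float-equality
guard handles representation error), otherwise enriched in the condition
with the larger β. Note that the opposite-sign rule zeroes any pair whose
weaker-condition coefficient is noise around zero, so a condition-specific
dependency is only reliably detected when the baseline coupling has a
consistent sign — the synthetic scenario therefore plants a weak positive
control-side coupling that strengthens in cases.

## Archetypes

Archetypal analysis minimizes ‖X − S·A‖² with S rows on the probability
simplex and A = B·X, B rows on the simplex (Cutler-Breiman). The S-step is
exact per cell (penalty-augmented NNLS); the B-step moves each archetype
toward its weighted residual target with Frank-Wolfe steps inside the data's
convex hull, accepting only updates that lower the objective — so the RSS
history is monotone by construction. Initialization is greedy
furthest-point. Model selection scans k and reports the RSS elbow (maximum
second difference); the RBF cell-weight length scale is half the median
centroid-to-archetype distance; weights are deliberately not normalized
across archetypes (the profile step normalizes instead). Bootstrap
stability is the mean best-match (Hungarian) cosine agreement with the
reference fit over resamples.

Patient means are averaged in embedding space (distances are taken there),
projected onto the archetype hull by simplex least squares, and per
archetype the program score is regressed on hull distance with HC3 robust
errors; BH (default) or Bonferroni across archetypes; optional permutation
p-values (plain score permutation, or Freedman-Lane when covariates are
included). Classes: SLE for negative slope at FDR < 0.05, HC for positive.

## Longitudinal flare risk

Bulk visits are z-scored to healthy-control gene statistics. "Three months"
is operationalized as 91 days (182 for six), remission as SLEDAI < 3 (for
integer SLEDAI this coincides with the ≤ 2 convention), and a flare as a
≥ 4-point SLEDAI rise at the first subsequent visit relative to the index
visit. Long-term remission additionally requires last recorded SLEDAI < 2
and > 90 days cumulative follow-up at the index visit. Pre-flare activity
differences use Welch's t with Holm correction. Cox models are fitted by
lifelines (Breslow ties, Newton precision 10⁻⁹, Wald CIs, Harrell C-index),
with likelihood-ratio tests against nested models; a brute-force partial-
likelihood optimization on a tiny instance serves as the independent oracle
in tests.

## Spatial analysis

The spatial weight matrix is binary 6-NN (ties broken toward lower spot
index; rows are not normalized — the n/S0 factor in Moran's I handles
scale). Bivariate Moran's I reduces exactly to univariate I when x = y.
Permutation p-values use the Davison-Hinkley form (1 + exceedances)/(101),
two-tailed via |I| exceedance by default (twice-the-smaller-tail is
available). Evidence is Fisher-combined across slides (χ², 2k df), BH
corrected, and gated on |mean I| ≥ 0.10. For neighbourhood modelling,
compositions below 0.05 are zeroed, CLR uses a 10⁻³¹ pseudocount, the
paraview radius is twice the nearest-neighbour spacing (mode of per-spot
minimum distances) with a Gaussian kernel of bandwidth r/2, and view
contributions are held-out R² gains of adding each view, with a random
forest (pluggable) base learner.

## Synthetic study conditions

The default cohort is 3 groups × 20 samples (half cases), 5 cell types ×
300 genes, with Poisson counts around an exponentiated linear predictor
(baseline mean counts 50-500, matching pseudobulk depth over thousands of
cells; log-normal noise SD 0.3). Two programs are planted: a multicellular
factor loading on 25% of genes in every cell type with the case scores
shifted +1.5 SD, and a factor restricted to classical monocytes. Loading SD
0.8 makes a loaded gene's variance ~40-60% program-driven, i.e. clearly
detectable programs of the kind the analysis targets; SLEDAI is a clipped
0-19 integer coupled to the multicellular score in cases. Single cells are
Dirichlet mixtures of k archetypes (coordinate-axis vertices, scale 4,
Gaussian noise SD 0.5), with per-patient concentration tilted toward
archetype 1 by exp(coupling × program score). Visits use gaps of 55-85
days, a base flare hazard of 0.0025/day scaled by exp(β × activity), with
the patient seen on the flare day (SLEDAI jump ≥ 4) when the flare precedes
the scheduled visit. Spatial slides are lattices with disk "glomerular"
niches where, on case slides only, immune abundance and the IFN program are
co-elevated.

These generators reproduce the *statistical structure* the pipeline
consumes — not the biology: gene symbols are synthetic, there are no
doublets, no ambient RNA, no batch effects beyond group score offsets, no
spatial anisotropy, and noise is homoscedastic. Passing tests therefore
demonstrate correctness and calibration of the statistical machinery under
the planted model, not performance on any real cohort.

## Problem sizes and numerics

Default analysis sizes (60 samples, ≤ 3,600 cells per archetype fit,
300 patients for Cox recovery, 18 × 18 spot lattices, 100 permutations,
5 CV folds) were chosen as the smallest sizes at which each stage's
statistical behaviour is stable; all are parameters. Numerical tie-breaks
and tolerances: NNLS penalty weight 10⁵ with post-hoc renormalization
(simplex sum holds to ~10⁻¹⁰), archetype convergence at relative RSS
improvement ≤ 10⁻⁷, ULM t capped at 10⁶, sign(0) treated as positive in
edge classification, kNN ties broken by stable sort order.
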