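# mcprogram

Multicellular immune-program analysis for systemic lupus erythematosus (SLE),
from blood single-cell cohorts to kidney tissue: a reusable, tested Python
implementation of the patient-map pipeline — pseudobulk factor modelling,
cell-type dependency networks, archetypal cell-state analysis, flare-risk
survival modelling and spatial co-localization — exercised end to end on
synthetic cohorts with planted, recoverable ground truth.

## Who this is for

Computational immunologists and methodologists who want to (a) run the
multicellular-program analysis on their own pseudobulk/single-cell/bulk/
spatial data, or (b) study the statistical behaviour of each stage under
controlled conditions, since every input the pipeline consumes can be
simulated with known parameters (`mcprogram.synthgen`).

## The model

**Multicellular programs.** Per-cell-type pseudobulk views
X⁽ᶜᵗ⁾ (samples × genes) are jointly factorized with shared gene loadings
w⁽ᶜᵗ⁾ (genes × factors) and group-wise sample scores z (samples × factors):

    X⁽ᶜᵗ⁾ ≈ z · w⁽ᶜᵗ⁾ᵀ     (genes centred per group, views scaled
                             to unit total variance)

The fit is a deterministic truncated SVD of the column-concatenated
standardized views, with per-sample scores re-estimated by least squares on
the views each sample is observed in, and factors below 0.1% incremental
explained variance dropped. A factor is a *program* when its variance
explained R²(group, cell type, factor) exceeds 10% somewhere; a
*multicellular* program does so in several cell types.

**Downstream statistics.**

- *Activity scoring (ULM):* a sample profile is regressed on a signed gene
  weight vector; the slope t-statistic, t = r·√(m−2)/√(1−r²), is the
  activity.
- *Dependency networks:* ridge regressions predict each cell type's program
  activity from the others; 5-fold CV R² measures coordination, the β
  matrix gives directed edges, and condition-specific edges satisfy
  |β_SLE − β_HC| ≥ 0.1 with consistent signs.
- *Archetypes:* cells are convex mixtures of extreme states, ‖X − S·A‖²
  minimized with S rows on the simplex and A = B·X; patient means are
  projected onto the archetype hull and distances regressed on program
  scores (OLS, HC3 errors) to classify archetypes as SLE- or HC-associated.
- *Flare risk:* remission visits (SLEDAI < 3) are labelled by whether a
  ≥ 4-point SLEDAI rise follows within 91 days; Cox proportional hazards
  (Breslow ties) relate program activity to time-to-flare.
- *Spatial co-localization:* bivariate global Moran's I between program
  scores and cell-type abundances under a binary 6-nearest-neighbour weight
  matrix, permutation-tested (floor p = 1/101) and Fisher-combined across
  slides.

## Worked example

```python
from mcprogram.pipeline import run_pipeline

res = run_pipeline(seed=1)
print(res["selected_programs"])        # ['Factor1', 'Factor2']
print(round(res["mc_recovery_r"], 3))  # 0.999
print(res["cox"].summary[["beta", "HR", "p"]].round(3))
```

On seed 1 this selects the two planted programs; the fitted multicellular
factor correlates with the planted score at |r| = 0.999; the Cox model on
231 labelled remission visits estimates a flare log-hazard of 0.78
(HR 2.19, C-index 0.71) for a planted log-hazard of 1.0; and the planted
immune/IFN co-localization yields mean Moran's I = 0.25 on case slides
versus 0.00 on control slides. The same run is available from a shell:

```bash
mcprogram run --seed 1 --out results/run1
mcprogram simulate pseudobulk --seed 1 --out data/sim   # inputs only
```

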