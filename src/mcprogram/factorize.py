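"""Multi-group, multi-view factor model for pseudobulk cohorts.

The model learns a shared set of gene loadings per cell type ("views") while
sample scores are estimated within groups (processing batches / sub-cohorts),
mirroring the multi-group factor-analysis contract: views scaled to unit total
variance, genes centred per group, Gaussian likelihood. The fit itself is a
deterministic truncated SVD of the column-concatenated standardized views,
with scores re-estimated per sample by least squares against the shared
loadings (samples missing from a view are excluded from that view's fit, not
zero-imputed). Factors contributing less than ``drop_r2`` incremental
explained variance are dropped.

Downstream helpers compute the per-(group, cell type, factor) variance
explained table, select disease-relevant programs (R² > 10% somewhere), and
associate factor scores with clinical covariates (Type II ANOVA F, η²,
directional t, Bonferroni across factors per covariate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class FactorModel:
    """Shared loadings per cell type, group-wise sample scores, and R² table."""

    loadings: dict[str, pd.DataFrame]          # celltype -> gene x factor
    scores: dict[str, pd.DataFrame]            # group -> sample x factor
    r2: pd.DataFrame                           # long: group, celltype, factor, r2
    view_scale: dict[str, float]
    n_factors: int
    gene_center: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)
    gene_scale: dict[str, pd.Series] = field(default_factory=dict, repr=False)
    groups: pd.Series | None = field(default=None, repr=False)

    @property
    def factor_names(self) -> list[str]:
        return list(next(iter(self.loadings.values())).columns)

    @property
    def pooled_scores(self) -> pd.DataFrame:
        """Sample x factor scores pooled across groups."""
        return pd.concat(self.scores.values(), axis=0)


def _standardize_view(
    view: pd.DataFrame, groups: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, float]:
    """Centre genes per group, scale genes to unit SD, scale view to unit
    total variance. Returns (standardized, per-group means, gene SDs, view scale)."""
    g = groups.reindex(view.index)
    centers = view.groupby(g, observed=True).mean()
    centred = view - centers.loc[g].to_numpy()
    sd = centred.std(axis=0, ddof=1).replace(0.0, np.nan)
    z = centred / sd
    z = z.loc[:, sd.notna()]
    total_var = float(z.shape[1])  # unit variance per gene
    scale = 1.0 / np.sqrt(total_var) if total_var > 0 else 1.0
    return z * scale, centers, sd, scale


def fit_factors(
    views: dict[str, pd.DataFrame],
    groups: pd.Series,
    n_factors: int = 20,
    drop_r2: float = 0.001,
) -> FactorModel:
    """Fit the shared-loadings factor model on standardized pseudobulk views."""
    samples = groups.index
    std_views: dict[str, pd.DataFrame] = {}
    centers: dict[str, pd.DataFrame] = {}
    scales: dict[str, pd.Series] = {}
    vscale: dict[str, float] = {}
    for ct, view in views.items():
        g = groups.reindex(view.index)
        counts = g.value_counts()
        small = counts[counts < 2].index
        if len(small):
            warnings.warn(f"view {ct!r}: groups {list(small)} have <2 samples "
                          "and are excluded from this view", stacklevel=2)
            view = view.loc[~g.isin(small)]
        z, c, sd, sc = _standardize_view(view, groups)
        std_views[ct], centers[ct], scales[ct], vscale[ct] = z, c, sd, sc

    # Column-concatenate on the union of samples; rows a view does not observe
    # are mean-imputed (zero on the standardized scale) for the SVD only.
    blocks = [std_views[ct].reindex(samples).fillna(0.0) for ct in std_views]
    concat = pd.concat(blocks, axis=1)
    k = min(n_factors, min(concat.shape) - 1) if min(concat.shape) > 1 else 1
    u, s, vt = np.linalg.svd(concat.to_numpy(), full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]

    col_ct = np.concatenate([[ct] * std_views[ct].shape[1] for ct in std_views])
    names = [f"Factor{j + 1}" for j in range(k)]
    w_all = pd.DataFrame(vt.T, index=concat.columns, columns=names)

    # Per-sample scores by least squares on observed views only.
    z_scores = pd.DataFrame(0.0, index=samples, columns=names)
    observed = {ct: set(std_views[ct].index) for ct in std_views}
    for smp in samples:
        mask = np.concatenate([
            np.full(std_views[ct].shape[1], smp in observed[ct])
            for ct in std_views])
        x = concat.loc[smp].to_numpy()[mask]
        w = w_all.to_numpy()[mask]
        z_scores.loc[smp] = np.linalg.lstsq(w, x, rcond=None)[0]

    # Drop factors below the incremental explained-variance floor, measured as
    # each factor's share of the total standardized sum of squares.
    ss_tot = float((concat.to_numpy() ** 2).sum())
    keep = []
    for f in names:
        recon = np.outer(z_scores[f], w_all[f])
        ss_exp = float((concat.to_numpy() * recon).sum() * 2 - (recon ** 2).sum())
        if ss_exp / ss_tot >= drop_r2:
            keep.append(f)
    if not keep:
        keep = names[:1]
    w_all, z_scores, names = w_all[keep], z_scores[keep], keep
    s = s[[int(f.removeprefix("Factor")) - 1 for f in keep]]

    # Rescale to interpretable units: scores have ~unit variance; loadings are
    # on the per-gene standardized scale, so |w| ~ sqrt(per-gene factor R²).
    n_total = len(samples)
    for j, f in enumerate(names):
        w_all[f] *= s[j] / np.sqrt(n_total)
        z_scores[f] *= np.sqrt(n_total) / s[j]

    # Canonical sign: largest-|loading| gene positive per factor.
    for f in names:
        top = np.abs(w_all[f].to_numpy()).argmax()
        if w_all[f].iloc[top] < 0:
            w_all[f] *= -1.0
            z_scores[f] *= -1.0

    loadings = {
        ct: (w_all.loc[col_ct == ct].set_axis(std_views[ct].columns)
             * np.sqrt(std_views[ct].shape[1]))
        for ct in std_views}
    scores = {g: z_scores.loc[groups[groups == g].index]
              for g in pd.unique(groups)}
    model = FactorModel(loadings=loadings, scores=scores, r2=pd.DataFrame(),
                        view_scale=vscale, n_factors=len(names),
                        gene_center=centers, gene_scale=scales, groups=groups)
    model.r2 = variance_explained(model, views)
    return model


def from_external(
    loadings: dict[str, pd.DataFrame],
    scores: dict[str, pd.DataFrame],
    views: dict[str, pd.DataFrame] | None = None,
    groups: pd.Series | None = None,
) -> FactorModel:
    """Adapter: wrap an externally fitted factor model (loadings/scores import).

    When standardized views and groups are supplied, the R² table is computed
    on the same standardized scale as :func:`fit_factors`.
    """
    n = next(iter(loadings.values())).shape[1]
    model = FactorModel(loadings=loadings, scores=scores, r2=pd.DataFrame(),
                        view_scale={ct: 1.0 for ct in loadings}, n_factors=n,
                        groups=groups)
    if views is not None and groups is not None:
        for ct, view in views.items():
            _, c, sd, _ = _standardize_view(view, groups)
            model.gene_center[ct], model.gene_scale[ct] = c, sd
        model.r2 = variance_explained(model, views)
    return model


def variance_explained(
    model: FactorModel, views: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-(group, celltype, factor) R² of the rank-1 reconstruction.

    Computed on the fit's standardized scale, clipped at 0; zero-variance
    views are reported missing (NaN).
    """
    rows = []
    groups = model.groups
    z_all = model.pooled_scores
    for ct, w in model.loadings.items():
        center, sd = model.gene_center[ct], model.gene_scale[ct]
        view = views[ct]
        g = groups.reindex(view.index)
        g = g[g.isin(center.index)]
        view = view.loc[g.index]
        z = ((view - center.loc[g].to_numpy()) / sd)[w.index]
        for grp in pd.unique(g):
            sub = z.loc[g == grp].to_numpy()
            ss_tot = float((sub ** 2).sum())
            zz = z_all.reindex(z.loc[g == grp].index)
            for f in w.columns:
                if ss_tot == 0 or not np.isfinite(ss_tot):
                    rows.append((grp, ct, f, np.nan))
                    continue
                recon = np.outer(zz[f].to_numpy(), w[f].to_numpy())
                r2 = 1.0 - float(((sub - recon) ** 2).sum()) / ss_tot
                rows.append((grp, ct, f, max(r2, 0.0)))
    return pd.DataFrame(rows, columns=["group", "celltype", "factor", "r2"])


def select_programs(r2: pd.DataFrame, threshold: float = 0.10) -> list[str]:
    """Factors explaining strictly more than ``threshold`` of variance in at
    least one (cell type, group) view."""
    if r2.empty:
        return []
    hit = r2[r2["r2"] > threshold]
    order = list(pd.unique(r2["factor"]))
    return [f for f in order if f in set(hit["factor"])]


@dataclass
class CovariateAssociation:
    """Factor-covariate association table plus per-covariate multivariate R²."""

    table: pd.DataFrame       # factor, covariate, F, p, eta2, t, p_adjusted
    multivariate_r2: pd.Series


def _encode(cov: pd.Series) -> pd.DataFrame:
    """Numeric covariates pass through; categoricals are one-hot encoded."""
    if pd.api.types.is_numeric_dtype(cov) and not isinstance(
            cov.dtype, pd.CategoricalDtype):
        return cov.astype(float).to_frame()
    dummies = pd.get_dummies(cov.astype("category"), drop_first=True)
    return dummies.astype(float)


def associate_covariates(
    scores: pd.DataFrame, covariates: pd.DataFrame
) -> CovariateAssociation:
    """Associate factor scores with clinical/demographic covariates.

    Per covariate, a multivariate linear model (covariate ~ all factor scores)
    yields a global R². Per (factor, covariate), a univariate model
    (score ~ covariate) yields a Type II ANOVA F-test p-value, η² effect size,
    and the slope t-statistic for direction; p-values are Bonferroni-adjusted
    across factors within each covariate.
    """
    scores = scores.loc[covariates.index.intersection(scores.index)]
    covariates = covariates.loc[scores.index]
    factor_cols = list(scores.columns)
    rows, mv = [], {}
    for cov_name in covariates.columns:
        cov = covariates[cov_name].dropna()
        enc = _encode(cov)
        if enc.shape[1] == 0 or (enc.nunique() <= 1).all():
            warnings.warn(f"covariate {cov_name!r} is constant; skipped",
                          stacklevel=2)
            continue
        x = sm.add_constant(scores.loc[cov.index].to_numpy())
        sse = sst = 0.0
        for col in enc.columns:
            y = enc[col].to_numpy()
            fit = sm.OLS(y, x).fit()
            sse += float(fit.ssr)
            sst += float(((y - y.mean()) ** 2).sum())
        mv[cov_name] = 1.0 - sse / sst if sst > 0 else np.nan

        df = pd.DataFrame({"cov": cov})
        cat = not pd.api.types.is_numeric_dtype(cov)
        for f in factor_cols:
            df["y"] = scores.loc[cov.index, f]
            formula = "y ~ C(cov)" if cat else "y ~ cov"
            fit = smf.ols(formula, data=df).fit()
            an = sm.stats.anova_lm(fit, typ=2)
            term = an.index[0]
            ss_cov, ss_res = an.loc[term, "sum_sq"], an.loc["Residual", "sum_sq"]
            eta2 = ss_cov / (ss_cov + ss_res) if ss_cov + ss_res > 0 else np.nan
            tstat = fit.tvalues.iloc[1] if len(fit.tvalues) == 2 else np.nan
            rows.append((f, cov_name, float(an.loc[term, "F"]),
                         float(an.loc[term, "PR(>F)"]), float(eta2),
                         float(tstat)))
    table = pd.DataFrame(
        rows, columns=["factor", "covariate", "F", "p", "eta2", "t"])
    m = len(factor_cols)
    table["p_adjusted"] = np.minimum(table["p"] * m, 1.0)
    return CovariateAssociation(table=table,
                                multivariate_r2=pd.Series(mv, name="r2"))
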