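"""Spatial co-localization of programs and cell types on tissue slides.

Each slide carries spot coordinates, spot-level features (program enrichment
scores, deconvolved cell-type abundances, compositions) and glomerular
annotations. Co-localization between a program score and a cell-type
abundance is the bivariate global Moran's I under a binary k-nearest-neighbour
weight matrix, with a two-tailed permutation p (Davison-Hinkley form, floor
1/(n_perms+1)); evidence is combined across slides per condition with Fisher's
method and gated on both FDR and effect size. The module also builds the
intra/para views for neighbourhood modelling of glomerular composition with a
pluggable (random forest) learner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SpatialSlide:
    """Spot coordinates, feature matrices, annotations and condition."""

    coords: pd.DataFrame                    # spot x (x, y)
    features: dict[str, pd.DataFrame]       # name -> spot x feature
    annotations: pd.DataFrame               # spot flags (glomerular, ...)
    condition: str                          # {"case", "control"}
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        if self.coords.index.duplicated().any():
            raise ValueError("duplicate spot ids")
        if not np.isfinite(self.coords.to_numpy(float)).all():
            raise ValueError("non-finite coordinates")


@dataclass
class SpatialWeights:
    """Binary kNN weight matrix; each row has exactly k ones, w_ii = 0."""

    w: np.ndarray
    k: int

    @property
    def s0(self) -> float:
        return float(self.w.sum())


def knn_weights(coords: pd.DataFrame | np.ndarray, k: int = 6) -> SpatialWeights:
    """Binary k-nearest-neighbour spatial weights (Euclidean), ties broken by
    lowest spot index (stable sort on distances)."""
    x = coords.to_numpy(float) if isinstance(coords, pd.DataFrame) else \
        np.asarray(coords, float)
    n = x.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} spots, got {n}")
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    w = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(d[i], kind="stable")
        w[i, order[:k]] = 1.0
    return SpatialWeights(w=w, k=k)


def bivariate_moran(x: np.ndarray, y: np.ndarray, weights: SpatialWeights
                    ) -> float:
    """Bivariate global Moran's I of x against spatially lagged y.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(y_j - ybar)
        / sqrt(sum_i (x_i - xbar)^2 * sum_i (y_i - ybar)^2)

    With x = y this reduces exactly to the univariate global Moran's I.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    zx, zy = x - x.mean(), y - y.mean()
    sx2, sy2 = float(zx @ zx), float(zy @ zy)
    if sx2 == 0 or sy2 == 0:
        raise ValueError("bivariate_moran: zero-variance input")
    n = len(x)
    num = float(zx @ weights.w @ zy)
    return (n / weights.s0) * num / np.sqrt(sx2 * sy2)


def moran_permutation_p(
    x: np.ndarray, y: np.ndarray, weights: SpatialWeights,
    n_perms: int = 100, seed: int = 0, two_tailed: str = "abs",
) -> tuple[float, float]:
    """Permutation p-value for bivariate Moran's I.

    y is shuffled over spots; the Davison-Hinkley small-sample form
    ``p = (1 + #{|I*| >= |I_obs|}) / (n_perms + 1)`` gives a minimum
    achievable p of 1/(n_perms + 1). ``two_tailed="2min"`` uses twice the
    smaller tail instead of |I| exceedance.

    Returns (I_obs, p).
    """
    rng = np.random.default_rng(seed)
    i_obs = bivariate_moran(x, y, weights)
    y = np.asarray(y, float)
    zx = np.asarray(x, float) - np.mean(x)
    lagged = zx @ weights.w      # precompute row-sums against permuted y
    n = len(y)
    i_perm = np.empty(n_perms)
    sx2 = float(zx @ zx)
    for b in range(n_perms):
        yp = rng.permutation(y)
        zy = yp - yp.mean()
        i_perm[b] = (n / weights.s0) * float(lagged @ zy) / \
            np.sqrt(sx2 * float(zy @ zy))
    if two_tailed == "abs":
        p = (1 + int((np.abs(i_perm) >= abs(i_obs)).sum())) / (n_perms + 1)
    else:
        hi = (1 + int((i_perm >= i_obs).sum())) / (n_perms + 1)
        lo = (1 + int((i_perm <= i_obs).sum())) / (n_perms + 1)
        p = min(1.0, 2.0 * min(hi, lo))
    return i_obs, p


def aggregate_colocalization(
    per_slide: pd.DataFrame, alpha: float = 0.05, min_abs_i: float = 0.10
) -> pd.DataFrame:
    """Combine per-slide Moran results across slides within condition.

    ``per_slide`` has columns (celltype, program, condition, slide, I, p).
    Per (celltype, program, condition): mean I over slides and Fisher's
    combined p (chi-square with 2k df, k slides); BH correction across all
    combinations; significant iff fdr < alpha and |mean I| >= ``min_abs_i``.
    """
    rows = []
    for (ct, prog, cond), sub in per_slide.groupby(
            ["celltype", "program", "condition"], sort=True):
        k = len(sub)
        chi2 = -2.0 * np.log(sub["p"]).sum()
        p_comb = float(stats.chi2.sf(chi2, df=2 * k))
        rows.append((ct, prog, cond, float(sub["I"].mean()), k, p_comb))
    out = pd.DataFrame(rows, columns=["celltype", "program", "condition",
                                      "mean_I", "n_slides", "p_combined"])
    from statsmodels.stats.multitest import multipletests
    if len(out):
        out["fdr"] = multipletests(out["p_combined"], method="fdr_bh")[1]
        out["significant"] = (out["fdr"] < alpha) & \
            (out["mean_I"].abs() >= min_abs_i)
    else:
        out["fdr"], out["significant"] = [], []
    return out


def colocalize_slides(
    slides: list[SpatialSlide],
    programs: list[str] | None = None,
    celltypes: list[str] | None = None,
    k: int = 6,
    n_perms: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-slide bivariate Moran's I of every (program, cell type) pair."""
    rows = []
    for si, slide in enumerate(slides):
        wts = knn_weights(slide.coords, k=k)
        prog_mat = slide.features["program_scores"]
        ab_mat = slide.features["abundance"]
        for prog in programs or prog_mat.columns:
            for ct in celltypes or ab_mat.columns:
                i_obs, p = moran_permutation_p(
                    prog_mat[prog].to_numpy(), ab_mat[ct].to_numpy(),
                    wts, n_perms=n_perms, seed=seed + 7919 * si)
                rows.append((ct, prog, slide.condition, slide.slide_id,
                             i_obs, p))
    return pd.DataFrame(rows, columns=["celltype", "program", "condition",
                                       "slide", "I", "p"])


def _nn_spacing(coords: np.ndarray) -> float:
    """Nearest-neighbour spacing: mode of per-spot minimum distances."""
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    mins = np.round(d.min(axis=1), 9)
    vals, counts = np.unique(mins, return_counts=True)
    return float(vals[np.argmax(counts)])


def build_views(
    compositions: pd.DataFrame,
    coords: pd.DataFrame,
    glomerular: pd.Series,
    zero_thresh: float = 0.05,
    pseudocount: float = 1e-31,
    l: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Intraview (CLR compositions), paraview (neighbourhood means), and mask.

    Compositions below ``zero_thresh`` are zeroed and zero-variance cell types
    dropped before a pseudocount-CLR transform. The paraview feature of a spot
    is the distance-weighted (Gaussian kernel, bandwidth r/2) mean of its
    neighbours within radius ``r = l * nearest-neighbour spacing``, self
    excluded; spots with no neighbour in r get a zero row. The mask flags
    glomerular spots and their neighbours within two spot spacings.
    """
    if not glomerular.any():
        raise ValueError("no glomerular annotation; mask would be empty")
    comp = compositions.copy()
    comp[comp < zero_thresh] = 0.0
    keep = comp.columns[comp.std(axis=0, ddof=0) > 0]
    comp = comp[keep]
    logp = np.log(comp.to_numpy(float) + pseudocount)
    intra = pd.DataFrame(logp - logp.mean(axis=1, keepdims=True),
                         index=comp.index, columns=comp.columns)

    xy = coords.to_numpy(float)
    spacing = _nn_spacing(xy)
    r = l * spacing
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    kern = np.exp(-d ** 2 / (2.0 * (r / 2.0) ** 2))
    kern[d > r] = 0.0
    row_sums = kern.sum(axis=1)
    isolated = row_sums == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} spot(s) have no neighbour "
                      f"within r={r:.3g}; paraview rows set to 0",
                      stacklevel=2)
        row_sums[isolated] = 1.0
    para_mat = (kern / row_sums[:, None]) @ intra.to_numpy()
    para = pd.DataFrame(para_mat, index=intra.index,
                        columns=[f"para_{c}" for c in intra.columns])

    glom = glomerular.reindex(coords.index).fillna(False).to_numpy(bool)
    near = (d[:, glom] <= 2.0 * spacing).any(axis=1)
    mask = pd.Series(glom | near, index=coords.index, name="mask")
    return intra, para, mask


def fit_multiview(
    intra: pd.DataFrame,
    para: pd.DataFrame,
    target: str,
    mask: pd.Series | None = None,
    learner: str = "random_forest",
    seed: int = 0,
) -> dict[str, object]:
    """Predict a cell type's intraview signal from both views.

    Fits the chosen learner (random forest by default; any scikit-learn
    regressor name in the registry) on intraview predictors (target excluded)
    plus paraview features, using 5-fold out-of-sample predictions for R².
    View contributions are R²-gain attributions: the drop in held-out R² when
    a view is removed, clipped at 0.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.linear_model import Ridge
    from sklearn.model_selection import KFold, cross_val_predict

    registry = {
        "random_forest": lambda: RandomForestRegressor(
            n_estimators=100, random_state=seed),
        "ridge": lambda: Ridge(alpha=1.0),
    }
    if learner not in registry:
        raise ValueError(f"unknown learner {learner!r}")
    if mask is not None:
        intra, para = intra.loc[mask], para.loc[mask]
    intra = intra.sort_index()
    para = para.reindex(intra.index)
    if intra.shape[0] < 20:
        raise ValueError("need >= 20 masked spots")
    y = intra[target].to_numpy()
    x_intra = intra.drop(columns=[target])
    x_para = para

    def _cv_r2(x: pd.DataFrame) -> float:
        cv = KFold(5, shuffle=True, random_state=seed)
        pred = cross_val_predict(registry[learner](), x.to_numpy(), y, cv=cv)
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    both = pd.concat([x_intra, x_para], axis=1)
    r2_both = _cv_r2(both)
    r2_intra_only = _cv_r2(x_intra)
    r2_para_only = _cv_r2(x_para)
    contrib = {
        "intra": max(r2_both - max(r2_para_only, 0.0), 0.0),
        "para": max(r2_both - max(r2_intra_only, 0.0), 0.0),
    }

    model = registry[learner]().fit(both.to_numpy(), y)
    if hasattr(model, "feature_importances_"):
        imp = pd.Series(model.feature_importances_, index=both.columns)
    else:
        imp = pd.Series(np.abs(model.coef_), index=both.columns)
    return {
        "target": target,
        "r2": {"both": r2_both, "intra_only": r2_intra_only,
               "para_only": r2_para_only},
        "contributions": contrib,
        "importances": {"intra": imp[x_intra.columns],
                        "para": imp[x_para.columns]},
    }


def glomerular_enrichment(
    scores: pd.DataFrame,
    glomerular: pd.Series,
    immune_composition: pd.Series,
    condition: pd.Series,
) -> pd.DataFrame:
    """Per-program OLS t-test of glomerular spot enrichment in cases.

    Restricted to glomerular spots with immune composition > 0; positive t
    means higher enrichment in case tissue. Also returns visualization-ready
    scores with negative values clamped at zero.
    """
    import statsmodels.api as sm

    mask = glomerular.astype(bool) & (immune_composition > 0)
    sub = scores.loc[mask]
    cond = condition.loc[mask]
    is_case = (cond == "case").astype(float).to_numpy()
    if is_case.min() == is_case.max():
        raise ValueError("both conditions must be present among masked spots")
    rows = []
    x = sm.add_constant(is_case)
    for prog in scores.columns:
        fit = sm.OLS(sub[prog].to_numpy(), x).fit()
        rows.append((prog, float(fit.tvalues[1]), float(fit.pvalues[1])))
    out = pd.DataFrame(rows, columns=["program", "t", "p"])
    out.attrs["viz_scores"] = scores.clip(lower=0.0)
    return out
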