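"""Program activity scoring, coordinated signatures, bulk mapping, and
ligand-receptor communication filtering.

Activity scoring uses the univariate linear model (ULM): a sample's expression
profile is regressed on a signed gene-weight vector (weight 0 for genes
outside the set), and the slope t-statistic is the activity score. The same
primitive scores factor loadings per cell type, cytokine response signatures,
and coordinated gene signatures on bulk or spot profiles.

The cell-cell communication (CCC) part scores ligand-receptor quadruplets
(source cell type - ligand - receptor - target cell type) per sample with a
geometric-mean expression magnitude gated on detection fraction, applies the
view filters (prevalence, view size, sample coverage, zero-fill, restriction
to dependency-network edges), and selects program-associated interactions by
Pearson correlation with the program score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Cap on the ULM t-statistic when the profile is perfectly collinear with
#: the weights (|r| -> 1).
T_CAP = 1e6


def score_ulm(profile: pd.Series, gene_set: pd.Series) -> tuple[float, float]:
    """ULM activity of one profile against one weighted gene set.

    The gene universe is all genes in the profile; set members carry their
    weights, all other genes weight 0. Returns the slope t-statistic and its
    two-sided p-value (t distribution, m-2 df); equivalently
    ``t = r * sqrt(m - 2) / sqrt(1 - r^2)`` with r the Pearson correlation
    between profile and weight vector over the m universe genes.
    """
    w = gene_set.reindex(profile.index).fillna(0.0)
    matched = gene_set.index.intersection(profile.index)
    if len(matched) < 3:
        raise ValueError("score_ulm needs >= 3 set genes in the profile")
    m = len(profile)
    x, y = w.to_numpy(float), profile.to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("score_ulm: zero-variance weights or profile")
    r = float(np.corrcoef(x, y)[0, 1])
    denom = 1.0 - r * r
    if denom <= 0:
        t = np.sign(r) * T_CAP
    else:
        t = r * np.sqrt(m - 2) / np.sqrt(denom)
        t = float(np.clip(t, -T_CAP, T_CAP))
    p = float(2.0 * stats.t.sf(abs(t), df=m - 2))
    return t, max(p, np.finfo(float).tiny)


@dataclass
class ActivityMatrix:
    """Sample x source ULM t-statistics and p-values."""

    scores: pd.DataFrame
    pvalues: pd.DataFrame


def score_activities(
    matrix: pd.DataFrame,
    gene_sets: dict[str, pd.Series],
    zscore: bool = False,
) -> ActivityMatrix:
    """ULM-score every sample (row) against every weighted gene set.

    Vectorized over samples and sets; with ``zscore=True`` each activity
    column is standardized across samples (the network-stage convention).
    """
    genes = matrix.columns
    m = len(genes)
    kept, w_cols = [], []
    for name, gs in gene_sets.items():
        if len(gs.index.intersection(genes)) < 3:
            warnings.warn(f"gene set {name!r}: <3 genes matched; dropped",
                          stacklevel=2)
            continue
        kept.append(name)
        w_cols.append(gs.reindex(genes).fillna(0.0).to_numpy(float))
    if not kept:
        empty = pd.DataFrame(index=matrix.index)
        return ActivityMatrix(scores=empty, pvalues=empty.copy())
    w = np.column_stack(w_cols)                      # genes x sets
    x = matrix.to_numpy(float)                       # samples x genes
    xc = x - x.mean(axis=1, keepdims=True)
    wc = w - w.mean(axis=0, keepdims=True)
    num = xc @ wc
    denom = np.sqrt((xc ** 2).sum(axis=1))[:, None] * \
        np.sqrt((wc ** 2).sum(axis=0))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(m - 2) / np.sqrt(np.clip(1.0 - r * r,
                                                 np.finfo(float).tiny, None))
    t = np.clip(np.nan_to_num(t), -T_CAP, T_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
    scores = pd.DataFrame(t, index=matrix.index, columns=kept)
    pvals = pd.DataFrame(np.maximum(p, np.finfo(float).tiny),
                         index=matrix.index, columns=kept)
    if zscore:
        scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=0)
    return ActivityMatrix(scores=scores, pvalues=pvals)


def factor_gene_sets(
    loadings: dict[str, pd.DataFrame], factor: str
) -> dict[str, pd.Series]:
    """One weighted gene set per cell type from a factor's loadings."""
    return {ct: w[factor].rename(f"{factor}|{ct}")
            for ct, w in loadings.items()}


def coordinated_signature(
    model,
    cv_r2: pd.Series,
    factor: str,
    r2_coord: float = 0.8,
    var_thresh: float = 0.10,
    w_thresh: float = 0.5,
) -> pd.Series:
    """Summarize a program as a single weighted gene signature.

    Cell types are selected as the union of network-coordinated targets
    (cross-validated R² >= ``r2_coord``) and cell types where the factor
    explains more than ``var_thresh`` variance; if the explained variance is
    restricted to a single cell type, only that one is kept. Genes with
    |loading| >= ``w_thresh`` in at least one selected cell type are retained,
    weighted by the mean of their retained (above-threshold) loadings.
    """
    r2 = model.r2[model.r2["factor"] == factor]
    var_cts = sorted(set(r2[r2["r2"] > var_thresh]["celltype"]))
    if len(var_cts) == 1:
        selected = var_cts
    else:
        coord = [ct for ct, v in cv_r2.items() if v >= r2_coord]
        selected = sorted(set(coord) | set(var_cts))
    if not selected:
        raise ValueError(f"no cell types selected for {factor}")
    weights: dict[str, list[float]] = {}
    for ct in selected:
        w = model.loadings[ct][factor]
        for gene, val in w[w.abs() >= w_thresh].items():
            weights.setdefault(gene, []).append(float(val))
    if not weights:
        raise ValueError(f"no genes pass |w| >= {w_thresh} for {factor}")
    return pd.Series({g: float(np.mean(v)) for g, v in weights.items()},
                     name=factor).sort_index()


def map_programs_bulk(
    bulk_z: pd.DataFrame,
    model,
    factors: list[str] | None = None,
) -> pd.DataFrame:
    """Map factor activity onto bulk samples as an R²-weighted mean over
    cell types.

    Each (factor, cell type) loading set is ULM-scored per bulk sample; the
    per-factor score is the weighted mean across cell types with weight
    ``sum over groups of r2(group, ct, factor)``, normalized to sum 1.
    """
    factors = factors or model.factor_names
    out = {}
    for f in factors:
        sets = {ct: w[f] for ct, w in model.loadings.items()
                if len(w.index.intersection(bulk_z.columns)) >= 3
                and w[f].abs().sum() > 0}
        if not sets:
            raise ValueError(f"no loading genes of {f} present in bulk matrix")
        act = score_activities(bulk_z, sets)
        r2f = model.r2[model.r2["factor"] == f]
        wts = r2f.groupby("celltype")["r2"].sum().reindex(act.scores.columns)
        wts = wts.fillna(0.0)
        if wts.sum() <= 0:
            wts[:] = 1.0
        wts = wts / wts.sum()
        out[f] = act.scores.mul(wts, axis=1).sum(axis=1)
    return pd.DataFrame(out, index=bulk_z.index)


def score_ccc(
    mean_expr: dict[str, pd.DataFrame],
    detect_frac: dict[str, pd.DataFrame],
    lr_resource: pd.DataFrame,
    expr_prop: float = 0.1,
) -> pd.DataFrame:
    """Score ligand-receptor quadruplets per sample.

    ``mean_expr[ct]`` / ``detect_frac[ct]`` are sample x gene mean expression
    and cell-level detection fractions per cell type. For each
    (source, ligand, receptor, target) and sample, the score is
    ``sqrt(mean_expr[ligand, source] * mean_expr[receptor, target])`` when the
    detection fraction reaches ``expr_prop`` in both sender and receiver,
    else 0. Samples missing a cell type get NaN for that quadruplet.

    Returns a long-format frame indexed by (source, ligand, receptor, target)
    with one column per sample.
    """
    celltypes = list(mean_expr)
    samples = sorted(set().union(*[set(m.index) for m in mean_expr.values()]))
    rows, index = [], []
    for src in celltypes:
        for tgt in celltypes:
            for _, lr in lr_resource.iterrows():
                lig, rec = lr["ligand"], lr["receptor"]
                if (lig not in mean_expr[src].columns
                        or rec not in mean_expr[tgt].columns):
                    continue
                e_l = mean_expr[src][lig].reindex(samples)
                e_r = mean_expr[tgt][rec].reindex(samples)
                f_l = detect_frac[src][lig].reindex(samples)
                f_r = detect_frac[tgt][rec].reindex(samples)
                score = np.sqrt(e_l.clip(lower=0) * e_r.clip(lower=0))
                gate = (f_l >= expr_prop) & (f_r >= expr_prop)
                score = score.where(gate, 0.0)
                score[e_l.isna() | e_r.isna()] = np.nan
                rows.append(score.to_numpy())
                index.append((src, lig, rec, tgt))
    idx = pd.MultiIndex.from_tuples(index,
                                    names=["source", "ligand", "receptor",
                                           "target"])
    return pd.DataFrame(rows, index=idx, columns=samples)


def filter_ccc_views(
    table: pd.DataFrame,
    lr_prop: float = 0.3,
    min_inter: int = 20,
    min_lr: int = 20,
    min_samples: int = 100,
    net_edges: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Apply the CCC view filters.

    Keeps LR rows nonzero in >= ``lr_prop`` of samples; keeps (source, target)
    views with >= ``min_inter`` interactions in the view's median sample,
    >= ``min_lr`` LR pairs, and >= ``min_samples`` covered samples; missing
    values are then zero-filled; finally, views are restricted to
    sender-receiver pairs that are edges of the supplied dependency network.
    """
    if table.empty:
        warnings.warn("filter_ccc_views: empty input", stacklevel=2)
        return table
    nonzero_frac = (table.fillna(0.0) > 0).mean(axis=1)
    table = table[nonzero_frac >= lr_prop]

    keep_views = []
    for (src, tgt), sub in table.groupby(level=["source", "target"], sort=False):
        covered = sub.notna().any(axis=0).sum()
        n_lr = sub.shape[0]
        inter_per_sample = (sub.fillna(0.0) > 0).sum(axis=0)
        median_inter = float(inter_per_sample.median()) if len(sub) else 0.0
        if median_inter >= min_inter and n_lr >= min_lr and covered >= min_samples:
            keep_views.append((src, tgt))
    mask = [
        (s, t) in keep_views
        for s, t in zip(table.index.get_level_values("source"),
                        table.index.get_level_values("target"))]
    table = table[mask].fillna(0.0)

    if net_edges is not None:
        mask = [
            (s, t) in net_edges
            for s, t in zip(table.index.get_level_values("source"),
                            table.index.get_level_values("target"))]
        table = table[mask]
    if table.empty:
        warnings.warn("filter_ccc_views: no interactions survive filtering",
                      stacklevel=2)
    return table


def correlate_ccc_program(
    table: pd.DataFrame,
    program_scores: pd.Series,
    r_min: float = 0.3,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select program-associated LR interactions by Pearson correlation.

    Rows are kept when r > ``r_min`` (strict) and p < ``alpha``. Returns the
    annotated kept table and per-cell-type sender/receiver counts.
    """
    common = [s for s in table.columns if s in program_scores.index]
    y = program_scores.loc[common].to_numpy(float)
    rs, ps, keep = [], [], []
    for _, row in table[common].iterrows():
        x = row.to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            rs.append(np.nan), ps.append(np.nan), keep.append(False)
            continue
        r, p = stats.pearsonr(x, y)
        rs.append(float(r)), ps.append(float(p))
        keep.append(r > r_min and p < alpha)
    out = table.copy()
    out["r"], out["p"], out["keep"] = rs, ps, keep
    kept = out[out["keep"]]
    senders = kept.index.get_level_values("source").value_counts()
    receivers = kept.index.get_level_values("target").value_counts()
    summary = pd.DataFrame({"as_sender": senders, "as_receiver": receivers}
                           ).fillna(0).astype(int)
    return out, summary
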