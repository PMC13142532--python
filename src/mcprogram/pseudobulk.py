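"""Pseudobulk aggregation, quality control, compositions and concordance.

A pseudobulk profile is the per-sample, per-cell-type sum of single-cell
counts; it is the unit of the multicellular factor model. This module builds
those profiles, applies the sample/gene quality filters, computes CLR-
transformed cell-type compositions, and provides the two cross-cohort
concordance summaries (marker Jaccard index and t-statistic correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PseudobulkCohort:
    """Per-cell-type sample x gene count views plus sample metadata.

    ``views[ct]`` is a DataFrame of non-negative counts indexed by sample;
    views may cover different sample subsets (QC is per cell type).
    ``cell_counts`` is celltype x sample (cells aggregated per profile).
    """

    views: dict[str, pd.DataFrame]
    meta: pd.DataFrame
    cell_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for ct, view in self.views.items():
            missing = view.index.difference(self.meta.index)
            if len(missing):
                raise ValueError(f"view {ct!r} has samples absent from meta: "
                                 f"{list(missing)[:5]}")
            if (view.to_numpy() < 0).any():
                raise ValueError(f"view {ct!r} contains negative counts")

    @property
    def celltypes(self) -> list[str]:
        return list(self.views)

    @property
    def total_counts(self) -> pd.DataFrame:
        """Celltype x sample total counts (sums over genes)."""
        rows = {ct: v.sum(axis=1) for ct, v in self.views.items()}
        return pd.DataFrame(rows).T.reindex(columns=self.meta.index).fillna(0.0)

    @property
    def gene_universe(self) -> list[str]:
        genes: set[str] = set()
        for v in self.views.values():
            genes.update(v.columns)
        return sorted(genes)


@dataclass
class CompositionMatrix:
    """Sample x celltype proportions and their CLR transform."""

    proportions: pd.DataFrame
    clr: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def aggregate_pseudobulk(
    cells: np.ndarray | pd.DataFrame,
    celltype_labels: np.ndarray | pd.Series,
    sample_labels: np.ndarray | pd.Series,
    meta: pd.DataFrame | None = None,
    gene_names: list[str] | None = None,
) -> PseudobulkCohort:
    """Sum raw counts over cells, per (cell type, sample).

    Rows with no cells for a (cell type, sample) pair are absent from that
    view (not zero-filled); ``cell_counts`` records 0 for them.
    """
    x = cells.to_numpy() if isinstance(cells, pd.DataFrame) else np.asarray(cells)
    ct = np.asarray(celltype_labels)
    sm = np.asarray(sample_labels)
    if not (len(ct) == len(sm) == x.shape[0]):
        raise ValueError("labels must align with cell rows")
    if gene_names is None:
        gene_names = (list(cells.columns) if isinstance(cells, pd.DataFrame)
                      else [f"G{i:04d}" for i in range(x.shape[1])])

    all_samples = sorted(pd.unique(sm))
    views: dict[str, pd.DataFrame] = {}
    cell_counts = pd.DataFrame(0, index=sorted(pd.unique(ct)), columns=all_samples)
    for c in cell_counts.index:
        mask_c = ct == c
        rows, samples_here = [], []
        for s in all_samples:
            mask = mask_c & (sm == s)
            n_cells = int(mask.sum())
            cell_counts.loc[c, s] = n_cells
            if n_cells:
                rows.append(x[mask].sum(axis=0))
                samples_here.append(s)
        views[c] = pd.DataFrame(np.vstack(rows) if rows else
                                np.empty((0, x.shape[1])),
                                index=samples_here, columns=gene_names)
    if meta is None:
        meta = pd.DataFrame(index=pd.Index(all_samples))
    return PseudobulkCohort(views=views, meta=meta, cell_counts=cell_counts)


def qc_filter_samples(
    pb: PseudobulkCohort, min_cells: int = 10, min_counts: int = 1000
) -> PseudobulkCohort:
    """Keep, per view, samples with >= min_cells cells and >= min_counts counts.

    Thresholds are inclusive ("a minimum of", "at least"). Filtering is per
    (cell type, sample), so views may end up with different sample subsets.
    """
    if pb.cell_counts is None:
        raise ValueError("qc_filter_samples requires cell_counts")
    views: dict[str, pd.DataFrame] = {}
    for ct, view in pb.views.items():
        totals = view.sum(axis=1)
        ncells = pb.cell_counts.loc[ct].reindex(view.index).fillna(0)
        keep = view.index[(ncells >= min_cells) & (totals >= min_counts)]
        views[ct] = view.loc[keep]
    return PseudobulkCohort(views=views, meta=pb.meta, cell_counts=pb.cell_counts)


def qc_filter_genes(
    view: pd.DataFrame, min_count: int = 10, min_total: int = 15
) -> pd.Index:
    """Genes with max count >= min_count in some sample and total >= min_total.

    The default thresholds (10/15) are the factor-model input filter; the
    differential-expression stage uses the looser (5/10) parameterization.
    """
    if view.shape[0] == 0 or view.shape[1] == 0:
        warnings.warn("qc_filter_genes: empty view", stacklevel=2)
        return pd.Index([], dtype=object)
    keep = (view.max(axis=0) >= min_count) & (view.sum(axis=0) >= min_total)
    return view.columns[keep]


def highly_variable_genes(
    view: pd.DataFrame, batch_labels: pd.Series | np.ndarray, n_hvg: int
) -> pd.Index:
    """Batch-aware HVG: top-``n_hvg`` standardized dispersion within any batch.

    Dispersion = variance / mean of log1p counts, z-scored within mean bins of
    a batch; a gene qualifies if it ranks in the top ``n_hvg`` of at least one
    batch. This is the pluggable default strategy; any callable returning a
    gene index may replace it in :func:`select_model_genes`.
    """
    batches = np.asarray(batch_labels)
    logx = np.log1p(view)
    selected: set[str] = set()
    for b in pd.unique(batches):
        sub = logx.loc[batches == b]
        if sub.shape[0] < 2:
            continue
        mean, var = sub.mean(axis=0), sub.var(axis=0)
        disp = var / mean.replace(0, np.nan)
        # Standardize dispersion within quantile bins of the mean.
        bins = pd.qcut(mean.rank(method="first"), q=min(10, len(mean)),
                       labels=False)
        z = pd.Series(index=view.columns, dtype=float)
        for q in pd.unique(bins):
            in_bin = bins == q
            d = disp[in_bin]
            sd = d.std()
            z[in_bin] = (d - d.mean()) / sd if sd and sd > 0 else 0.0
        selected.update(z.nlargest(min(n_hvg, z.notna().sum())).index)
    return view.columns[view.columns.isin(selected)]


def select_model_genes(
    view: pd.DataFrame,
    batch_labels: pd.Series | np.ndarray,
    n_hvg: int,
    marker_ranks: list[str] | None = None,
    n_markers_drop: int = 25,
    qc_genes: pd.Index | None = None,
) -> pd.Index:
    """Factor-model feature set: (batch-aware HVG) ∩ (QC-passed), minus the
    top ``n_markers_drop`` cell-identity marker genes."""
    if n_hvg > view.shape[1]:
        warnings.warn("n_hvg exceeds available genes; returning all",
                      stacklevel=2)
        hvg = view.columns
    else:
        hvg = highly_variable_genes(view, batch_labels, n_hvg)
    keep = hvg if qc_genes is None else hvg.intersection(qc_genes)
    if marker_ranks and n_markers_drop > 0:
        drop = set(marker_ranks[:n_markers_drop])
        keep = keep[~keep.isin(drop)]
    return view.columns[view.columns.isin(keep)]


def multiplicative_replacement(p: np.ndarray, delta_frac: float = 1e-6) -> np.ndarray:
    """Replace zeros in a composition row-wise, preserving the unit sum.

    Zeros become ``delta = delta_frac * min nonzero proportion`` of the row;
    nonzero entries shrink by the total mass assigned to zeros.
    """
    p = np.asarray(p, dtype=float)
    out = p.copy()
    for i in range(p.shape[0]):
        row = p[i]
        zero = row == 0
        if not zero.any():
            continue
        delta = delta_frac * row[~zero].min()
        out[i, zero] = delta
        out[i, ~zero] = row[~zero] * (1.0 - delta * zero.sum())
    return out


def clr_compositions(counts_per_type: pd.DataFrame) -> CompositionMatrix:
    """Row-normalize cell counts to proportions and CLR-transform them.

    Zeros are handled by multiplicative replacement before taking logs.
    """
    x = counts_per_type.to_numpy(dtype=float)
    row_sums = x.sum(axis=1)
    if (row_sums <= 0).any():
        raise ValueError("clr_compositions: all-zero sample row")
    p = x / row_sums[:, None]
    p_repl = multiplicative_replacement(p)
    logp = np.log(p_repl)
    clr = logp - logp.mean(axis=1, keepdims=True)
    idx, cols = counts_per_type.index, counts_per_type.columns
    return CompositionMatrix(
        proportions=pd.DataFrame(p, index=idx, columns=cols),
        clr=pd.DataFrame(clr, index=idx, columns=cols),
    )


def marker_jaccard(
    markers_a: dict[str, set[str]], markers_b: dict[str, set[str]]
) -> pd.DataFrame:
    """Jaccard index |A∩B| / |A∪B| for every cell-type pair across cohorts."""
    out = pd.DataFrame(index=list(markers_a), columns=list(markers_b),
                       dtype=float)
    for ca, a in markers_a.items():
        for cb, b in markers_b.items():
            union = set(a) | set(b)
            if not union:
                warnings.warn(f"empty marker union for ({ca}, {cb})",
                              stacklevel=2)
                out.loc[ca, cb] = 0.0
            else:
                out.loc[ca, cb] = len(set(a) & set(b)) / len(union)
    return out


def tstat_concordance(tstats_a: pd.Series, tstats_b: pd.Series) -> float:
    """Pearson correlation of differential-expression t-statistics over the
    genes common to both cohorts."""
    common = tstats_a.index.intersection(tstats_b.index)
    if len(common) < 3:
        raise ValueError("tstat_concordance needs >= 3 common genes")
    r, _ = stats.pearsonr(tstats_a.loc[common], tstats_b.loc[common])
    return float(r)
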