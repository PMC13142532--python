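"""Directed cell-type dependency networks from program activities.

For one latent program, per-cell-type activity (ULM t, z-standardized across
samples) is modelled with one ridge regression per target cell type using the
other cell types as predictors. Held-out predictability (5-fold CV R²) says
how "coordinated" a target is; the ridge coefficients give directed edge
weights. Fitting the network separately in cases and controls and comparing
coefficients classifies each ordered pair as shared, HC-enriched or
SLE-enriched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import KFold, cross_val_score

#: Ridge penalty grid searched by generalized cross-validation.
ALPHA_GRID = (1e-2, 1e-1, 1.0, 10.0, 100.0)


@dataclass
class DependencyNetwork:
    """Directed beta matrix between cell types with per-target CV R²."""

    celltypes: list[str]
    beta: pd.DataFrame          # source x target, diagonal = 0
    cv_r2: pd.Series            # per target
    condition: str              # {"all", "case", "control"}
    penalty: pd.Series          # chosen alpha per target

    def edges(self, beta_min: float = 0.1) -> set[tuple[str, str]]:
        """(source, target) pairs with |beta| above ``beta_min``."""
        out = set()
        for src in self.celltypes:
            for tgt in self.celltypes:
                if src != tgt and abs(self.beta.loc[src, tgt]) > beta_min:
                    out.add((src, tgt))
        return out


def fit_dependency_network(
    activities: pd.DataFrame,
    condition_mask: pd.Series | np.ndarray | None = None,
    condition: str = "all",
    n_folds: int = 5,
    seed: int = 0,
) -> DependencyNetwork:
    """Fit one ridge model per target cell type from all other cell types.

    ``activities`` is a sample x celltype matrix of z-scored program
    activities. The penalty is chosen per target by leave-one-out generalized
    CV over :data:`ALPHA_GRID`; ``cv_r2`` is the mean held-out R² over
    ``n_folds`` folds at that penalty; betas come from a final fit on all
    masked samples. Samples are sorted by index before folding so that row
    order does not affect the result.
    """
    if condition_mask is not None:
        activities = activities.loc[np.asarray(condition_mask)]
    activities = activities.sort_index()
    n = activities.shape[0]
    if n < 10:
        raise ValueError(f"need >= 10 samples, got {n}")
    if (activities.std(axis=0, ddof=0) == 0).any():
        bad = activities.columns[activities.std(axis=0, ddof=0) == 0]
        raise ValueError(f"constant activity column(s): {list(bad)}")

    celltypes = list(activities.columns)
    beta = pd.DataFrame(0.0, index=celltypes, columns=celltypes)
    cv_r2, penalty = {}, {}
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tgt in celltypes:
        preds = [c for c in celltypes if c != tgt]
        x = activities[preds].to_numpy()
        y = activities[tgt].to_numpy()
        model = RidgeCV(alphas=ALPHA_GRID).fit(x, y)
        alpha = float(model.alpha_)
        scores = cross_val_score(RidgeCV(alphas=[alpha]), x, y,
                                 cv=folds, scoring="r2")
        cv_r2[tgt] = float(np.mean(scores))
        penalty[tgt] = alpha
        beta.loc[preds, tgt] = model.coef_
    return DependencyNetwork(
        celltypes=celltypes, beta=beta, cv_r2=pd.Series(cv_r2),
        condition=condition, penalty=pd.Series(penalty))


def classify_edges(
    net_hc: DependencyNetwork,
    net_sle: DependencyNetwork,
    tol: float = 0.1,
) -> pd.DataFrame:
    """Classify each ordered cell-type pair by condition specificity.

    An edge is ``shared`` when the coefficients have opposite signs across
    conditions or |beta_SLE - beta_HC| is strictly below ``tol``; otherwise it
    is ``HC_enriched`` (beta_HC > beta_SLE) or ``SLE_enriched``. sign(0) is
    treated as positive.
    """
    if net_hc.celltypes != net_sle.celltypes:
        raise ValueError("networks must share cell types")
    rows = []
    for src in net_hc.celltypes:
        for tgt in net_hc.celltypes:
            if src == tgt:
                continue
            b_hc = float(net_hc.beta.loc[src, tgt])
            b_sle = float(net_sle.beta.loc[src, tgt])
            delta = b_sle - b_hc
            sign = lambda v: 1.0 if v >= 0 else -1.0
            # |delta| == tol is classified; guard the boundary against
            # float representation error.
            below_tol = abs(delta) < tol and not np.isclose(abs(delta), tol)
            if sign(b_hc) != sign(b_sle) or below_tol:
                cls = "shared"
            elif b_hc > b_sle:
                cls = "HC_enriched"
            else:
                cls = "SLE_enriched"
            rows.append((src, tgt, b_hc, b_sle, delta, cls))
    return pd.DataFrame(
        rows, columns=["source", "target", "beta_hc", "beta_sle", "delta",
                       "class"])


def to_long(net: DependencyNetwork) -> pd.DataFrame:
    """Long-format (source, target, beta, condition) edge table."""
    rows = [(s, t, float(net.beta.loc[s, t]), net.condition)
            for s in net.celltypes for t in net.celltypes if s != t]
    return pd.DataFrame(rows, columns=["source", "target", "beta", "condition"])


def to_graph(net: DependencyNetwork, beta_min: float = 0.1):
    """Directed networkx graph of edges with |beta| > ``beta_min``."""
    import networkx as nx

    g = nx.DiGraph(condition=net.condition)
    g.add_nodes_from(net.celltypes)
    for src, tgt in net.edges(beta_min):
        g.add_edge(src, tgt, beta=float(net.beta.loc[src, tgt]))
    return g
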