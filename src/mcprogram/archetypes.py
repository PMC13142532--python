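"""Archetypal analysis of cell states and archetype-program association.

Cells of one type are modelled as convex mixtures of k archetypes — extreme
transcriptional states under the Pareto-task view of cell identity. The fit
minimizes ``||X - S A||^2`` with the mixture rows S on the probability
simplex and the archetypes A themselves convex combinations of data points
(A = B X, B rows on the simplex), by alternating constrained least squares
from a furthest-point initialization (Cutler-Breiman scheme; the B-step uses
Frank-Wolfe updates with an accept-if-better guard, so the residual sum of
squares never increases).

Downstream: RBF cell weights around each archetype build archetype expression
profiles; patient mean embeddings are projected onto the archetype hull and
their distances to archetypes regressed (OLS + HC3 robust errors) on the
patient's program score to classify archetypes as SLE- or HC-associated; and
cytokine-response/blood-protein priors are linked to archetype profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from ._simplex import simplex_lstsq, simplex_lstsq_rows


@dataclass
class ArchetypeModel:
    embedding: np.ndarray            # cell x dim
    A: np.ndarray                    # k x dim archetype coordinates
    S: np.ndarray                    # cell x k mixture weights (simplex rows)
    rss: float
    rss_history: list[float] = field(default_factory=list, repr=False)
    k: int = 0
    converged: bool = True
    stability: np.ndarray | None = None

    @property
    def lengthscale(self) -> float:
        """RBF length scale: half the median centroid-to-archetype distance."""
        centroid = self.embedding.mean(axis=0)
        d = np.linalg.norm(self.A - centroid, axis=1)
        return 0.5 * float(np.median(d))


def _furthest_point_init(x: np.ndarray, k: int, rng: np.random.Generator
                         ) -> np.ndarray:
    """Indices of k mutually distant data points (greedy furthest-point)."""
    centroid = x.mean(axis=0)
    first = int(np.argmax(((x - centroid) ** 2).sum(axis=1)))
    chosen = [first]
    d2 = ((x - x[first]) ** 2).sum(axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d2))
        chosen.append(nxt)
        d2 = np.minimum(d2, ((x - x[nxt]) ** 2).sum(axis=1))
    return np.asarray(chosen)


def _frank_wolfe_b(x: np.ndarray, b: np.ndarray, target: np.ndarray,
                   n_steps: int = 30) -> np.ndarray:
    """Minimize ||X.T b - target||^2 over the simplex by Frank-Wolfe."""
    a = x.T @ b
    for _ in range(n_steps):
        grad = 2.0 * (x @ (a - target))
        j = int(np.argmin(grad))
        direction = x[j] - a
        denom = float(direction @ direction)
        if denom <= 1e-30:
            break
        gamma = float(np.clip(-((a - target) @ direction) / denom, 0.0, 1.0))
        if gamma <= 0:
            break
        b = (1.0 - gamma) * b
        b[j] += gamma
        a = (1.0 - gamma) * a + gamma * x[j]
    return b


def fit_archetypes(
    embedding: np.ndarray,
    k: int,
    max_iter: int = 100,
    tol: float = 1e-7,
    seed: int = 0,
) -> ArchetypeModel:
    """Fit k archetypes to an embedding by alternating simplex least squares."""
    if k < 2:
        raise ValueError("k must be >= 2")
    x = np.asarray(embedding, dtype=float)
    n = x.shape[0]
    rng = np.random.default_rng(seed)

    init = _furthest_point_init(x, k, rng)
    b = np.zeros((k, n))
    b[np.arange(k), init] = 1.0
    a = b @ x
    s = simplex_lstsq_rows(a, x)
    rss = float(((x - s @ a) ** 2).sum())
    history = [rss]
    converged = False
    for _ in range(max_iter):
        # B-step: update each archetype toward its weighted residual target,
        # staying inside the convex hull of the data; accept only improvements.
        for c in range(k):
            sc = s[:, c]
            denom = float(sc @ sc)
            if denom <= 1e-30:
                continue
            resid = x - s @ a + np.outer(sc, a[c])
            target = (sc @ resid) / denom
            b_new = _frank_wolfe_b(x, b[c].copy(), target)
            a_new = b_new @ x
            a_cand = a.copy()
            a_cand[c] = a_new
            rss_cand = float(((x - s @ a_cand) ** 2).sum())
            if rss_cand <= rss:
                b[c], a, rss = b_new, a_cand, rss_cand
        # S-step (exact): mixture weights per cell.
        s = simplex_lstsq_rows(a, x)
        rss = float(((x - s @ a) ** 2).sum())
        history.append(rss)
        if history[-2] - history[-1] <= tol * max(history[-2], 1e-30):
            converged = True
            break
    return ArchetypeModel(embedding=x, A=a, S=s, rss=rss,
                          rss_history=history, k=k, converged=converged)


def scan_k(embedding: np.ndarray, k_range: range | list[int],
           seed: int = 0, **kwargs) -> pd.DataFrame:
    """Per-k RSS and an elbow criterion (second difference of RSS).

    The recommended k maximizes the discrete second difference of the RSS
    curve (interior points of the scanned range).
    """
    ks = list(k_range)
    rss = [fit_archetypes(embedding, k, seed=seed, **kwargs).rss for k in ks]
    out = pd.DataFrame({"k": ks, "rss": rss})
    second = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        second[i] = rss[i - 1] - 2 * rss[i] + rss[i + 1]
    out["elbow_criterion"] = second
    out["recommended"] = False
    if len(ks) > 2:
        out.loc[int(np.nanargmax(second)), "recommended"] = True
    elif ks:
        out.loc[0, "recommended"] = True
    return out


def match_archetypes(a_fit: np.ndarray, a_ref: np.ndarray) -> np.ndarray:
    """Hungarian assignment of fitted to reference archetypes; returns, for
    each reference archetype, the index of its matched fitted archetype."""
    cost = np.linalg.norm(a_ref[:, None, :] - a_fit[None, :, :], axis=2)
    ref_idx, fit_idx = linear_sum_assignment(cost)
    out = np.empty(a_ref.shape[0], dtype=int)
    out[ref_idx] = fit_idx
    return out


def bootstrap_stability(
    embedding: np.ndarray, k: int, n_boot: int = 50, seed: int = 0, **kwargs
) -> np.ndarray:
    """Per-archetype mean best-match cosine agreement over bootstrap refits.

    Archetype vectors are taken relative to the data centroid; agreement is
    the cosine similarity with the matched reference archetype, clipped at 0.
    """
    x = np.asarray(embedding, dtype=float)
    ref = fit_archetypes(x, k, seed=seed, **kwargs)
    centroid = x.mean(axis=0)
    rng = np.random.default_rng(seed)
    agree = np.zeros((n_boot, k))
    for b in range(n_boot):
        idx = rng.integers(0, x.shape[0], size=x.shape[0])
        boot = fit_archetypes(x[idx], k, seed=seed, **kwargs)
        matched = match_archetypes(boot.A, ref.A)
        for c in range(k):
            u = ref.A[c] - centroid
            v = boot.A[matched[c]] - centroid
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            cos = float(u @ v / (nu * nv)) if nu > 0 and nv > 0 else 0.0
            agree[b, c] = float(np.clip(cos, 0.0, 1.0))
    return agree.mean(axis=0)


def rbf_weights(model: ArchetypeModel) -> np.ndarray:
    """Cell x k RBF weights: exp(-d(cell, archetype)^2 / (2 l^2))."""
    ell = model.lengthscale
    if ell <= 0:
        raise ValueError("degenerate geometry: all archetypes at the centroid")
    d2 = ((model.embedding[:, None, :] - model.A[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * ell ** 2))


def archetype_profiles(
    weights: np.ndarray, zscored: pd.DataFrame
) -> pd.DataFrame:
    """Weight-normalized mean of z-scored expression per archetype."""
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != zscored.shape[0]:
        raise ValueError("weights and expression must align on cells")
    totals = w.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("archetype with zero total weight")
    prof = (w.T @ zscored.to_numpy(float)) / totals[:, None]
    return pd.DataFrame(prof, columns=zscored.columns,
                        index=[f"arch{c}" for c in range(w.shape[1])])


def project_patient_means(
    patient_means: pd.DataFrame, a: np.ndarray
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.DataFrame]:
    """Project patient mean embeddings onto the archetype convex hull.

    Returns (projected points, deviations, mixture coordinates, distances to
    each archetype measured from the projected point). The deviation is the
    residual norm; it is 0 (within solver tolerance) iff the mean lies inside
    the hull.
    """
    pts = patient_means.to_numpy(float)
    mix = simplex_lstsq_rows(a, pts)
    proj = mix @ a
    dev = np.linalg.norm(pts - proj, axis=1)
    d = np.linalg.norm(proj[:, None, :] - a[None, :, :], axis=2)
    arch_names = [f"arch{c}" for c in range(a.shape[0])]
    idx = patient_means.index
    return (pd.DataFrame(proj, index=idx),
            pd.Series(dev, index=idx, name="deviation"),
            pd.DataFrame(mix, index=idx, columns=arch_names),
            pd.DataFrame(d, index=idx, columns=arch_names))


@dataclass
class ArchetypeAssociation:
    """Per-archetype regression of program score on hull distance."""

    table: pd.DataFrame        # archetype, slope, se, t, p, fdr, class
    distances: pd.DataFrame
    deviations: pd.Series


def _freedman_lane_p(y: np.ndarray, d: np.ndarray, cov: np.ndarray,
                     t_obs: float, n_perm: int, rng: np.random.Generator
                     ) -> float:
    """Freedman-Lane residual-permutation p for the distance coefficient."""
    xr = sm.add_constant(cov)
    reduced = sm.OLS(y, xr).fit()
    fitted, resid = reduced.fittedvalues, reduced.resid
    x_full = sm.add_constant(np.column_stack([d, cov]))
    count = 0
    for _ in range(n_perm):
        y_star = fitted + rng.permutation(resid)
        t_star = sm.OLS(y_star, x_full).fit().tvalues[1]
        if abs(t_star) >= abs(t_obs):
            count += 1
    return (1 + count) / (n_perm + 1)


def associate_archetype_program(
    distances: pd.DataFrame,
    program_scores: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    method: str = "fdr_bh",
    n_perm: int = 0,
    seed: int = 0,
) -> ArchetypeAssociation:
    """Test whether patients closer to an archetype have higher program scores.

    One OLS per archetype (score ~ distance [+ covariates]) with HC3 robust
    standard errors; multiplicity across archetypes controlled by BH (or
    Bonferroni). Class: SLE when slope < 0 and fdr < alpha (closer to the
    archetype means higher program score), HC when slope > 0 and fdr < alpha,
    else neutral. With ``n_perm > 0`` a permutation p-value is added: plain
    score permutation without covariates, Freedman-Lane with covariates.
    """
    common = distances.index.intersection(program_scores.index)
    distances = distances.loc[common]
    y = program_scores.loc[common].to_numpy(float)
    cov = covariates.loc[common].to_numpy(float) if covariates is not None else None
    rng = np.random.default_rng(seed)
    rows = []
    for arch in distances.columns:
        d = distances[arch].to_numpy(float)
        if np.std(d) == 0:
            continue
        x = d[:, None] if cov is None else np.column_stack([d, cov])
        fit = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC3")
        slope, se = float(fit.params[1]), float(fit.bse[1])
        t, p = float(fit.tvalues[1]), float(fit.pvalues[1])
        p_perm = np.nan
        if n_perm > 0:
            if cov is None:
                count = 0
                for _ in range(n_perm):
                    yp = rng.permutation(y)
                    tp = sm.OLS(yp, sm.add_constant(x)).fit().tvalues[1]
                    if abs(tp) >= abs(t):
                        count += 1
                p_perm = (1 + count) / (n_perm + 1)
            else:
                p_perm = _freedman_lane_p(y, d, cov, t, n_perm, rng)
        rows.append((arch, slope, se, t, p, p_perm))
    table = pd.DataFrame(rows, columns=["archetype", "slope", "se", "t", "p",
                                        "p_perm"])
    if len(table):
        table["fdr"] = multipletests(table["p"], method=method)[1]
        sig = table["fdr"] < alpha
        table["class"] = np.where(sig & (table["slope"] < 0), "SLE",
                                  np.where(sig & (table["slope"] > 0), "HC",
                                           "neutral"))
    else:
        table["fdr"], table["class"] = [], []
    return ArchetypeAssociation(table=table, distances=distances,
                                deviations=pd.Series(dtype=float))


@dataclass
class CytokineActivityTable:
    activity: pd.DataFrame      # archetype x cytokine ULM t (NaN = no prior)
    pvalues: pd.DataFrame
    adj_pvalues: pd.DataFrame
    delta: pd.DataFrame         # cytokine, delta, wilcoxon_p, fdr, significant
    cosine: pd.DataFrame        # SLE archetype x SLE archetype


def score_cytokines(
    profiles: pd.DataFrame,
    dictionary: dict[tuple[str, str], pd.Series],
    celltype_map: pd.Series,
    classes: pd.Series,
    alpha: float = 0.05,
) -> CytokineActivityTable:
    """Cytokine activity of archetype profiles, restricted to own cell type.

    Each archetype profile (z-scored gene vector) is ULM-scored only against
    cytokine signatures of its own cell type. Per cytokine present in both
    SLE- and HC-class archetypes, the effect size is
    ``delta = mean_SLE - mean_HC`` with a two-sided Wilcoxon rank-sum p and BH
    correction. Cosine similarity is computed between SLE archetypes over the
    cytokines significant (BH-adjusted p < alpha) in at least one SLE
    archetype.
    """
    from .programs import score_ulm

    cytokines = sorted({c for c, _ in dictionary})
    act = pd.DataFrame(np.nan, index=profiles.index, columns=cytokines)
    pv = act.copy()
    import warnings as _w
    for arch in profiles.index:
        ct = celltype_map.get(arch)
        keys = [c for c in cytokines if (c, ct) in dictionary]
        if not keys:
            _w.warn(f"no cytokine priors for cell type of {arch!r}; skipped",
                    stacklevel=2)
            continue
        for c in keys:
            t, p = score_ulm(profiles.loc[arch], dictionary[(c, ct)])
            act.loc[arch, c], pv.loc[arch, c] = t, p
    flat = pv.to_numpy().ravel()
    mask = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if mask.any():
        adj[mask] = multipletests(flat[mask], method="fdr_bh")[1]
    adj_pv = pd.DataFrame(adj.reshape(pv.shape), index=pv.index,
                          columns=pv.columns)

    sle = [a for a in profiles.index if classes.get(a) == "SLE"]
    hc = [a for a in profiles.index if classes.get(a) == "HC"]
    rows = []
    for c in cytokines:
        vals_sle = act.loc[sle, c].dropna()
        vals_hc = act.loc[hc, c].dropna()
        if len(vals_sle) == 0 or len(vals_hc) == 0:
            continue
        delta = float(vals_sle.mean() - vals_hc.mean())
        wp = float(stats.ranksums(vals_sle, vals_hc).pvalue)
        rows.append((c, delta, wp))
    delta_df = pd.DataFrame(rows, columns=["cytokine", "delta", "wilcoxon_p"])
    if len(delta_df):
        delta_df["fdr"] = multipletests(delta_df["wilcoxon_p"],
                                        method="fdr_bh")[1]
        delta_df["significant"] = delta_df["fdr"] < alpha
    else:
        delta_df["fdr"], delta_df["significant"] = [], []

    sig_cyt = [c for c in cytokines
               if (adj_pv.loc[sle, c] < alpha).any()] if sle else []
    if sle and sig_cyt:
        mat = act.loc[sle, sig_cyt].fillna(0.0).to_numpy()
        norms = np.linalg.norm(mat, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        unit = mat / norms
        cos = pd.DataFrame(unit @ unit.T, index=sle, columns=sle)
    else:
        cos = pd.DataFrame(index=sle, columns=sle, dtype=float)
    return CytokineActivityTable(activity=act, pvalues=pv, adj_pvalues=adj_pv,
                                 delta=delta_df, cosine=cos)


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score archetype profiles per gene across archetypes (same cell type)."""
    sd = profiles.std(axis=0, ddof=0).replace(0.0, np.nan)
    return (profiles - profiles.mean(axis=0)) / sd


def link_blood_proteins(
    profiles_z: pd.DataFrame,
    classes: pd.Series,
    protein_list: pd.DataFrame,
    z_thresh: float = 0.2,
) -> list[str]:
    """Blood proteins with selective transcriptional support in SLE archetypes.

    A protein's gene is retained iff its cross-archetype z-score exceeds
    ``z_thresh`` in at least one SLE-class archetype, in no HC-class
    archetype, and the protein is flagged elevated in cases.
    """
    sle = [a for a in profiles_z.index if classes.get(a) == "SLE"]
    hc = [a for a in profiles_z.index if classes.get(a) == "HC"]
    if not sle and not hc:
        raise ValueError("no SLE/HC class assignments supplied")
    elevated = set(protein_list.loc[protein_list["elevated_in_cases"], "gene"])
    out = []
    for gene in profiles_z.columns:
        if gene not in elevated:
            continue
        up_sle = (profiles_z.loc[sle, gene] > z_thresh).any() if sle else False
        up_hc = (profiles_z.loc[hc, gene] > z_thresh).any() if hc else False
        if up_sle and not up_hc:
            out.append(gene)
    return sorted(out)
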