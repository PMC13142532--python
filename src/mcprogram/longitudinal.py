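"""Flare-risk analysis of longitudinal SLE visits.

Bulk visit expression is z-scored to healthy-control statistics, program
activities are mapped per visit, remission visits (SLEDAI < 3) are labelled
short-term (flare — a >= 4-point SLEDAI rise relative to the index visit —
at the next follow-up within the window) or long-term (sustained remission),
pre-flare activity differences are Welch-tested with Holm correction, and
time-to-flare is modelled with Cox proportional hazards (Breslow ties,
Harrell C-index, likelihood-ratio tests for nested models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests


def zscore_to_controls(
    bulk: pd.DataFrame, control_mean: pd.Series, control_sd: pd.Series
) -> pd.DataFrame:
    """Standardize each gene to healthy-control mean/SD; drop unusable genes.

    Genes with missing values, missing control statistics, or zero control SD
    are removed (the latter with a warning).
    """
    genes = bulk.columns.intersection(control_mean.index).intersection(
        control_sd.index)
    bulk = bulk[genes].dropna(axis=1)
    sd = control_sd.loc[bulk.columns]
    zero = sd[sd == 0].index
    if len(zero):
        warnings.warn(f"dropping {len(zero)} gene(s) with zero control SD",
                      stacklevel=2)
        bulk = bulk.drop(columns=zero)
        sd = sd.drop(index=zero)
    return (bulk - control_mean.loc[bulk.columns]) / sd


def label_remission_visits(
    visits: pd.DataFrame,
    window_days: int = 91,
    remission_max: float = 2.99,
    flare_delta: int = 4,
    longterm_sledai: int = 2,
    min_followup: int = 90,
) -> pd.DataFrame:
    """Label remission visits by subsequent flare within the window.

    A remission (index) visit is labelled ``short_term`` when the first
    subsequent visit falls within ``window_days`` and shows a SLEDAI increase
    of at least ``flare_delta`` relative to the index visit; ``long_term``
    when no flare occurs in the window, the patient's last recorded SLEDAI is
    below ``longterm_sledai``, and cumulative follow-up at the index visit
    exceeds ``min_followup`` days; otherwise ``excluded``. Survival time is
    days from index to the next visit, with flare as the event.
    """
    out = visits.copy()
    out["time_since_prev"] = np.nan
    out["cum_followup"] = np.nan
    out["remission"] = out["SLEDAI"] <= remission_max
    out["label"] = pd.Series(pd.NA, index=out.index, dtype="object")
    out["time_to_next"] = np.nan
    out["event"] = pd.Series(pd.NA, index=out.index, dtype="object")
    for _, idx in out.groupby("patient_id", sort=False).groups.items():
        sub = out.loc[idx].sort_values("day")
        days = sub["day"].to_numpy(float)
        sled = sub["SLEDAI"].to_numpy(float)
        last_sledai = sled[-1]
        out.loc[sub.index, "time_since_prev"] = np.concatenate(
            [[np.nan], np.diff(days)])
        out.loc[sub.index, "cum_followup"] = days - days[0]
        for i, vi in enumerate(sub.index):
            if not out.at[vi, "remission"]:
                continue
            if i == len(sub) - 1:
                out.at[vi, "label"] = "excluded"
                continue
            gap = days[i + 1] - days[i]
            flared = (sled[i + 1] - sled[i]) >= flare_delta
            out.at[vi, "time_to_next"] = gap
            if flared and gap <= window_days:
                out.at[vi, "label"] = "short_term"
                out.at[vi, "event"] = "flare"
            elif (last_sledai < longterm_sledai
                  and (days[i] - days[0]) > min_followup
                  and not (flared and gap <= window_days)):
                out.at[vi, "label"] = "long_term"
                out.at[vi, "event"] = "none"
            else:
                out.at[vi, "label"] = "excluded"
    return out


def test_preflare(
    activities: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Welch t-test of each activity column between short- and long-term
    remission visits, with Holm correction and significance stars.

    Positive t means higher activity before an imminent flare.
    """
    short = activities.loc[labels == "short_term"]
    long_ = activities.loc[labels == "long_term"]
    if len(short) < 2 or len(long_) < 2:
        raise ValueError("need >= 2 visits per label")
    rows = []
    for col in activities.columns:
        t, p = stats.ttest_ind(short[col], long_[col], equal_var=False)
        rows.append((col, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["activity", "t", "p"])
    out["p_holm"] = multipletests(out["p"], method="holm")[1]
    out["stars"] = pd.cut(out["p_holm"], [-np.inf, 0.001, 0.01, 0.05, np.inf],
                          labels=["***", "**", "*", ""]).astype(str)
    return out


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary."""

    summary: pd.DataFrame       # covariate, beta, HR, ci_low, ci_high, p
    log_likelihood: float
    c_index: float
    lrt_p: float = float("nan")


def fit_cox(
    covariates: pd.DataFrame,
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
    nested_base: list[str] | None = None,
) -> CoxFit:
    """Cox proportional-hazards model of time-to-flare.

    Partial likelihood with Breslow tie handling, Wald confidence intervals
    and Harrell's C-index (lifelines). When ``nested_base`` names a covariate
    subset, a likelihood-ratio test compares the full model against the
    nested model with only those covariates.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() < 1:
        raise ValueError("fit_cox needs at least one event")
    if (time <= 0).any():
        raise ValueError("fit_cox: non-positive survival times")
    df = covariates.reset_index(drop=True).copy()
    df["__time"], df["__event"] = time, event

    def _fit(frame: pd.DataFrame) -> CoxPHFitter:
        cph = CoxPHFitter()
        cph.fit(frame, duration_col="__time", event_col="__event",
                fit_options={"precision": 1e-9})
        return cph

    cph = _fit(df)
    summ = cph.summary
    summary = pd.DataFrame({
        "covariate": summ.index,
        "beta": summ["coef"].to_numpy(),
        "HR": summ["exp(coef)"].to_numpy(),
        "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
        "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
        "p": summ["p"].to_numpy(),
    }).reset_index(drop=True)
    fit = CoxFit(summary=summary,
                 log_likelihood=float(cph.log_likelihood_),
                 c_index=float(cph.concordance_index_))
    if nested_base is not None:
        base_cols = list(nested_base)
        if base_cols:
            base = _fit(df[base_cols + ["__time", "__event"]])
            ll0 = float(base.log_likelihood_)
        else:
            ll0 = float(_null_log_likelihood(time, event))
        lr = 2.0 * (fit.log_likelihood - ll0)
        dof = covariates.shape[1] - len(base_cols)
        fit.lrt_p = float(stats.chi2.sf(max(lr, 0.0), df=dof))
    return fit


def _null_log_likelihood(time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of the covariate-free model."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d = int(((time == t) & (event == 1)).sum())
        ll -= d * np.log((time >= t).sum())
    return ll


def gene_flare_screen(
    z: pd.DataFrame,
    signatures: dict[str, dict[str, set[str]]],
    protein_list: pd.DataFrame,
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Univariate Cox screen of candidate blood-biomarker genes.

    Genes are restricted to top-loading program genes (union over
    ``signatures[program][celltype]``) that are also in the blood-protein
    list; each gets a univariate :func:`fit_cox` (HR, CI, p) plus, per
    program, the count of cell-type signatures containing it.
    """
    proteins = set(protein_list["gene"])
    candidates = sorted(
        {g for prog in signatures.values() for s in prog.values() for g in s}
        & proteins & set(z.columns))
    rows = []
    for gene in candidates:
        fit = fit_cox(z[[gene]], time, event)
        row = {"gene": gene,
               "beta": fit.summary["beta"].iloc[0],
               "HR": fit.summary["HR"].iloc[0],
               "ci_low": fit.summary["ci_low"].iloc[0],
               "ci_high": fit.summary["ci_high"].iloc[0],
               "p": fit.summary["p"].iloc[0]}
        for prog, by_ct in signatures.items():
            row[f"n_celltypes_{prog}"] = sum(gene in s for s in by_ct.values())
        rows.append(row)
    return pd.DataFrame(rows)
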