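"""End-to-end pipeline on synthetic cohorts.

Chains every stage on generated data with planted ground truth: pseudobulk QC
-> factor model -> program selection & covariate association -> per-cell-type
activities -> dependency networks & edge classes -> coordinated signature ->
priors & ligand-receptor communication -> archetypes & program association ->
longitudinal flare risk -> spatial co-localization. Returns a dict of stage
outputs; useful as a smoke test, a worked example, and the acceptance-run
driver.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import archetypes as arch
from . import depnet, factorize, longitudinal, programs, pseudobulk, spatial
from . import synthgen


def best_matching_factor(model: factorize.FactorModel,
                         true_scores: pd.Series) -> tuple[str, float]:
    """Fitted factor with the highest |Pearson r| against a true score."""
    pooled = model.pooled_scores.reindex(true_scores.index)
    best, best_r = model.factor_names[0], 0.0
    for f in model.factor_names:
        r = float(np.corrcoef(pooled[f], true_scores)[0, 1])
        if abs(r) > abs(best_r):
            best, best_r = f, r
    return best, best_r


def run_pipeline(seed: int = 0, quick: bool = False) -> dict:
    """Run the full analysis on default synthetic study conditions."""
    out: dict = {"seed": seed}

    # --- cohort simulation, QC, factor model -----------------------------
    cfg = synthgen.SimConfig(seed=seed)
    pb, gt = synthgen.generate_pseudobulk_cohort(cfg)
    pb_qc = pseudobulk.qc_filter_samples(pb)
    raw_views = {ct: v[pseudobulk.qc_filter_genes(v)]
                 for ct, v in pb_qc.views.items()}
    views = {ct: np.log1p(v) for ct, v in raw_views.items()}
    groups = pb.meta["group"]
    model = factorize.fit_factors(views, groups, n_factors=10)
    out["model"], out["ground_truth"], out["cohort"] = model, gt, pb

    mc_factor, r_mc = best_matching_factor(model, gt.true_scores.iloc[:, 0])
    rs_factor, r_rs = best_matching_factor(model, gt.true_scores.iloc[:, 1])
    out["mc_factor"], out["mc_recovery_r"] = mc_factor, r_mc
    out["restricted_factor"], out["restricted_recovery_r"] = rs_factor, r_rs
    out["selected_programs"] = factorize.select_programs(model.r2)

    covars = pb.meta[["condition", "SLEDAI", "age", "sex"]]
    out["covariate_assoc"] = factorize.associate_covariates(
        model.pooled_scores, covars)

    # --- per-cell-type activities and dependency networks ----------------
    sets = programs.factor_gene_sets(model.loadings, mc_factor)
    acts = {}
    for ct, view in views.items():
        acts[ct] = programs.score_activities(
            view, {ct: sets[ct]}).scores[ct]
    activity = pd.DataFrame(acts).dropna()
    activity = (activity - activity.mean()) / activity.std(ddof=0)
    out["activity"] = activity

    cond = pb.meta["condition"].reindex(activity.index)
    net_all = depnet.fit_dependency_network(activity, condition="all",
                                            seed=seed)
    net_hc = depnet.fit_dependency_network(
        activity, cond == "control", condition="control", seed=seed)
    net_sle = depnet.fit_dependency_network(
        activity, cond == "case", condition="case", seed=seed)
    out["net_all"], out["net_hc"], out["net_sle"] = net_all, net_hc, net_sle
    out["edge_classes"] = depnet.classify_edges(net_hc, net_sle)

    # --- coordinated signature and priors --------------------------------
    signature = programs.coordinated_signature(model, net_all.cv_r2, mc_factor)
    out["signature"] = signature
    priors = synthgen.generate_priors(
        n_lr=40, n_cytokines=5, n_proteins=30, seed=seed,
        gene_universe=pb.gene_universe, celltypes=cfg.celltypes,
        factor_loadings=gt.true_loadings)
    out["priors"] = priors

    # --- ligand-receptor communication -----------------------------------
    cell_counts = pb.cell_counts
    mean_expr = {ct: np.log1p(v.div(cell_counts.loc[ct].reindex(v.index),
                                    axis=0))
                 for ct, v in raw_views.items()}
    detect = {ct: m / (m + 1.0) for ct, m in mean_expr.items()}
    ccc = programs.score_ccc(mean_expr, detect, priors["lr"])
    ccc_f = programs.filter_ccc_views(
        ccc, min_inter=5, min_lr=5, min_samples=30,
        net_edges=net_all.edges(beta_min=0.1))
    mc_scores = model.pooled_scores[mc_factor]
    if len(ccc_f):
        ccc_flagged, ccc_summary = programs.correlate_ccc_program(
            ccc_f, mc_scores)
    else:
        ccc_flagged = ccc_f.assign(r=[], p=[], keep=[])
        ccc_summary = pd.DataFrame(columns=["as_sender", "as_receiver"])
    out["ccc"], out["ccc_summary"] = ccc_flagged, ccc_summary

    # --- archetypes -------------------------------------------------------
    n_pat, cpp = (30, 40) if quick else (60, 60)
    adata, cell_gt = synthgen.generate_single_cells(
        k=4, dim=5, cells_per_patient=cpp, n_patients=n_pat,
        coupling=0.8, seed=seed)
    amodel = arch.fit_archetypes(adata.obsm["X_embed"], k=4, seed=seed)
    weights = arch.rbf_weights(amodel)
    zexpr = pd.DataFrame(
        (adata.X - adata.X.mean(0)) / adata.X.std(0),
        index=adata.obs_names, columns=adata.var_names)
    profiles = arch.archetype_profiles(weights, zexpr)
    pat_means = pd.DataFrame(adata.obsm["X_embed"], index=adata.obs_names) \
        .groupby(adata.obs["patient_id"].to_numpy()).mean()
    _, dev, _, dists = arch.project_patient_means(pat_means, amodel.A)
    assoc = arch.associate_archetype_program(dists, cell_gt.patient_scores)
    out["archetype_model"], out["archetype_assoc"] = amodel, assoc
    out["archetype_truth_err"] = float(np.mean(np.min(np.linalg.norm(
        cell_gt.archetype_coords_true[:, None, :] - amodel.A[None, :, :],
        axis=2), axis=1)))

    # Cytokine & protein linkage on a single simulated cell type ("cM").
    cyt_dict = priors["cytokines"]
    cmap = pd.Series({a: "cM" for a in profiles.index})
    classes = pd.Series(assoc.table.set_index("archetype")["class"])
    gene_universe = list(adata.var_names)
    cyt_dict_cells = {
        (c, "cM"): pd.Series(
            np.random.default_rng(seed + i).standard_normal(10),
            index=np.random.default_rng(seed + i).choice(
                gene_universe, 10, replace=False))
        for i, c in enumerate(sorted({c for c, _ in cyt_dict}))}
    out["cytokines"] = arch.score_cytokines(profiles, cyt_dict_cells, cmap,
                                            classes)
    prot = pd.DataFrame({"gene": gene_universe[:20],
                         "elevated_in_cases": [True] * 20})
    out["proteins"] = arch.link_blood_proteins(
        arch.zscore_profiles(profiles), classes, prot)

    # --- longitudinal flare risk ------------------------------------------
    n_lpat = 60 if quick else 150
    visits, vis_gt = synthgen.generate_longitudinal(
        n_patients=n_lpat, visits_per_patient=5, beta_flare=1.0, seed=seed)
    labeled = longitudinal.label_remission_visits(visits)
    sig_cols = [c for c in visits.columns if c.startswith("sig_")]
    expr_cols = sig_cols + [c for c in visits.columns if c.startswith("bg_")]
    act_vis = programs.score_activities(
        labeled[expr_cols],
        {"program": pd.Series(1.0, index=sig_cols)}).scores
    act_vis["wmean"] = act_vis["program"]
    mask = labeled["label"].isin(["short_term", "long_term"])
    out["preflare"] = longitudinal.test_preflare(
        act_vis.loc[mask], labeled.loc[mask, "label"])
    cox = longitudinal.fit_cox(
        labeled.loc[mask, ["activity"]],
        labeled.loc[mask, "time_to_next"],
        (labeled.loc[mask, "event"] == "flare"),
        nested_base=[])
    out["cox"], out["visits"] = cox, labeled

    # --- spatial ----------------------------------------------------------
    n_slides = 2 if quick else 4
    slides, sp_gt = synthgen.generate_spatial(
        n_slides=n_slides, grid=(18, 18), niche_radius=2.5, coloc=2.0,
        seed=seed)
    per_slide = spatial.colocalize_slides(
        slides, programs=["IFN"], celltypes=["IMM"], seed=seed,
        n_perms=100)
    out["coloc"] = spatial.aggregate_colocalization(per_slide)
    out["coloc_per_slide"] = per_slide

    case = next(s for s in slides if s.condition == "case")
    intra, para, mask_sp = spatial.build_views(
        case.features["composition"], case.coords,
        case.annotations["glomerular"])
    out["multiview"] = spatial.fit_multiview(intra, para, target="IMM",
                                             mask=mask_sp, seed=seed)

    all_scores = pd.concat([s.features["program_scores"] for s in slides],
                           keys=[s.slide_id for s in slides])
    all_glom = pd.concat([s.annotations["glomerular"] for s in slides],
                         keys=[s.slide_id for s in slides])
    all_imm = pd.concat([s.features["composition"]["IMM"] for s in slides],
                        keys=[s.slide_id for s in slides])
    all_cond = pd.concat(
        [pd.Series(s.condition, index=s.coords.index) for s in slides],
        keys=[s.slide_id for s in slides])
    out["glom_enrichment"] = spatial.glomerular_enrichment(
        all_scores, all_glom, all_imm, all_cond)
    return out
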