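"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes — multi-group pseudobulk cohorts, archetype-
mixture single cells, longitudinal visit tables with flare events, spatial
lattices with immune niches, and weighted gene-set priors — can be simulated
here with known parameters, so that each downstream stage has a recoverable
answer: planted factor scores and loadings, a planted flare log-hazard, planted
archetype coordinates, and a planted co-localization sign.

All generators draw from a single ``numpy.random.default_rng`` stream seeded
from the call's seed; a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .pseudobulk import PseudobulkCohort
from .spatial import SpatialSlide

CELLTYPE_NAMES = ("B", "NK", "T4", "T8", "cM", "ncM", "cDC", "pDC", "Prolif")

#: Kidney deconvolution feature names used on spatial slides (immune + structural).
SPATIAL_CELLTYPES = ("IMM", "POD", "EC", "MES", "TUB")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the pseudobulk cohort generator.

    Defaults describe a three-batch cohort of 60 blood samples (half SLE, half
    healthy) profiled over five immune cell types, with two planted latent
    programs: one multicellular program shifted upward in cases, and one
    restricted to a single cell type.
    """

    n_groups: int = 3
    samples_per_group: int = 20
    n_celltypes: int = 5
    genes_per_celltype: int = 300
    n_factors_true: int = 2
    disease_effect: float = 1.5
    restricted_factor_celltype: str = "cM"
    noise_sd: float = 0.3
    composition_shift: float = 0.5
    seed: int = 0
    # Fraction of genes carrying non-zero loadings per factor, and loading SD.
    loading_density: float = 0.25
    loading_sd: float = 0.8

    def __post_init__(self) -> None:
        for name in ("n_groups", "samples_per_group", "n_celltypes",
                     "genes_per_celltype", "n_factors_true"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_celltypes > len(CELLTYPE_NAMES):
            raise ValueError(f"at most {len(CELLTYPE_NAMES)} cell types supported")
        if self.restricted_factor_celltype not in self.celltypes:
            raise ValueError(
                f"restricted_factor_celltype {self.restricted_factor_celltype!r} "
                f"not among generated cell types {self.celltypes}")
        if self.n_factors_true < 2:
            raise ValueError("need >= 2 factors (one multicellular, one restricted)")

    @property
    def celltypes(self) -> tuple[str, ...]:
        return CELLTYPE_NAMES[: self.n_celltypes]

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.samples_per_group


@dataclass
class GroundTruth:
    """Planted parameters recorded by the generators."""

    true_scores: pd.DataFrame | None = None          # sample x factor
    true_loadings: dict[str, pd.DataFrame] = field(default_factory=dict)
    flare_log_hazard: float = float("nan")
    planted_moran_sign: str = "none"                 # {"positive", "none"}
    archetype_coords_true: np.ndarray | None = None  # k x dim
    patient_scores: pd.Series | None = None          # per-patient program score


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_pseudobulk_cohort(cfg: SimConfig) -> tuple[PseudobulkCohort, GroundTruth]:
    """Simulate a multi-group pseudobulk cohort with planted latent programs.

    Counts for each cell-type view are Poisson around an exponentiated linear
    predictor ``baseline + loadings @ score + eps``. Factor 0 ("the
    multicellular program") loads on every cell type and its score is shifted
    by ``disease_effect`` SD in cases; factor 1 loads only on
    ``restricted_factor_celltype``; any further factors load everywhere with no
    condition shift. SLEDAI is a clipped 0-19 integer positively coupled to the
    multicellular score in cases.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    genes = _gene_names(cfg.genes_per_celltype)
    samples = [f"S{i:03d}" for i in range(n)]
    groups = np.repeat([f"batch{g}" for g in range(cfg.n_groups)],
                       cfg.samples_per_group)
    # Half cases per group, interleaved so every group has both conditions.
    condition = np.where(np.arange(n) % 2 == 0, "case", "control")

    scores = rng.standard_normal((n, cfg.n_factors_true))
    scores[condition == "case", 0] += cfg.disease_effect
    true_scores = pd.DataFrame(
        scores, index=samples,
        columns=[f"true_factor{j}" for j in range(cfg.n_factors_true)])

    views: dict[str, pd.DataFrame] = {}
    true_loadings: dict[str, pd.DataFrame] = {}
    for ct in cfg.celltypes:
        w = np.zeros((cfg.genes_per_celltype, cfg.n_factors_true))
        for j in range(cfg.n_factors_true):
            if j == 1 and ct != cfg.restricted_factor_celltype:
                continue
            n_loaded = max(2, int(round(cfg.loading_density * cfg.genes_per_celltype)))
            loaded = rng.choice(cfg.genes_per_celltype, size=n_loaded, replace=False)
            w[loaded, j] = rng.normal(0.0, cfg.loading_sd, size=n_loaded)
        baseline = rng.uniform(np.log(50.0), np.log(500.0),
                               size=cfg.genes_per_celltype)
        eta = (baseline[None, :] + scores @ w.T
               + rng.normal(0.0, cfg.noise_sd, size=(n, cfg.genes_per_celltype)))
        counts = rng.poisson(np.exp(eta))
        views[ct] = pd.DataFrame(counts, index=samples, columns=genes)
        true_loadings[ct] = pd.DataFrame(
            w, index=genes, columns=true_scores.columns)

    # Cell counts: ~3000 cells per sample, multinomial over cell types; cases
    # tilted toward the first cell type by composition_shift on the log scale.
    base_logit = rng.normal(0.0, 0.3, size=cfg.n_celltypes)
    cell_counts = np.zeros((cfg.n_celltypes, n), dtype=int)
    for s in range(n):
        logit = base_logit.copy()
        if condition[s] == "case":
            logit[0] += cfg.composition_shift
        p = np.exp(logit) / np.exp(logit).sum()
        cell_counts[:, s] = rng.multinomial(rng.poisson(3000), p)
    cell_counts_df = pd.DataFrame(cell_counts, index=list(cfg.celltypes),
                                  columns=samples)

    sledai_latent = 5.0 + 2.5 * scores[:, 0]
    sledai = np.clip(np.round(sledai_latent + rng.normal(0, 1, n)), 0, 19).astype(int)
    sledai[condition == "control"] = 0
    meta = pd.DataFrame(
        {
            "condition": condition,
            "group": groups,
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "age": np.clip(np.round(rng.normal(40, 12, n)), 18, 80).astype(int),
            "sex": rng.choice(["F", "M"], size=n, p=[0.85, 0.15]),
            "ancestry": rng.choice(["EUR", "AFR", "EAS", "AMR"], size=n),
            "SLEDAI": sledai,
            "anti_dsDNA": (condition == "case") & (rng.random(n) < 0.6),
            "renal": (condition == "case") & (rng.random(n) < 0.3),
        },
        index=samples,
    )

    pb = PseudobulkCohort(views=views, meta=meta, cell_counts=cell_counts_df)
    gt = GroundTruth(true_scores=true_scores, true_loadings=true_loadings)
    return pb, gt


def generate_single_cells(
    k: int,
    dim: int,
    cells_per_patient: int,
    n_patients: int,
    coupling: float,
    seed: int,
    *,
    noise_sd: float = 0.5,
    concentration: float = 1.0,
    n_genes: int = 100,
) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate single cells as Dirichlet mixtures of ``k`` planted archetypes.

    Each patient has a program score (cases shifted +1.5 SD); the Dirichlet
    concentration of their cells is tilted toward archetype 1 by
    ``exp(coupling * score)``. With ``concentration=0`` cells sit exactly on
    archetype vertices (up to ``noise_sd``). Expression is a fixed random
    linear read-out of the embedding.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > dim + 1:
        raise ValueError(f"k={k} archetypes cannot be affinely independent in "
                         f"dim={dim} (need k <= dim + 1)")
    rng = np.random.default_rng(seed)

    # Regular-simplex-like vertex set: scaled coordinate axes (k <= dim works;
    # k == dim + 1 adds the origin's reflection).
    a = np.zeros((k, dim))
    for j in range(min(k, dim)):
        a[j, j] = 4.0
    if k == dim + 1:
        a[dim, :] = -4.0 / np.sqrt(dim)

    condition = np.where(np.arange(n_patients) % 2 == 0, "SLE", "HC")
    score = rng.standard_normal(n_patients)
    score[condition == "SLE"] += 1.5
    patient_ids = [f"P{i:03d}" for i in range(n_patients)]

    n_cells = n_patients * cells_per_patient
    mixtures = np.empty((n_cells, k))
    patient_col = np.repeat(patient_ids, cells_per_patient)
    for i in range(n_patients):
        alpha = np.full(k, max(concentration, 1e-12))
        alpha[0] *= np.exp(coupling * score[i])
        rows = slice(i * cells_per_patient, (i + 1) * cells_per_patient)
        if concentration == 0:
            vert = rng.integers(0, k, size=cells_per_patient)
            s = np.zeros((cells_per_patient, k))
            s[np.arange(cells_per_patient), vert] = 1.0
        else:
            s = rng.dirichlet(alpha, size=cells_per_patient)
        mixtures[rows] = s

    embedding = mixtures @ a
    if noise_sd > 0:
        embedding = embedding + rng.normal(0.0, noise_sd, size=embedding.shape)

    readout = rng.normal(0.0, 1.0, size=(dim, n_genes)) / np.sqrt(dim)
    expr = embedding @ readout + rng.normal(0.0, 0.2, size=(n_cells, n_genes))

    adata = ad.AnnData(
        X=expr.astype(np.float64),
        obs=pd.DataFrame(
            {
                "patient_id": patient_col,
                "condition": np.repeat(condition, cells_per_patient),
                "program_score": np.repeat(score, cells_per_patient),
            },
            index=[f"cell{i:05d}" for i in range(n_cells)],
        ),
        var=pd.DataFrame(index=_gene_names(n_genes)),
    )
    adata.obsm["X_embed"] = embedding
    adata.obsm["true_mixture"] = mixtures

    gt = GroundTruth(
        archetype_coords_true=a,
        patient_scores=pd.Series(score, index=patient_ids, name="program_score"),
    )
    return adata, gt


def generate_longitudinal(
    n_patients: int,
    visits_per_patient: int,
    beta_flare: float,
    seed: int,
    *,
    base_hazard: float = 0.0025,
    n_signature_genes: int = 20,
    n_background_genes: int = 30,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate longitudinal SLE visits with program-dependent flare hazard.

    Each patient carries a latent program activity (patient random effect plus
    per-visit noise). Between scheduled visits (gaps of 55-85 days) a flare
    time is drawn from an exponential with per-day rate
    ``base_hazard * exp(beta_flare * activity)``; if it precedes the scheduled
    visit the patient is seen on the flare day with a >= 4-point SLEDAI jump,
    otherwise at the scheduled day in (near-)remission. Signature-gene z-scores
    scale with activity.
    """
    if visits_per_patient < 3:
        raise ValueError("visits_per_patient must be >= 3")
    rng = np.random.default_rng(seed)
    gene_cols = [f"sig_{g}" for g in _gene_names(n_signature_genes)]
    gene_cols += [f"bg_{g}" for g in _gene_names(n_background_genes)]
    gene_slope = np.concatenate([
        rng.uniform(0.5, 1.5, size=n_signature_genes),
        np.zeros(n_background_genes)])  # background genes carry no program

    rows = []
    for p in range(n_patients):
        u = rng.standard_normal()
        day = 0.0
        sledai = int(np.clip(rng.poisson(1.0), 0, 2))
        for v in range(visits_per_patient):
            activity = u + 0.3 * rng.standard_normal()
            expr = activity * gene_slope + rng.normal(0, 0.5, len(gene_cols))
            rows.append([f"P{p:03d}", day, sledai, activity, *expr])
            if v == visits_per_patient - 1:
                break
            gap = rng.uniform(55.0, 85.0)
            rate = base_hazard * np.exp(beta_flare * activity)
            t_flare = rng.exponential(1.0 / rate)
            if t_flare < gap:
                day += t_flare
                sledai = int(np.clip(sledai + 4 + rng.poisson(1.0), 0, 19))
            else:
                day += gap
                sledai = int(np.clip(rng.poisson(1.0), 0, 19))
    visits = pd.DataFrame(
        rows, columns=["patient_id", "day", "SLEDAI", "activity", *gene_cols])
    visits["day"] = visits["day"].round(2)
    gt = GroundTruth(flare_log_hazard=beta_flare)
    return visits, gt


def generate_spatial(
    n_slides: int,
    grid: tuple[int, int],
    niche_radius: float,
    coloc: float,
    seed: int,
    *,
    n_niches: int = 3,
    noise_sd: float = 1.0,
) -> tuple[list[SpatialSlide], GroundTruth]:
    """Simulate spatial slides with disk-shaped glomerular niches.

    Slides alternate case ("SLE") and control ("HC"). On case slides, immune
    abundance and the IFN program score are both elevated by ``coloc`` inside
    niches (plus noise), planting positive program-immune co-localization; on
    control slides all features are independent noise.
    """
    nx, ny = grid
    if min(nx, ny) <= 2 * niche_radius:
        raise ValueError("grid too small to contain a niche")
    rng = np.random.default_rng(seed)
    slides: list[SpatialSlide] = []
    programs = ["IFN", "NFkB", "T8cyto", "T4eff"]
    for s in range(n_slides):
        cond = "case" if s % 2 == 0 else "control"
        xs, ys = np.meshgrid(np.arange(nx, dtype=float),
                             np.arange(ny, dtype=float), indexing="ij")
        coords = pd.DataFrame(
            {"x": xs.ravel(), "y": ys.ravel()},
            index=[f"spot{i:04d}" for i in range(nx * ny)])
        centers = rng.uniform([niche_radius, niche_radius],
                              [nx - 1 - niche_radius, ny - 1 - niche_radius],
                              size=(n_niches, 2))
        d2 = ((coords[["x", "y"]].to_numpy()[:, None, :] - centers[None]) ** 2
              ).sum(axis=2)
        in_niche = (d2.min(axis=1) <= niche_radius ** 2)

        n_spots = len(coords)
        bump = coloc * in_niche.astype(float) if cond == "case" else 0.0
        prog = pd.DataFrame(
            rng.normal(0.0, noise_sd, size=(n_spots, len(programs))),
            index=coords.index, columns=programs)
        prog["IFN"] += bump

        abund = pd.DataFrame(
            rng.normal(0.0, noise_sd, size=(n_spots, len(SPATIAL_CELLTYPES))),
            index=coords.index, columns=list(SPATIAL_CELLTYPES))
        abund["IMM"] += bump

        comp_alpha = np.full(len(SPATIAL_CELLTYPES), 2.0)
        comp = rng.dirichlet(comp_alpha, size=n_spots)
        if cond == "case":
            # Tilt composition toward IMM inside niches.
            w = np.where(in_niche, 1.0 + coloc, 1.0)
            comp[:, 0] *= w
            comp /= comp.sum(axis=1, keepdims=True)
        comp_df = pd.DataFrame(comp, index=coords.index,
                               columns=list(SPATIAL_CELLTYPES))

        ann = pd.DataFrame({"glomerular": in_niche}, index=coords.index)
        slides.append(SpatialSlide(
            coords=coords,
            features={"program_scores": prog, "abundance": abund,
                      "composition": comp_df},
            annotations=ann,
            condition=cond,
            slide_id=f"slide{s}",
        ))
    gt = GroundTruth(planted_moran_sign="positive" if coloc > 0 else "none")
    return slides, gt


def generate_priors(
    n_lr: int,
    n_cytokines: int,
    n_proteins: int,
    seed: int,
    *,
    gene_universe: list[str] | None = None,
    celltypes: tuple[str, ...] = CELLTYPE_NAMES[:5],
    factor_loadings: dict[str, pd.DataFrame] | None = None,
    n_planted_genes: int = 20,
) -> dict[str, object]:
    """Generate prior-knowledge tables from the cohort gene universe.

    Returns a dict with:

    - ``"lr"``: ligand-receptor DataFrame (columns ligand, receptor);
    - ``"cytokines"``: weighted gene sets keyed ``(cytokine, celltype)``; when
      planted factor loadings are supplied, an ``IFN_like`` cytokine per cell
      type reuses that cell type's top multicellular-factor genes and weights,
      so its ULM activity tracks the planted score by construction;
    - ``"proteins"``: blood-protein DataFrame (gene, elevated_in_cases), with
      planted program genes flagged elevated when loadings are supplied.
    """
    if min(n_lr, n_cytokines) < 0 or n_proteins < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    universe = list(gene_universe) if gene_universe is not None else _gene_names(300)

    lig = rng.choice(universe, size=n_lr, replace=n_lr > len(universe) // 2)
    rec = rng.choice(universe, size=n_lr, replace=n_lr > len(universe) // 2)
    seen: set[tuple[str, str]] = set()
    lr_rows = []
    for l, r in zip(lig, rec):
        while (l, r) in seen or l == r:
            l, r = rng.choice(universe), rng.choice(universe)
        seen.add((l, r))
        lr_rows.append((l, r))
    lr = pd.DataFrame(lr_rows, columns=["ligand", "receptor"])

    cytokines: dict[tuple[str, str], pd.Series] = {}
    for ct in celltypes:
        if factor_loadings is not None and ct in factor_loadings:
            w = factor_loadings[ct].iloc[:, 0]
            top = w.abs().nlargest(n_planted_genes).index
            cytokines[("IFN_like", ct)] = w.loc[top].astype(float)
        for c in range(n_cytokines):
            members = rng.choice(universe, size=n_planted_genes, replace=False)
            cytokines[(f"cytokine{c}", ct)] = pd.Series(
                rng.standard_normal(n_planted_genes), index=members)

    protein_genes: list[str] = []
    elevated: list[bool] = []
    if n_proteins > 0:
        planted: list[str] = []
        if factor_loadings is not None:
            ct0 = next(iter(factor_loadings))
            w = factor_loadings[ct0].iloc[:, 0]
            planted = list(w.abs().nlargest(min(n_proteins // 2, n_planted_genes)).index)
        rest = [g for g in universe if g not in planted]
        extra = list(rng.choice(rest, size=max(n_proteins - len(planted), 0),
                                replace=False))
        protein_genes = planted + extra
        elevated = [True] * len(planted) + list(rng.random(len(extra)) < 0.5)
    proteins = pd.DataFrame({"gene": protein_genes, "elevated_in_cases": elevated})

    return {"lr": lr, "cytokines": cytokines, "proteins": proteins}


def config_from_dict(d: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a plain dict (e.g. parsed YAML)."""
    names = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(**d)
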