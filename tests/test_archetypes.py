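"""Archetypal analysis: geometry recovery, descent, projection, association."""

import numpy as np
import pandas as pd
import pytest

from mcprogram import archetypes as arch
from mcprogram import synthgen
from mcprogram._simplex import simplex_lstsq


def _vertex_data(k=3, dim=3, reps=30):
    verts = np.eye(dim)[:k] * 3.0
    return np.tile(verts, (reps, 1)), verts


class TestSimplexSolver:
    def test_interior_point_recovered(self, rng):
        basis = rng.standard_normal((4, 6))
        s_true = rng.dirichlet(np.ones(4))
        target = s_true @ basis
        s = simplex_lstsq(basis, target)
        assert np.allclose(s @ basis, target, atol=1e-6)
        assert s.sum() == pytest.approx(1.0, abs=1e-9)
        assert (s >= -1e-12).all()

    def test_matches_quadratic_program_oracle(self, rng):
        """Agreement with a dense grid search over the simplex (k=3)."""
        basis = rng.standard_normal((3, 2)) * 2
        target = rng.standard_normal(2) * 3
        s = simplex_lstsq(basis, target)
        best, best_val = None, np.inf
        ticks = np.linspace(0, 1, 201)
        for a in ticks:
            for b in ticks[ticks <= 1 - a + 1e-12]:
                cand = np.array([a, b, 1 - a - b])
                val = ((cand @ basis - target) ** 2).sum()
                if val < best_val:
                    best, best_val = cand, val
        got = ((s @ basis - target) ** 2).sum()
        assert got <= best_val + 1e-6


class TestFit:
    def test_exact_vertices_recovered(self):
        x, verts = _vertex_data()
        m = arch.fit_archetypes(x, k=3, seed=0)
        match = arch.match_archetypes(m.A, verts)
        err = np.linalg.norm(verts - m.A[match], axis=1).max()
        assert err < 1e-6

    def test_rss_monotone_descent(self, rng):
        x = rng.standard_normal((200, 4))
        m = arch.fit_archetypes(x, k=3, seed=1)
        hist = np.asarray(m.rss_history)
        assert (np.diff(hist) <= 1e-9 * np.maximum(hist[:-1], 1)).all()

    def test_dirichlet_mixture_recovery(self):
        hits, n_seeds = 0, 10
        for seed in range(n_seeds):
            adata, gt = synthgen.generate_single_cells(
                k=4, dim=5, cells_per_patient=50, n_patients=40,
                coupling=0.0, seed=seed)
            m = arch.fit_archetypes(adata.obsm["X_embed"], k=4, seed=seed)
            match = arch.match_archetypes(m.A, gt.archetype_coords_true)
            err = np.linalg.norm(
                gt.archetype_coords_true - m.A[match], axis=1).mean()
            diam = max(np.linalg.norm(a - b)
                       for a in gt.archetype_coords_true
                       for b in gt.archetype_coords_true)
            hits += err < 0.1 * diam
        assert hits >= 0.9 * n_seeds

    def test_beats_kmeans_on_vertex_data(self):
        from sklearn.cluster import KMeans

        x, _ = _vertex_data(reps=20)
        x = x + np.random.default_rng(0).normal(0, 0.05, x.shape)
        m = arch.fit_archetypes(x, k=3, seed=0)
        km = KMeans(n_clusters=3, n_init=5, random_state=0).fit(x)
        km_rss = ((x - km.cluster_centers_[km.labels_]) ** 2).sum()
        assert m.rss <= km_rss + 1e-9

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            arch.fit_archetypes(np.zeros((10, 2)), k=1)

    def test_scan_k_reports_elbow(self):
        x, _ = _vertex_data(k=3, dim=4, reps=40)
        x = x + np.random.default_rng(1).normal(0, 0.15, x.shape)
        out = arch.scan_k(x, range(2, 6), seed=0)
        assert set(out.columns) >= {"k", "rss", "elbow_criterion",
                                    "recommended"}
        assert (out["rss"].diff().dropna() <= 1e-6).all()  # rss decreases in k


class TestStability:
    def test_vertex_data_fully_stable(self):
        x, _ = _vertex_data(reps=40)
        stab = arch.bootstrap_stability(x, k=3, n_boot=5, seed=0)
        assert np.all(stab > 0.99)

    def test_noise_less_stable_than_structure(self):
        rng = np.random.default_rng(0)
        x, _ = _vertex_data(reps=40)
        noise = rng.standard_normal((120, 3))
        s_struct = arch.bootstrap_stability(x, k=3, n_boot=5, seed=1)
        s_noise = arch.bootstrap_stability(noise, k=3, n_boot=5, seed=1)
        assert s_struct.mean() > s_noise.mean()

    def test_single_resample_in_unit_interval(self):
        x, _ = _vertex_data()
        stab = arch.bootstrap_stability(x, k=3, n_boot=1, seed=0)
        assert ((stab >= 0) & (stab <= 1)).all()


class TestWeightsAndProfiles:
    def _model(self):
        x, verts = _vertex_data(k=3, dim=3, reps=10)
        return arch.fit_archetypes(x, k=3, seed=0)

    def test_weight_one_at_archetype_and_closed_form(self):
        m = self._model()
        w = arch.rbf_weights(m)
        # cells sitting exactly on archetypes get weight 1 for that archetype
        assert w.max() == pytest.approx(1.0, abs=1e-9)
        # closed form at d = lengthscale
        ell = m.lengthscale
        d = np.linalg.norm(m.embedding - m.A[0], axis=1)
        i = np.argmin(np.abs(d - ell))
        expected = np.exp(-d[i] ** 2 / (2 * ell ** 2))
        assert w[i, 0] == pytest.approx(expected, abs=1e-12)
        assert np.exp(-0.5) == pytest.approx(0.6065, abs=1e-4)

    def test_weights_decrease_with_distance(self):
        m = self._model()
        w = arch.rbf_weights(m)
        d = np.linalg.norm(m.embedding[:, None] - m.A[None], axis=2)
        order = np.argsort(d[:, 0])
        assert (np.diff(w[order, 0]) <= 1e-12).all()

    def test_profiles_equal_weighted_loop(self, rng):
        w = rng.random((50, 4))
        z = pd.DataFrame(rng.standard_normal((50, 20)),
                         columns=[f"g{i}" for i in range(20)])
        prof = arch.archetype_profiles(w, z)
        for c in range(4):
            manual = (z.to_numpy() * w[:, c:c + 1]).sum(0) / w[:, c].sum()
            assert np.allclose(prof.iloc[c], manual, atol=1e-10)

    def test_uniform_weights_give_column_means(self, rng):
        z = pd.DataFrame(rng.standard_normal((30, 5)))
        prof = arch.archetype_profiles(np.ones((30, 2)), z)
        assert np.allclose(prof.iloc[0], z.mean(0), atol=1e-12)

    def test_one_hot_weights_select_cell(self, rng):
        z = pd.DataFrame(rng.standard_normal((10, 5)))
        w = np.zeros((10, 1))
        w[3, 0] = 1.0
        prof = arch.archetype_profiles(w, z)
        assert np.allclose(prof.iloc[0], z.iloc[3], atol=1e-12)


class TestProjection:
    def test_interior_point_unchanged(self, rng):
        a = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        p = pd.DataFrame([[1.0, 1.0]])
        proj, dev, mix, d = arch.project_patient_means(p, a)
        assert dev.iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(proj.iloc[0], [1.0, 1.0], atol=1e-6)

    def test_vertex_projection_is_one_hot(self):
        a = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        p = pd.DataFrame([a[1]])
        proj, dev, mix, d = arch.project_patient_means(p, a)
        assert mix.iloc[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_idempotent(self, rng):
        a = rng.standard_normal((4, 3)) * 2
        p = pd.DataFrame(rng.standard_normal((6, 3)) * 4)
        proj1, _, _, _ = arch.project_patient_means(p, a)
        proj2, dev2, _, _ = arch.project_patient_means(proj1, a)
        assert np.allclose(proj1.to_numpy(), proj2.to_numpy(), atol=1e-5)
        assert (dev2 < 1e-5).all()


class TestAssociation:
    def test_exact_negative_relation_classed_sle(self, rng):
        d = pd.DataFrame({"arch0": rng.random(30) + 0.5,
                          "arch1": rng.random(30) + 0.5})
        scores = pd.Series(-d["arch0"].to_numpy(), index=d.index)
        res = arch.associate_archetype_program(d, scores)
        row = res.table.set_index("archetype").loc["arch0"]
        assert row["slope"] == pytest.approx(-1.0, abs=1e-8)
        assert row["class"] == "SLE"

    def test_hc3_matches_hat_matrix_formula(self, rng):
        """HC3 robust SE equals the explicit (X'X)^-1 X' diag(e²/(1-h)²) X
        (X'X)^-1 sandwich on a random 30-patient instance."""
        n = 30
        d = rng.random(n)
        y = 0.5 * d + rng.standard_normal(n) * (0.2 + d)
        dd = pd.DataFrame({"arch0": d})
        res = arch.associate_archetype_program(dd, pd.Series(y))
        x = np.column_stack([np.ones(n), d])
        xtx_inv = np.linalg.inv(x.T @ x)
        h = np.einsum("ij,jk,ik->i", x, xtx_inv, x)
        e = y - x @ (xtx_inv @ x.T @ y)
        meat = x.T @ np.diag(e ** 2 / (1 - h) ** 2) @ x
        se = np.sqrt((xtx_inv @ meat @ xtx_inv)[1, 1])
        assert res.table["se"].iloc[0] == pytest.approx(se, abs=1e-8)

    def test_calibration_under_null(self):
        """coupling=0: non-neutral calls stay near the FDR level."""
        calls, total = 0, 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            d = pd.DataFrame(rng.random((40, 4)),
                             columns=[f"arch{i}" for i in range(4)])
            scores = pd.Series(rng.standard_normal(40), index=d.index)
            res = arch.associate_archetype_program(d, scores)
            calls += (res.table["class"] != "neutral").sum()
            total += len(res.table)
        assert calls / total <= 0.07

    def test_freedman_lane_permutation_reasonable(self, rng):
        n = 40
        cov = pd.DataFrame({"age": rng.standard_normal(n)})
        d = pd.DataFrame({"arch0": rng.random(n)})
        y = pd.Series(-2.0 * d["arch0"] + 0.5 * cov["age"].to_numpy()
                      + rng.standard_normal(n) * 0.2)
        res = arch.associate_archetype_program(d, y, covariates=cov,
                                               n_perm=99, seed=0)
        assert res.table["p_perm"].iloc[0] <= 0.05

    def test_constant_distance_skipped(self, rng):
        d = pd.DataFrame({"arch0": np.ones(20),
                          "arch1": rng.random(20)})
        res = arch.associate_archetype_program(
            d, pd.Series(rng.standard_normal(20)))
        assert list(res.table["archetype"]) == ["arch1"]


class TestCytokinesAndProteins:
    def _profiles(self):
        genes = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.standard_normal((4, 20)),
                            index=[f"arch{i}" for i in range(4)],
                            columns=genes)
        return prof, genes

    def test_cosine_extremes(self):
        prof, genes = self._profiles()
        # two SLE archetypes with identical profiles -> identical activities
        prof.loc["arch1"] = prof.loc["arch0"]
        dictionary = {(f"c{i}", "cM"): pd.Series(
            np.random.default_rng(i).standard_normal(5),
            index=np.random.default_rng(i).choice(genes, 5, replace=False))
            for i in range(6)}
        cmap = pd.Series({a: "cM" for a in prof.index})
        classes = pd.Series({"arch0": "SLE", "arch1": "SLE", "arch2": "HC",
                             "arch3": "neutral"})
        res = arch.score_cytokines(prof, dictionary, cmap, classes, alpha=1.0)
        assert res.cosine.loc["arch0", "arch1"] == pytest.approx(1.0)
        assert res.cosine.loc["arch0", "arch0"] == pytest.approx(1.0)
        assert set(res.delta.columns) >= {"cytokine", "delta", "wilcoxon_p",
                                          "fdr", "significant"}

    def test_own_celltype_restriction(self):
        prof, genes = self._profiles()
        dictionary = {("c0", "B"): pd.Series([1.0, -1.0, 2.0],
                                             index=genes[:3])}
        cmap = pd.Series({a: "cM" for a in prof.index})
        classes = pd.Series({a: "neutral" for a in prof.index})
        with pytest.warns(UserWarning, match="no cytokine priors"):
            res = arch.score_cytokines(prof, dictionary, cmap, classes)
        assert res.activity.isna().all().all()

    @pytest.mark.parametrize("z_sle,z_hc,in_list,kept", [
        (0.5, 0.1, True, True),
        (0.5, 0.3, True, False),   # HC archetype above threshold
        (0.5, 0.1, False, False),  # not in protein list
        (0.1, 0.0, True, False),   # SLE below threshold
    ])
    def test_protein_rule(self, z_sle, z_hc, in_list, kept):
        prof_z = pd.DataFrame({"g1": [z_sle, z_hc]},
                              index=["arch0", "arch1"])
        classes = pd.Series({"arch0": "SLE", "arch1": "HC"})
        plist = pd.DataFrame({"gene": ["g1"] if in_list else ["other"],
                              "elevated_in_cases": [True]})
        out = arch.link_blood_proteins(prof_z, classes, plist)
        assert (["g1"] == out) is kept or (out == [] and not kept)

    def test_no_classes_rejected(self):
        prof_z = pd.DataFrame({"g1": [0.5]}, index=["arch0"])
        with pytest.raises(ValueError, match="class"):
            arch.link_blood_proteins(
                prof_z, pd.Series({"arch0": "neutral"}),
                pd.DataFrame({"gene": ["g1"], "elevated_in_cases": [True]}))
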