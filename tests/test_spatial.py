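"""Spatial weights, Moran's I, evidence aggregation, views and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mcprogram import spatial, synthgen


def _random_coords(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.uniform(0, 10, size=(n, 2)), columns=["x", "y"],
                        index=[f"s{i}" for i in range(n)])


class TestKnnWeights:
    def test_row_sums_and_s0(self):
        w = spatial.knn_weights(_random_coords(10), k=6)
        assert (w.w.sum(axis=1) == 6).all()
        assert w.s0 == 60
        assert np.diag(w.w).sum() == 0

    def test_collinear_tie_broken_by_lower_index(self):
        coords = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0]})
        w = spatial.knn_weights(coords, k=1)
        assert w.w[1, 0] == 1 and w.w[1, 2] == 0

    def test_matches_bruteforce_all_pairs_sort(self):
        coords = _random_coords(50, seed=3)
        w = spatial.knn_weights(coords, k=6).w
        x = coords.to_numpy()
        for i in range(50):
            d = np.array([np.inf if j == i else np.linalg.norm(x[i] - x[j])
                          for j in range(50)])
            expected = set(np.argsort(d, kind="stable")[:6])
            assert set(np.flatnonzero(w[i])) == expected

    def test_too_few_spots_rejected(self):
        with pytest.raises(ValueError, match="more than"):
            spatial.knn_weights(_random_coords(5), k=6)


class TestMoran:
    def test_matches_bruteforce_double_sum(self):
        rng = np.random.default_rng(1)
        coords = _random_coords(50, seed=1)
        w = spatial.knn_weights(coords, k=6)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        i_fast = spatial.bivariate_moran(x, y, w)
        zx, zy = x - x.mean(), y - y.mean()
        num = sum(w.w[i, j] * zx[i] * zy[j]
                  for i in range(50) for j in range(50))
        i_brute = (50 / w.s0) * num / np.sqrt((zx ** 2).sum() * (zy ** 2).sum())
        assert i_fast == pytest.approx(i_brute, abs=1e-12)

    def test_complete_graph_self_moran_closed_form(self):
        n = 12
        w = np.ones((n, n)) - np.eye(n)
        wt = spatial.SpatialWeights(w=w, k=n - 1)
        x = np.random.default_rng(0).standard_normal(n)
        assert spatial.bivariate_moran(x, x, wt) == pytest.approx(
            -1.0 / (n - 1), abs=1e-12)

    def test_bivariate_reduces_to_univariate(self):
        coords = _random_coords(40, seed=2)
        w = spatial.knn_weights(coords, k=6)
        x = np.random.default_rng(2).standard_normal(40)
        # univariate Moran's I computed directly
        z = x - x.mean()
        i_uni = (40 / w.s0) * (z @ w.w @ z) / (z @ z)
        assert spatial.bivariate_moran(x, x, w) == pytest.approx(i_uni,
                                                                 abs=1e-12)

    def test_zero_variance_rejected(self):
        w = spatial.knn_weights(_random_coords(10), k=3)
        with pytest.raises(ValueError, match="zero-variance"):
            spatial.bivariate_moran(np.ones(10),
                                    np.random.default_rng(0).random(10), w)


class TestPermutation:
    def test_floor_is_one_over_nperms_plus_one(self):
        """Forced-extreme observed statistic hits exactly p = 1/101."""
        slides, _ = synthgen.generate_spatial(1, (10, 10), 2.0, 50.0, seed=0,
                                              noise_sd=0.01)
        s = slides[0]
        w = spatial.knn_weights(s.coords, k=6)
        i_obs, p = spatial.moran_permutation_p(
            s.features["program_scores"]["IFN"].to_numpy(),
            s.features["abundance"]["IMM"].to_numpy(), w, n_perms=100, seed=0)
        assert p == pytest.approx(1 / 101)

    def test_p_values_on_achievable_grid(self):
        coords = _random_coords(30, seed=5)
        w = spatial.knn_weights(coords, k=4)
        rng = np.random.default_rng(5)
        for seed in range(10):
            x, y = rng.standard_normal(30), rng.standard_normal(30)
            _, p = spatial.moran_permutation_p(x, y, w, n_perms=100, seed=seed)
            assert p >= 1 / 101
            assert (p * 101) == pytest.approx(round(p * 101), abs=1e-9)

    def test_fixed_seed_reproducible(self):
        coords = _random_coords(30, seed=6)
        w = spatial.knn_weights(coords, k=4)
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        p1 = spatial.moran_permutation_p(x, y, w, seed=9)
        p2 = spatial.moran_permutation_p(x, y, w, seed=9)
        assert p1 == p2


class TestAggregation:
    def test_single_slide_passthrough(self):
        per = pd.DataFrame([("IMM", "IFN", "case", "s0", 0.2, 0.03)],
                           columns=["celltype", "program", "condition",
                                    "slide", "I", "p"])
        out = spatial.aggregate_colocalization(per)
        assert out["p_combined"].iloc[0] == pytest.approx(0.03, abs=1e-12)

    def test_two_extreme_ps_chi_square_oracle(self):
        per = pd.DataFrame([
            ("IMM", "IFN", "case", "s0", 0.3, 1 / 101),
            ("IMM", "IFN", "case", "s1", 0.3, 1 / 101)],
            columns=["celltype", "program", "condition", "slide", "I", "p"])
        out = spatial.aggregate_colocalization(per)
        chi2 = -2 * 2 * np.log(1 / 101)
        assert chi2 == pytest.approx(18.46, abs=0.01)
        assert out["p_combined"].iloc[0] == pytest.approx(
            stats.chi2.sf(chi2, 4), rel=1e-9)
        assert out["p_combined"].iloc[0] == pytest.approx(1.0e-3, abs=2e-4)

    def test_effect_size_gate(self):
        per = pd.DataFrame([("IMM", "IFN", "case", "s0", 0.09, 0.001)],
                           columns=["celltype", "program", "condition",
                                    "slide", "I", "p"])
        out = spatial.aggregate_colocalization(per)
        assert not out["significant"].iloc[0]

    def test_fisher_combination_uniform_under_null(self):
        rng = np.random.default_rng(0)
        combined = []
        for _ in range(300):
            ps = rng.uniform(size=3)
            combined.append(stats.chi2.sf(-2 * np.log(ps).sum(), 6))
        assert stats.kstest(combined, "uniform").pvalue > 0.01


class TestBuildViews:
    def _slide(self):
        slides, _ = synthgen.generate_spatial(1, (12, 12), 2.0, 1.0, seed=4)
        return slides[0]

    def test_zero_threshold_applied_before_clr(self):
        s = self._slide()
        comp = s.features["composition"].copy()
        comp.iloc[0, 0] = 0.04
        intra, _, _ = spatial.build_views(comp, s.coords,
                                          s.annotations["glomerular"])
        # a zeroed entry becomes log(pseudocount)-driven, far below the rest
        assert intra.iloc[0, 0] < -10

    def test_uniform_composition_gives_zero_clr(self):
        s = self._slide()
        comp = pd.DataFrame(0.2, index=s.coords.index,
                            columns=list("ABCDE"))
        comp += np.random.default_rng(0).normal(0, 1e-3, comp.shape)
        intra, _, _ = spatial.build_views(comp.clip(lower=0.06), s.coords,
                                          s.annotations["glomerular"])
        assert np.abs(intra.to_numpy()).max() < 0.1

    def test_isolated_spot_paraview_zero(self):
        coords = pd.DataFrame({"x": [0, 1, 2, 50.0], "y": [0, 0, 0, 0]},
                              index=list("abcd"))
        comp = pd.DataFrame(
            np.random.default_rng(0).dirichlet(np.ones(3), 4) + 0.06,
            index=coords.index, columns=["A", "B", "C"])
        glom = pd.Series([True, False, False, False], index=coords.index)
        with pytest.warns(UserWarning, match="no neighbour"):
            _, para, _ = spatial.build_views(comp, coords, glom)
        assert np.allclose(para.loc["d"], 0.0)

    def test_mask_includes_neighbours(self):
        s = self._slide()
        intra, para, mask = spatial.build_views(
            s.features["composition"], s.coords, s.annotations["glomerular"])
        assert mask.sum() > s.annotations["glomerular"].sum()

    def test_no_glomeruli_rejected(self):
        s = self._slide()
        glom = pd.Series(False, index=s.coords.index)
        with pytest.raises(ValueError, match="glomerular"):
            spatial.build_views(s.features["composition"], s.coords, glom)


class TestMultiview:
    def test_copied_predictor_dominates_importance(self):
        rng = np.random.default_rng(0)
        n = 120
        idx = [f"s{i}" for i in range(n)]
        intra = pd.DataFrame(rng.standard_normal((n, 4)),
                             columns=["T", "A", "B", "C"], index=idx)
        intra["T"] = intra["A"]  # target copies predictor A
        para = pd.DataFrame(rng.standard_normal((n, 2)),
                            columns=["pA", "pB"], index=idx)
        res = spatial.fit_multiview(intra, para, target="T", seed=0)
        imp = pd.concat([res["importances"]["intra"],
                         res["importances"]["para"]])
        assert res["importances"]["intra"]["A"] > 0.5 * imp.sum()
        assert res["contributions"]["intra"] > res["contributions"]["para"]

    def test_noise_target_near_zero_contributions(self):
        rng = np.random.default_rng(1)
        n = 100
        intra = pd.DataFrame(rng.standard_normal((n, 4)),
                             columns=["T", "A", "B", "C"])
        para = pd.DataFrame(rng.standard_normal((n, 2)),
                            columns=["pA", "pB"])
        res = spatial.fit_multiview(intra, para, target="T", seed=1)
        assert res["r2"]["both"] <= 0.05
        assert res["contributions"]["intra"] <= 0.05
        assert res["contributions"]["para"] <= 0.05

    def test_spot_order_invariance(self):
        rng = np.random.default_rng(2)
        n = 60
        idx = [f"s{i:02d}" for i in range(n)]
        intra = pd.DataFrame(rng.standard_normal((n, 3)),
                             columns=["T", "A", "B"], index=idx)
        para = pd.DataFrame(rng.standard_normal((n, 2)),
                            columns=["pA", "pB"], index=idx)
        r1 = spatial.fit_multiview(intra, para, "T", seed=5)
        perm = rng.permutation(n)
        r2 = spatial.fit_multiview(intra.iloc[perm], para.iloc[perm], "T",
                                   seed=5)
        assert r1["r2"]["both"] == pytest.approx(r2["r2"]["both"])

    def test_too_few_spots_rejected(self):
        intra = pd.DataFrame(np.zeros((5, 2)), columns=["T", "A"])
        para = pd.DataFrame(np.zeros((5, 1)), columns=["p"])
        with pytest.raises(ValueError, match=">= 20"):
            spatial.fit_multiview(intra, para, "T")


class TestGlomerularEnrichment:
    def _inputs(self, shift, n=100, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(2 * n)]
        scores = pd.DataFrame({"IFN": rng.standard_normal(2 * n)}, index=idx)
        cond = pd.Series(["case"] * n + ["control"] * n, index=idx)
        scores.loc[cond == "case", "IFN"] += shift
        glom = pd.Series(True, index=idx)
        imm = pd.Series(0.2, index=idx)
        return scores, glom, imm, cond

    def test_identical_distributions_null_t(self):
        scores, glom, imm, cond = self._inputs(0.0)
        out = spatial.glomerular_enrichment(scores, glom, imm, cond)
        assert abs(out["t"].iloc[0]) < 3

    def test_shifted_cases_detected(self):
        hits = 0
        for seed in range(5):
            scores, glom, imm, cond = self._inputs(1.0, seed=seed)
            out = spatial.glomerular_enrichment(scores, glom, imm, cond)
            hits += out["t"].iloc[0] > 5
        assert hits >= 4

    def test_zero_immune_spots_excluded_and_clamping(self):
        scores, glom, imm, cond = self._inputs(1.0)
        imm.iloc[:10] = 0.0
        out = spatial.glomerular_enrichment(scores, glom, imm, cond)
        viz = out.attrs["viz_scores"]
        assert (viz.to_numpy() >= 0).all()

    def test_single_condition_rejected(self):
        scores, glom, imm, cond = self._inputs(0.0)
        cond[:] = "case"
        with pytest.raises(ValueError, match="both conditions"):
            spatial.glomerular_enrichment(scores, glom, imm, cond)


class TestPlantedColocalization:
    def test_case_positive_control_null(self):
        """Planted niches give positive I in cases and ~0 in controls."""
        case_sig, ctrl_null, n_seeds = 0, 0, 10
        for seed in range(n_seeds):
            slides, _ = synthgen.generate_spatial(
                2, (15, 15), 2.5, 2.0, seed=seed)
            per = spatial.colocalize_slides(slides, programs=["IFN"],
                                            celltypes=["IMM"], seed=seed)
            case_i = per[per["condition"] == "case"]["I"].mean()
            ctrl_i = per[per["condition"] == "control"]["I"].mean()
            case_sig += case_i > 0.1
            ctrl_null += abs(ctrl_i) < 0.1
        assert case_sig >= 0.8 * n_seeds
        assert ctrl_null >= 0.8 * n_seeds

    def test_null_coloc_mean_i_small(self):
        vals = []
        for seed in range(15):
            slides, _ = synthgen.generate_spatial(
                1, (12, 12), 2.0, 0.0, seed=seed)
            w = spatial.knn_weights(slides[0].coords, k=6)
            vals.append(spatial.bivariate_moran(
                slides[0].features["program_scores"]["IFN"].to_numpy(),
                slides[0].features["abundance"]["IMM"].to_numpy(), w))
        assert abs(np.mean(vals)) < 0.05
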