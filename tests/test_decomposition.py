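from itertools import permutations

import numpy as np
import pytest

from wmconn.decomposition import (
    DScoreMatrix,
    _mixed_anova_F,
    align_to_reference,
    cluster_summed_dscores,
    d_scores,
    ks_model_vs_other_connections,
    kw_per_connection_fdr,
    perm_two_way_anova,
    z_scores,
)
from wmconn.model import SparseBayesianRegression


def _manual_model(coef: dict, n_features: int) -> SparseBayesianRegression:
    est = SparseBayesianRegression()
    est.coef_ = np.zeros(n_features)
    for i, c in coef.items():
        est.coef_[i] = c
    est.intercept_ = 1.3
    est.support_ = np.array(sorted(coef), dtype=int)
    est.n_features_in_ = n_features
    return est


class TestAlignment:
    def test_identity_when_source_equals_reference(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(30, 5))
        ac, ap, amap = align_to_reference(ref, ref[:10] + 0.0, ref)
        assert np.allclose(ac, ref, atol=1e-12)
        assert np.allclose(amap.mu_src, amap.mu_ref)
        assert np.allclose(amap.sigma_src, amap.sigma_ref)

    def test_arithmetic_example(self):
        """Controls ~ N(0,1) mapped to reference N(5,2): 1 -> 7, 2 -> 9."""
        rng = np.random.default_rng(1)
        n = 200_000
        ctl = rng.normal(0, 1, (n, 1))
        ref = rng.normal(5, 2, (n, 1))
        pat = np.array([[2.0]])
        ac, ap, amap = align_to_reference(ctl, pat, ref)
        one_mapped = amap.apply(np.array([[1.0]]))[0, 0]
        assert one_mapped == pytest.approx(7.0, abs=0.05)
        assert ap[0, 0] == pytest.approx(9.0, abs=0.05)
        # aligned controls reproduce the reference moments exactly
        assert ac.mean() == pytest.approx(ref.mean(), abs=1e-10)
        assert ac.std(ddof=1) == pytest.approx(ref.std(ddof=1), abs=1e-10)

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(2)
        ctl = rng.normal(2, 3, (40, 8))
        pat = rng.normal(1, 2, (25, 8))
        ref = rng.normal(0, 1, (60, 8))
        ac, ap, amap = align_to_reference(ctl, pat, ref)
        assert np.allclose(amap.invert(ac), ctl, atol=1e-12)
        assert np.allclose(amap.invert(ap), pat, atol=1e-12)

    def test_zero_control_sd_names_connection(self):
        ctl = np.ones((10, 3))
        ctl[:, 0] = np.arange(10.0)
        ctl[:, 2] = np.arange(10.0)
        with pytest.raises(ValueError, match="featB"):
            align_to_reference(ctl, ctl[:2], ctl,
                               feature_labels=["featA", "featB", "featC"])


class TestDScores:
    def test_patient_at_control_mean_gives_zero(self):
        model = _manual_model({0: 2.0, 2: -1.0}, 4)
        rng = np.random.default_rng(3)
        ctl = rng.normal(size=(50, 4))
        pat = np.tile(ctl.mean(axis=0), (3, 1))
        D = d_scores(model, pat, ctl)
        assert np.allclose(D.values, 0.0, atol=1e-12)

    def test_arithmetic_example(self):
        """w = 2, x_patient = 0.5, control mean 0.3 -> D = 0.4."""
        model = _manual_model({0: 2.0}, 2)
        ctl = np.array([[0.2, 0.0], [0.4, 0.0]])
        pat = np.array([[0.5, 9.9]])
        D = d_scores(model, pat, ctl)
        assert D.values[0, 0] == pytest.approx(0.4)

    def test_row_sums_equal_predicted_deviation(self, fitted_model, atlas18,
                                                ground_truth):
        from wmconn.simulate import simulate_cohort

        recs = simulate_cohort(30, ("HC", "SCZ"), ground_truth, atlas18, seed=41)
        fc = np.vstack([r.fc for r in recs])
        ctl, pat = fc[:30], fc[30:]
        D = d_scores(fitted_model, pat, ctl)
        lhs = D.values.sum(axis=1)
        rhs = fitted_model.predict(pat) - fitted_model.predict(ctl).mean()
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_planted_shift_concentrates_on_shifted_connection(self):
        """A mean shift planted on one weighted connection dominates the
        diagnosis-mean D-scores."""
        rng = np.random.default_rng(4)
        model = _manual_model({1: 1.0, 3: 1.0, 5: 1.0}, 8)
        ctl = rng.normal(0, 0.1, (400, 8))
        pat = rng.normal(0, 0.1, (400, 8))
        pat[:, 3] += 0.5
        D = d_scores(model, pat, ctl)
        mean_d = np.abs(D.values.mean(axis=0))
        col = list(D.feature_indices).index(3)
        others = np.delete(mean_d, col)
        assert mean_d[col] > 5 * others.max()

    def test_empty_control_group_rejected(self):
        model = _manual_model({0: 1.0}, 2)
        with pytest.raises(ValueError, match="empty control"):
            d_scores(model, np.ones((2, 2)), np.empty((0, 2)))


class TestZScores:
    def test_z_is_d_over_control_sd(self):
        model = _manual_model({0: 2.0}, 1)
        ctl = np.array([[0.2], [0.4]])  # weighted FC SD = 2*0.1414 = 0.2*sqrt(2)/2...
        D = d_scores(model, np.array([[0.5]]), ctl)
        Z = z_scores(D, ctl, model)
        sd = np.std([0.4, 0.8], ddof=1)
        assert Z[0, 0] == pytest.approx(D.values[0, 0] / sd)

    def test_controls_self_standardized(self, fitted_model, training_cohort):
        _, X, _ = training_cohort
        ctl = X[:40]
        D = d_scores(fitted_model, ctl, ctl)
        Z = z_scores(D, ctl, fitted_model)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.abs(Z.std(axis=0, ddof=1) - 1.0).max() < 1e-10

    def test_zero_d_gives_zero_z(self):
        model = _manual_model({0: 1.0}, 1)
        ctl = np.array([[0.1], [0.3], [0.5]])
        D = d_scores(model, ctl.mean(axis=0, keepdims=True), ctl)
        Z = z_scores(D, ctl, model)
        assert Z[0, 0] == pytest.approx(0.0, abs=1e-12)


class TestPermTwoWayAnova:
    def test_exhaustive_enumeration_for_small_n(self):
        """With <= 6 subjects the main-effect p equals brute-force
        enumeration over all row-label permutations."""
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(6, 4))
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        res = perm_two_way_anova(Z, labels, n_perm_main=1000, n_perm_inter=100,
                                 seed=0, posthoc=False)
        codes = (labels == "B").astype(int)
        F_obs, _ = _mixed_anova_F(Z, codes, 2)
        count = 0
        for perm in permutations(range(6)):
            Fp, _ = _mixed_anova_F(Z[list(perm)], codes, 2)
            count += Fp >= F_obs - 1e-12
        assert res.p_main == pytest.approx(count / 720)

    def test_null_main_effect_uniform(self):
        """Exchangeable diagnoses: permutation p_main is uniform (KS)."""
        from scipy import stats as sst

        rng = np.random.default_rng(6)
        ps = []
        for _ in range(500):
            Z = rng.normal(size=(30, 6))
            labels = np.repeat(["a", "b", "c"], 10)
            res = perm_two_way_anova(Z, labels, n_perm_main=199, n_perm_inter=100,
                                     seed=int(rng.integers(1 << 30)), posthoc=False)
            ps.append(res.p_main)
        assert sst.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_main_effect_detected_interaction_null(self):
        """Diagnosis-specific constant offsets across all connections: small
        p_main, interaction p stays non-significant."""
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(60, 8))
        labels = np.repeat(["a", "b", "c"], 20)
        Z[20:40] += 1.0
        Z[40:] -= 1.0
        res = perm_two_way_anova(Z, labels, n_perm_main=999, n_perm_inter=999,
                                 seed=1, posthoc=True)
        assert res.p_main <= 0.01
        assert res.p_interaction > 0.05
        flagged = {frozenset((d["group1"], d["group2"]))
                   for d in res.posthoc_pairs if d["p_perm"] < 0.05}
        assert frozenset(("a", "c")) in flagged

    def test_planted_interaction_detected(self):
        """Crossed diagnosis-by-connection offsets with zero marginal means
        produce a small interaction p."""
        rng = np.random.default_rng(8)
        Z = rng.normal(0, 0.5, size=(40, 4))
        labels = np.repeat(["a", "b"], 20)
        Z[:20, 0] += 1.0
        Z[:20, 1] -= 1.0
        Z[20:, 0] -= 1.0
        Z[20:, 1] += 1.0
        res = perm_two_way_anova(Z, labels, n_perm_main=199, n_perm_inter=999,
                                 seed=2, posthoc=False)
        assert res.p_interaction <= 0.01

    def test_global_shuffle_scheme_also_calibrated(self):
        rng = np.random.default_rng(9)
        Z = rng.normal(size=(20, 5))
        labels = np.repeat(["a", "b"], 10)
        res = perm_two_way_anova(Z, labels, n_perm_main=199, n_perm_inter=199,
                                 seed=3, posthoc=False,
                                 interaction_shuffle="global")
        assert 0.0 < res.p_interaction <= 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="n_perm"):
            perm_two_way_anova(np.ones((10, 3)), np.repeat(["a", "b"], 5),
                               n_perm_main=10, n_perm_inter=10)
        with pytest.raises(ValueError, match="diagnoses"):
            perm_two_way_anova(np.ones((4, 3)), np.repeat("a", 4))


class TestKruskalWallisFDR:
    def test_hand_computed_rank_statistic(self):
        """Groups {1,2,3} vs {4,5,6}: H = 27/7 ~ 3.857."""
        Z = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        labels = np.repeat(["a", "b"], 3)
        res = kw_per_connection_fdr(Z, labels)
        assert res["chi_square"][0] == pytest.approx(27 / 7, abs=1e-10)

    def test_all_tied_column_warns(self):
        Z = np.column_stack([np.ones(8), np.arange(8.0)])
        with pytest.warns(UserWarning, match="all-tied"):
            res = kw_per_connection_fdr(Z, np.repeat(["a", "b"], 4))
        assert res["chi_square"][0] == 0.0
        assert res["p"][0] == 1.0

    def test_null_fdr_yields_no_discoveries(self):
        """Identical group distributions over 16 connections: about zero
        BH-FDR discoveries on average across seeds."""
        rng = np.random.default_rng(10)
        counts = []
        for _ in range(30):
            Z = rng.normal(size=(60, 16))
            res = kw_per_connection_fdr(Z, np.repeat(["a", "b", "c"], 20))
            counts.append(int(res["significant"].sum()))
        assert np.mean(counts) < 0.5

    def test_separated_connection_flagged_with_power(self):
        """A 1.5-SD group separation on one connection (n=50/group) is
        flagged in >= 90% of simulations."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 30
        for _ in range(reps):
            Z = rng.normal(size=(100, 10))
            Z[50:, 4] += 1.5
            res = kw_per_connection_fdr(Z, np.repeat(["a", "b"], 50))
            hits += bool(res["significant"][4]) and res["significant"].sum() == 1
        assert hits / reps >= 0.9


class TestKSComparison:
    def test_identical_samples(self):
        x = np.arange(10.0)
        stat, p = ks_model_vs_other_connections(x, x.copy())
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stat, _ = ks_model_vs_other_connections(np.arange(5.0),
                                                np.arange(10.0, 15.0))
        assert stat == 1.0

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(12)
        rej = 0
        reps = 2000
        for _ in range(reps):
            stat, p = ks_model_vs_other_connections(
                rng.normal(size=16), rng.normal(size=155)
            )
            rej += p <= 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_model_vs_other_connections(np.array([]), np.arange(3.0))


class TestClusterSummedDScores:
    def test_single_bridging_connection_counted_in_both_clusters(self, atlas18):
        # networks 0 (fronto-parietal) and 11 (cerebellum) bridge clusters
        feat = atlas18.feature_index(0, 11)
        D = DScoreMatrix(
            values=np.full((4, 1), -0.3),
            feature_indices=np.array([feat]),
            diagnosis=np.repeat("SCZ", 4),
        )
        out = cluster_summed_dscores(D, atlas18).set_index("cluster")
        assert set(out.index) == {"fronto-parietal", "cerebellum"}
        assert out.loc["fronto-parietal", "summed_d"] == pytest.approx(-0.3)
        assert out.loc["cerebellum", "summed_d"] == pytest.approx(-0.3)

    def test_within_cluster_connections_excluded(self, atlas18):
        # network 0 within-network feature and 0-1 (both fronto-parietal)
        feats = np.array([atlas18.feature_index(0), atlas18.feature_index(0, 1)])
        D = DScoreMatrix(
            values=np.ones((3, 2)),
            feature_indices=feats,
            diagnosis=np.repeat("MDD", 3),
        )
        out = cluster_summed_dscores(D, atlas18)
        assert out.empty

    def test_untouched_cluster_absent(self, atlas18):
        """Clusters with no selected bridging connection (here default-mode)
        do not appear in the summary."""
        feat = atlas18.feature_index(0, 11)
        D = DScoreMatrix(
            values=np.ones((2, 1)),
            feature_indices=np.array([feat]),
            diagnosis=np.repeat("OCD", 2),
        )
        out = cluster_summed_dscores(D, atlas18)
        assert "default-mode" not in set(out["cluster"])

    def test_missing_diagnosis_labels_rejected(self, atlas18):
        D = DScoreMatrix(values=np.ones((2, 1)),
                         feature_indices=np.array([20]))
        with pytest.raises(ValueError, match="diagnosis"):
            cluster_summed_dscores(D, atlas18)
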