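"""Constrained-mixture EM, BIC selection and controlled MAP assignment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mapktome import (
    Assignment,
    expected_misassigned,
    fit_vee_em,
    gen_mixture_profiles,
    select_K,
    summarise_clusters,
    threshold_map_assign,
)
from mapktome.mixture import MixtureModel


def three_component_overlapping(seed, n=2000, d=2):
    """Moderately overlapping mixture: means about two SDs apart, free volumes."""
    from mapktome import unit_det_shape

    C = unit_det_shape(np.array([[1.0, 0.25], [0.25, 1.0]]))
    means = np.array([[0.0, 0.0], [2.2, 0.0], [0.0, 2.2]])
    X, labels = gen_mixture_profiles(
        n, d, 3, [0.3, 0.4, 0.3], means, [0.7, 1.0, 1.5], C, seed=seed
    )
    return X.to_numpy(), labels


class TestFitVeeEm:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 3)) @ np.diag([1.0, 2.0, 0.5]) + [1.0, -1.0, 0.0]
        model = fit_vee_em(X, 1, n_starts=1, seed=0)
        S = np.cov(X.T, bias=True)
        lam = np.linalg.det(S) ** (1 / 3)
        np.testing.assert_allclose(model.means[0], X.mean(axis=0), atol=1e-8)
        assert model.volumes[0] == pytest.approx(lam, rel=1e-6)
        np.testing.assert_allclose(model.shape, S / lam, atol=1e-6)

    def test_well_separated_components_fully_recovered(self, shape2):
        means = np.array([[0.0, 0.0], [30.0, 30.0]])
        X, labels = gen_mixture_profiles(
            600, 2, 2, [0.4, 0.6], means, [1.0, 1.0], shape2, seed=2
        )
        model = fit_vee_em(X.to_numpy(), 2, n_starts=3, seed=1)
        post = model.predict_proba(X.to_numpy())
        assert adjusted_rand_score(labels, post.argmax(axis=1)) == 1.0

    def test_parameter_recovery_volumes_and_shape(self, shape2):
        means = np.array([[0.0, 0.0], [6.0, 6.0]])
        X, _ = gen_mixture_profiles(
            5000, 2, 2, [0.5, 0.5], means, [1.0, 4.0], shape2, seed=3
        )
        model = fit_vee_em(X.to_numpy(), 2, n_starts=4, seed=5)
        ratio = model.volumes.max() / model.volumes.min()
        assert abs(ratio - 4.0) < 0.15 * 4.0
        assert np.linalg.norm(model.shape - shape2, "fro") < 0.1

    def test_loglik_monotone_along_em(self):
        X, _ = three_component_overlapping(seed=4, n=800)
        model = fit_vee_em(X, 3, n_starts=2, seed=7)
        trace = np.array(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9 * np.abs(trace[:-1]))

    def test_constraints_hold_after_fit(self):
        X, _ = three_component_overlapping(seed=5, n=1000)
        model = fit_vee_em(X, 3, n_starts=2, seed=8)
        assert np.linalg.det(model.shape) == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(model.shape, model.shape.T)
        assert np.all(np.linalg.eigvalsh(model.shape) > 0)
        post = model.predict_proba(X)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_needs_enough_observations(self):
        with pytest.raises(ValueError):
            fit_vee_em(np.zeros((5, 3)), 2, seed=0)


class TestSelectK:
    def test_bic_selects_true_component_count(self):
        from mapktome import unit_det_shape

        C = unit_det_shape(np.array([[1.0, 0.2], [0.2, 1.0]]))
        means = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
        X, _ = gen_mixture_profiles(
            1500, 2, 3, [0.3, 0.3, 0.4], means, [1.0, 2.0, 0.5], C, seed=6
        )
        model, trace = select_K(X.to_numpy(), K_range=range(2, 7), n_starts=3, seed=2)
        assert model.K == 3
        assert set(trace["K"]) == {2, 3, 4, 5, 6}

    def test_parameter_count_increases_with_K(self):
        d = 7
        counts = [
            MixtureModel(
                weights=np.full(K, 1 / K), means=np.zeros((K, d)),
                volumes=np.ones(K), shape=np.eye(d), loglik=0.0,
            ).n_params
            for K in range(1, 10)
        ]
        assert np.all(np.diff(counts) > 0)
        # K components in d dims: (K-1) + Kd + K volumes + shared shape
        assert counts[0] == 0 + 7 + 1 + (7 * 8 // 2 - 1)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_K(np.zeros((10, 2)), K_range=[])


class TestThresholdMapAssign:
    def test_perfect_posteriors_classify_everything(self):
        model = MixtureModel(
            weights=np.array([0.5, 0.5]),
            means=np.array([[-50.0], [50.0]]),
            volumes=np.array([1.0, 1.0]),
            shape=np.eye(1),
            loglik=0.0,
        )
        X = np.concatenate([np.full(20, -50.0), np.full(20, 50.0)])[:, None]
        out = threshold_map_assign(model, X, alpha=0.05)
        assert out.n_classified == 40
        assert out.fap == pytest.approx(0.0, abs=1e-12)
        assert out.tau < 1.0

    def test_misclassification_controlled_on_overlapping_mixture(self):
        X, labels = three_component_overlapping(seed=11, n=5000)
        model = fit_vee_em(X, 3, n_starts=3, seed=12)
        out = threshold_map_assign(model, X, alpha=0.05)
        mask = out.table["classified"].to_numpy()
        assert mask.sum() > 100
        assigned = out.table["label"].to_numpy()[mask]
        true = labels[mask]
        # components are unordered: map each fitted label to its best truth match
        err = _best_mismatch_rate(true, assigned)
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / mask.sum())
        assert err <= bound

    def test_control_property_across_replicates(self):
        errors = []
        for seed in range(50):
            X, labels = three_component_overlapping(seed=100 + seed, n=2500)
            model = fit_vee_em(X, 3, n_starts=2, seed=seed)
            out = threshold_map_assign(model, X, alpha=0.05)
            mask = out.table["classified"].to_numpy()
            if mask.sum() == 0:
                continue
            errors.append(_best_mismatch_rate(labels[mask],
                                              out.table["label"].to_numpy()[mask]))
        assert np.mean(errors) <= 0.05 + 0.01

    def test_expected_misassigned_arithmetic(self):
        assert expected_misassigned(1928, 0.05) == 96

    def test_label_permutation_invariance(self):
        X, _ = three_component_overlapping(seed=13, n=600)
        model = fit_vee_em(X, 3, n_starts=2, seed=3)
        perm = [2, 0, 1]
        permuted = MixtureModel(
            weights=model.weights[perm], means=model.means[perm],
            volumes=model.volumes[perm], shape=model.shape, loglik=model.loglik,
        )
        a = threshold_map_assign(model, X, alpha=0.05)
        b = threshold_map_assign(permuted, X, alpha=0.05)
        assert a.tau == pytest.approx(b.tau)
        assert permuted.bic(len(X)) == pytest.approx(model.bic(len(X)))
        np.testing.assert_array_equal(a.table["classified"], b.table["classified"])


def _best_mismatch_rate(true, assigned):
    """Misclassification under the best one-to-one label matching."""
    from itertools import permutations

    K = int(max(true.max(), assigned.max())) + 1
    best = 1.0
    for perm in permutations(range(K)):
        mapped = np.array(perm)[assigned]
        best = min(best, float(np.mean(mapped != true)))
    return best


class TestSummariseClusters:
    def make_assignment(self, labels, index):
        n = len(labels)
        table = pd.DataFrame(
            {"label": labels, "max_posterior": np.ones(n), "classified": True},
            index=index,
        )
        return Assignment(table=table, posteriors=np.ones((n, 1)), tau=0.5,
                          alpha=0.05, fap=0.0)

    def test_quartiles_and_whiskers_match_hand_computation(self):
        X = pd.DataFrame({"c1": [1.0, 2.0, 3.0, 4.0, 5.0]},
                         index=[f"g{i}" for i in range(5)])
        flags = pd.DataFrame({"c1": [True] * 5}, index=X.index)
        profiles, clusters = summarise_clusters(
            self.make_assignment(np.zeros(5, int), X.index), X, flags
        )
        row = profiles.iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (2.0, 3.0, 4.0)
        assert (row["whisker_low"], row["whisker_high"]) == (-1.0, 7.0)
        assert row["n_outliers"] == 0

    def test_degenerate_spread_collapses_box(self):
        X = pd.DataFrame({"c1": [2.0] * 6}, index=[f"g{i}" for i in range(6)])
        flags = pd.DataFrame({"c1": [False] * 6}, index=X.index)
        profiles, _ = summarise_clusters(
            self.make_assignment(np.zeros(6, int), X.index), X, flags
        )
        row = profiles.iloc[0]
        assert row["q1"] == row["median"] == row["q3"] == 2.0
        assert row["whisker_low"] == row["whisker_high"] == 2.0
        assert row["n_outliers"] == 0

    def test_interpretability_needs_majority_de(self):
        X = pd.DataFrame({"c1": np.arange(10.0)}, index=[f"g{i}" for i in range(10)])
        flags = pd.DataFrame({"c1": [True] * 4 + [False] * 6}, index=X.index)
        _, clusters = summarise_clusters(
            self.make_assignment(np.zeros(10, int), X.index), X, flags
        )
        assert not clusters.loc[0, "interpretable"]
        flags["c1"] = [True] * 6 + [False] * 4
        _, clusters = summarise_clusters(
            self.make_assignment(np.zeros(10, int), X.index), X, flags
        )
        assert clusters.loc[0, "interpretable"]

    def test_small_cluster_flagged(self):
        X = pd.DataFrame({"c1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        flags = pd.DataFrame({"c1": [True] * 3}, index=X.index)
        _, clusters = summarise_clusters(
            self.make_assignment(np.zeros(3, int), X.index), X, flags
        )
        assert clusters.loc[0, "low_n"]
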