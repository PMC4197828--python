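"""Normalisation, replicate averaging, variance shrinkage and moderated tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mapktome import (
    ArrayDesign,
    EBayesPrior,
    LogRatioMatrix,
    adjust_pvalues,
    average_replicates,
    estimate_prior,
    gen_two_colour_arrays,
    loess_normalize,
    mapk_dependence,
    moderated_test,
    normalize_table,
    squeeze_var,
)


def replicate_matrix(values: np.ndarray, comparisons=("c1",)) -> LogRatioMatrix:
    """Wrap a (genes x reps) array as a single-comparison replicate matrix."""
    values = np.atleast_2d(values)
    cols = pd.MultiIndex.from_product([comparisons, range(1, values.shape[1] + 1)],
                                      names=["comparison", "bio_rep"])
    reps = pd.DataFrame(values, columns=cols,
                        index=[f"g{i:05d}" for i in range(len(values))])
    mean = reps.T.groupby(level="comparison").mean().T
    return LogRatioMatrix(mean=mean, replicates=reps)


class TestLoess:
    def test_zero_bias_barely_corrects(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(6, 16, 5000)
        m = rng.normal(0, 0.2, 5000)
        corrected = loess_normalize(m, a)
        assert np.mean(np.abs(m - corrected)) < 0.05

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(6, 16, 500)
        corrected = loess_normalize(np.full(500, 1.7), a)
        assert np.allclose(corrected, 0.0, atol=1e-6)

    def test_constant_intensity_falls_back_to_mean(self):
        m = np.arange(100, dtype=float)
        corrected = loess_normalize(m, np.full(100, 10.0))
        assert np.allclose(corrected, m - m.mean())

    def test_planted_bias_removed_to_noise_floor(self, small_design):
        noise = 0.1
        bias = lambda a: 0.3 * np.sin(a / 2.0) + 0.02 * (a - 11.0) ** 2
        table, _ = gen_two_colour_arrays(
            small_design, 600, de_fraction=0.0, bias_curve=bias, seed=4,
            d0=np.inf, s0_sq=1e-12, tech_sd=noise,
        )
        norm = normalize_table(table)
        # with no true effects the corrected M should be pure noise
        rms = np.sqrt(np.mean(norm["M"].to_numpy() ** 2))
        assert rms < noise * 1.2

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            loess_normalize(np.zeros(10), np.arange(10.0))


class TestAverageReplicates:
    def make_table(self, rows):
        return pd.DataFrame(
            rows, columns=["probe_id", "gene_id", "comparison", "bio_rep", "dye_swap", "M"]
        )

    def test_identical_duplicate_probes_pass_through(self):
        design = ArrayDesign(comparisons=("c1",), replicates_per_comparison=1, dye_swap=False)
        table = self.make_table([
            ["p1", "g1", "c1", 1, False, 1.5],
            ["p2", "g1", "c1", 1, False, 1.5],
        ])
        out = average_replicates(table, design)
        assert out.mean.loc["g1", "c1"] == pytest.approx(1.5)

    def test_dye_swap_pair_averages_to_biological_value(self):
        design = ArrayDesign(comparisons=("c1",), replicates_per_comparison=1)
        table = self.make_table([
            ["p1", "g1", "c1", 1, False, 0.9],
            ["p1", "g1", "c1", 1, True, -0.9],
        ])
        out = average_replicates(table, design)
        assert out.mean.loc["g1", "c1"] == pytest.approx(0.9)

    def test_matches_brute_force_grouped_mean(self, small_design):
        table, _ = gen_two_colour_arrays(small_design, 40, de_fraction=0.3, seed=6)
        norm = normalize_table(table)
        out = average_replicates(norm, small_design)
        # oracle: flip swapped values, then mean-of-means per replicate
        oracle = norm.assign(
            mb=lambda t: t["M"] * np.where(t["dye_swap"], -1.0, 1.0)
        ).groupby(["gene_id", "comparison", "bio_rep", "dye_swap"])["mb"].mean() \
         .groupby(["gene_id", "comparison", "bio_rep"]).mean() \
         .groupby(["gene_id", "comparison"]).mean()
        for (g, c), v in oracle.items():
            assert out.mean.loc[g, c] == pytest.approx(v)

    def test_orientation_flip_is_consistent(self, small_design):
        """Negating M and toggling the swap flag leaves the matrix unchanged."""
        table, _ = gen_two_colour_arrays(small_design, 30, de_fraction=0.5, seed=8)
        norm = normalize_table(table)
        flipped = norm.assign(M=-norm["M"], dye_swap=~norm["dye_swap"].astype(bool))
        pd.testing.assert_frame_equal(
            average_replicates(norm, small_design).mean,
            average_replicates(flipped, small_design).mean,
        )

    def test_replicate_count_per_gene(self, small_design):
        table, _ = gen_two_colour_arrays(small_design, 25, seed=1)
        out = average_replicates(normalize_table(table), small_design)
        assert out.replicates.shape[1] == len(small_design.comparisons) * 3
        assert out.replicates.notna().all().all()


class TestPriorEstimation:
    @staticmethod
    def simulate_s2(rng, n, d0, s0_sq, df):
        sigma2 = d0 * s0_sq / rng.chisquare(d0, n)
        return sigma2 * rng.chisquare(df, n) / df

    def test_recovers_planted_hyperparameters(self):
        rng = np.random.default_rng(42)
        s2 = self.simulate_s2(rng, 10000, d0=4.0, s0_sq=0.05, df=2)
        prior = estimate_prior(s2, np.full(10000, 2))
        assert abs(prior.d0 - 4.0) < 1.5
        assert abs(prior.s0_sq - 0.05) < 0.2 * 0.05

    def test_constant_variances_give_infinite_d0(self):
        prior = estimate_prior(np.full(100, 0.05), np.full(100, 2))
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        s2 = self.simulate_s2(rng, 2000, d0=5.0, s0_sq=0.1, df=3)
        p1 = estimate_prior(s2, np.full(2000, 3))
        p2 = estimate_prior(2 * s2, np.full(2000, 3))
        assert p2.s0_sq == pytest.approx(2 * p1.s0_sq, rel=1e-9)
        assert p2.d0 == pytest.approx(p1.d0, rel=1e-6)

    def test_matches_limma_fitfdist(self, tmp_path):
        """Same method-of-moments fit as the reference empirical-Bayes code."""
        rscript = pytest.importorskip("shutil").which("Rscript")
        if rscript is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(7)
        s2 = self.simulate_s2(rng, 500, d0=6.0, s0_sq=0.04, df=2)
        np.savetxt(tmp_path / "s2.txt", s2)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f's2 <- scan("{tmp_path / "s2.txt"}", quiet=TRUE)\n'
            'fit <- fitFDist(s2, df1=2)\n'
            'cat(fit$scale, fit$df2, sep="\\n")\n'
        )
        import subprocess

        out = subprocess.run([rscript, str(script)], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        ref_scale, ref_df2 = map(float, out.stdout.split())
        prior = estimate_prior(s2, np.full(500, 2))
        assert prior.s0_sq == pytest.approx(ref_scale, rel=1e-4)
        assert prior.d0 == pytest.approx(ref_df2, rel=1e-4)


class TestModeratedTest:
    def test_hand_computed_statistic(self):
        mat = replicate_matrix(np.array([[1.0, 1.2, 0.8]]))
        prior = EBayesPrior(d0=3.0, s0_sq=0.04)
        res = moderated_test(mat, prior)
        row = res.iloc[0]
        assert row["s2"] == pytest.approx(0.04)
        assert row["s2_post"] == pytest.approx(0.04)
        assert row["stat"] == pytest.approx(1.0 / (0.2 * np.sqrt(1 / 3)), abs=1e-3)
        assert row["stat"] == pytest.approx(8.660, abs=1e-3)
        assert row["p"] < 1e-15

    def test_null_replicates_give_zero_statistic(self):
        mat = replicate_matrix(np.array([[0.0, 0.0, 0.0]] * 25))
        res = moderated_test(mat, EBayesPrior(3.0, 0.04))
        assert (res["stat"] == 0).all()
        assert (res["p"] == 1).all()

    def test_infinite_prior_df_pins_posterior_variance(self):
        rng = np.random.default_rng(0)
        mat = replicate_matrix(rng.normal(size=(50, 3)))
        res = moderated_test(mat, EBayesPrior(np.inf, 0.07))
        assert np.allclose(res["s2_post"], 0.07)

    def test_shrinkage_is_convex_combination(self):
        rng = np.random.default_rng(1)
        s2 = rng.chisquare(2, 200) * 0.05
        prior = EBayesPrior(4.0, 0.05)
        post = squeeze_var(s2, np.full(200, 2), prior)
        lo = np.minimum(s2, prior.s0_sq)
        hi = np.maximum(s2, prior.s0_sq)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_type_one_error_directions(self):
        """The t null is calibrated; the normal null is anticonservative."""
        rng = np.random.default_rng(5)
        n_genes, df = 4000, 2
        sigma2 = 4.0 * 0.05 / rng.chisquare(4.0, n_genes)
        values = rng.normal(size=(n_genes, df + 1)) * np.sqrt(sigma2)[:, None]
        mat = replicate_matrix(values)
        prior = EBayesPrior(4.0, 0.05)
        frac_t = (moderated_test(mat, prior, null="t")["p"] < 0.05).mean()
        frac_n = (moderated_test(mat, prior, null="normal")["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(frac_t - 0.05) < 3 * se
        assert frac_n >= 0.05
        assert frac_n > frac_t


class TestAdjustPvalues:
    def test_bonferroni_definition(self):
        assert adjust_pvalues([0.01] * 7, "bonferroni")[0] == pytest.approx(0.07)

    def test_bh_matches_brute_force_step_up(self):
        def bh_oracle(p):
            p = np.asarray(p, float)
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            return adj

        p = [0.01, 0.02, 0.03, 0.04]
        np.testing.assert_allclose(adjust_pvalues(p, "bh"), [0.04] * 4)
        rng = np.random.default_rng(2)
        p = rng.uniform(size=37)
        np.testing.assert_allclose(adjust_pvalues(p, "bh"), bh_oracle(p), atol=1e-12)

    @pytest.mark.parametrize("method", ["bonferroni", "bh", "local_fdr"])
    def test_single_pvalue_unchanged(self, method):
        np.testing.assert_allclose(adjust_pvalues([0.42], method), [0.42])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_ordering_bonferroni_bh_raw(self, p):
        p = np.asarray(p)
        bonf = adjust_pvalues(p, "bonferroni")
        bh = adjust_pvalues(p, "bh")
        assert np.all(bonf >= bh - 1e-12)
        assert np.all(bh >= p - 1e-12)

    def test_local_fdr_separates_signal_from_null(self):
        rng = np.random.default_rng(8)
        z = np.concatenate([rng.normal(0, 1, 1800), rng.normal(4, 1, 200)])
        p = stats.norm.sf(z)
        lfdr = adjust_pvalues(p, "local_fdr")
        assert lfdr[-200:].mean() < 0.3 < lfdr[:1800].mean()

    def test_empty_and_invalid(self):
        assert len(adjust_pvalues([], "bh")) == 0
        with pytest.raises(ValueError):
            adjust_pvalues([1.2], "bh")


class TestMapkDependence:
    def make_inputs(self, col, mut):
        lr = pd.DataFrame({"col": col, "mpk": mut}, index=["g1"])
        flags = pd.Series([True], index=["g1"])
        return lr, flags

    @pytest.mark.parametrize(
        "col,mut,expected",
        [
            (2.0, 0.8, "affected"),
            (2.0, 1.5, "unaffected"),
            (-1.6, -0.4, "affected"),  # the rule ignores sign
            (2.0, np.nan, "unclassifiable"),
        ],
    )
    def test_one_logratio_rule(self, col, mut, expected):
        lr, flags = self.make_inputs(col, mut)
        out = mapk_dependence(lr, flags, "col", ["mpk"])
        assert out.loc[0, "status"] == expected

    def test_only_regulated_genes_are_classified(self):
        lr = pd.DataFrame({"col": [2.0, 0.1], "mpk": [0.5, 0.1]}, index=["g1", "g2"])
        flags = pd.Series([True, False], index=["g1", "g2"])
        out = mapk_dependence(lr, flags, "col", ["mpk"])
        assert set(out["gene_id"]) == {"g1"}
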