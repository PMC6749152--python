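import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from circenet.diffexpr import (
    ExpressionDataset,
    ModeratedStats,
    bh_adjust,
    combine_datasets,
    estimate_prior,
    moderated_t,
    select_de,
)
from conftest import make_dataset


def _tiny_dataset():
    """means 2 vs 1, pooled variance exactly 1, n1 = n2 = 3."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 0.0, 1.0, 2.0]],
        index=["f0"],
        columns=["a", "b", "c", "d", "e", "f"],
    )
    cond = pd.Series(["case"] * 3 + ["control"] * 3, index=values.columns)
    return ExpressionDataset(values=values, conditions=cond, tag="tiny")


def _stats_with(p_two, effect, tag="d", n=3):
    table = pd.DataFrame(
        {"effect": [effect], "s_sq": [1.0], "s_tilde_sq": [1.0], "t_mod": [0.0],
         "p_two": [p_two]},
        index=["f0"],
    )
    return ModeratedStats(table, d_g=2 * n - 2, d0=4.0, s0_sq=1.0,
                          n_case=n, n_control=n, tag=tag)


class TestModeratedT:
    def test_d0_zero_is_ordinary_pooled_t(self):
        ms = moderated_t(_tiny_dataset(), d0=0, s0_sq=1.0)
        assert ms.table["t_mod"].iloc[0] == pytest.approx(1.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert ms.table["t_mod"].iloc[0] == pytest.approx(1.2247, abs=1e-4)

    def test_d0_zero_matches_scipy_on_random_data(self, rng):
        ds = make_dataset(rng, n_features=150, de_shift=1.0)
        ms = moderated_t(ds, d0=0, s0_sq=1.0)
        t_ref, p_ref = stats.ttest_ind(
            ds.group_values("case"), ds.group_values("control"), axis=1
        )
        np.testing.assert_allclose(ms.table["t_mod"], t_ref, atol=1e-10)
        np.testing.assert_allclose(ms.table["p_two"], p_ref, atol=1e-10)

    def test_d0_infinite_shrinks_fully_to_prior(self, rng):
        ds = make_dataset(rng)
        ms = moderated_t(ds, d0=np.inf, s0_sq=0.7)
        assert (ms.table["s_tilde_sq"] == 0.7).all()
        z_ref = ms.table["effect"] / np.sqrt(0.7 * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(ms.table["t_mod"], z_ref, atol=1e-10)
        np.testing.assert_allclose(
            ms.table["p_two"], 2 * stats.norm.sf(np.abs(z_ref)), atol=1e-10
        )

    def test_zero_effect_gives_zero_t_and_p_one(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0], [3.0, 4.0, 3.0, 4.0]],
            index=["f0", "f1"],
            columns=["a", "b", "c", "d"],
        )
        cond = pd.Series(["case", "case", "control", "control"], index=values.columns)
        ms = moderated_t(ExpressionDataset(values, cond, "z"), d0=2.0, s0_sq=0.5)
        assert (ms.table["t_mod"] == 0).all()
        assert (ms.table["p_two"] == 1).all()

    def test_shrinkage_keeps_posterior_between_sample_and_prior(self, rng):
        ds = make_dataset(rng, n_features=200, var_prior=(4.0, 0.5))
        ms = moderated_t(ds)
        assert 0 < ms.d0 < np.inf
        lo = np.minimum(ms.table["s_sq"], ms.s0_sq)
        hi = np.maximum(ms.table["s_sq"], ms.s0_sq)
        inner = ms.table["s_sq"] != ms.s0_sq
        assert (ms.table["s_tilde_sq"][inner] > lo[inner]).all()
        assert (ms.table["s_tilde_sq"][inner] < hi[inner]).all()

    def test_moderated_t_magnitude_between_ordinary_and_prior_statistic(self, rng):
        ds = make_dataset(rng, n_features=200, de_shift=0.8, var_prior=(4.0, 0.5))
        ms = moderated_t(ds)
        t_ord = moderated_t(ds, d0=0, s0_sq=1.0).table["t_mod"]
        t_prior = moderated_t(ds, d0=np.inf, s0_sq=ms.s0_sq).table["t_mod"]
        lo = np.minimum(np.abs(t_ord), np.abs(t_prior))
        hi = np.maximum(np.abs(t_ord), np.abs(t_prior))
        t = np.abs(ms.table["t_mod"])
        assert ((t >= lo - 1e-12) & (t <= hi + 1e-12)).all()

    def test_matches_limma_ebayes(self, rng, tmp_path):
        """Independent oracle: R limma's eBayes on the same matrix."""
        import subprocess

        ds = make_dataset(rng, n_features=200, n_case=4, n_control=4, de_shift=1.0,
                          var_prior=(4.0, 0.1))
        expr = tmp_path / "expr.tsv"
        ds.values.to_csv(expr, sep="\t")
        out = tmp_path / "limma.tsv"
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{expr}", row.names=1))
        design <- cbind(Intercept=1, case=c(rep(1,4), rep(0,4)))
        fit <- eBayes(lmFit(x, design))
        write.table(data.frame(t=fit$t[,"case"], p=fit$p.value[,"case"],
                    d0=fit$df.prior, s0=fit$s2.prior), "{out}", sep="\\t")
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out, sep="\t")
        ms = moderated_t(ds)
        assert ms.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert ms.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(ms.table["t_mod"], ref["t"], rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(ms.table["p_two"], ref["p"], rtol=1e-6, atol=1e-10)

    def test_all_zero_variance_fails_prior_estimation(self):
        values = pd.DataFrame(
            np.tile([[1.0, 1.0, 2.0, 2.0]], (20, 1)),
            index=[f"f{i}" for i in range(20)],
            columns=["a", "b", "c", "d"],
        )
        cond = pd.Series(["case", "case", "control", "control"], index=values.columns)
        with pytest.raises(ValueError, match="prior estimation"):
            moderated_t(ExpressionDataset(values, cond, "flat"))


class TestEstimatePrior:
    def test_identical_variances_give_infinite_d0(self):
        d0, s0 = estimate_prior(np.full(50, 0.3), 4)
        assert np.isinf(d0)
        # with constant s^2, s0 = exp(mean(e)) = s^2 * exp(log(d/2) - psi(d/2))
        from scipy.special import digamma

        expected = 0.3 * np.exp(np.log(2.0) - digamma(2.0))
        assert s0 == pytest.approx(expected, rel=1e-12)

    def test_single_outlier_yields_finite_positive_d0(self):
        s2 = np.full(20, 0.2)
        s2[0] = 50.0
        d0, s0 = estimate_prior(s2, 6)
        assert 0 < d0 < np.inf
        assert s0 > 0

    def test_recovers_true_hyperparameters(self):
        d0s, s0s = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            sigma2 = 0.05 * 4.0 / r.chisquare(4.0, 5000)
            s2 = sigma2 * r.chisquare(4, 5000) / 4
            d0, s0 = estimate_prior(s2, 4)
            d0s.append(d0)
            s0s.append(s0)
        assert np.mean(d0s) == pytest.approx(4.0, rel=0.2)
        assert np.mean(s0s) == pytest.approx(0.05, rel=0.1)

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError, match="10"):
            estimate_prior(np.full(5, 0.2), 4)


class TestCombine:
    def test_single_dataset_passthrough(self, rng):
        ds = make_dataset(rng, de_shift=1.2)
        ms = moderated_t(ds)
        meta = combine_datasets([ms])
        z_expected = np.sign(ms.table["effect"]) * stats.norm.isf(ms.table["p_two"] / 2)
        np.testing.assert_allclose(meta.table["z_meta"], z_expected, atol=1e-12)

    def test_two_equal_datasets_hand_value(self):
        meta = combine_datasets(
            [_stats_with(0.10, 1.0, "a"), _stats_with(0.10, 1.0, "b")], weights=[1, 1]
        )
        assert meta.table["z_meta"].iloc[0] == pytest.approx(2.3262, abs=1e-4)
        assert meta.table["p_two"].iloc[0] == pytest.approx(0.0200, abs=1e-4)

    def test_opposite_signs_cancel(self):
        meta = combine_datasets(
            [_stats_with(0.10, 1.0, "a"), _stats_with(0.10, -1.0, "b")], weights=[1, 1]
        )
        assert meta.table["z_meta"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert meta.table["p_two"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_partial_observation_combines_observed_only(self, rng):
        ds1 = make_dataset(rng, n_features=40, tag="a")
        ds2 = make_dataset(rng, n_features=60, tag="b")
        meta = combine_datasets([moderated_t(ds1), moderated_t(ds2)])
        tbl = meta.table
        assert (tbl.loc[tbl.index[tbl["n_datasets_observed"] == 1]].index >= "f040").all()
        assert set(tbl.index) == {f"f{i:03d}" for i in range(60)}

    def test_default_weights_are_sqrt_sample_size(self, rng):
        ds1 = make_dataset(rng, n_case=8, n_control=8, tag="big")
        ds2 = make_dataset(rng, n_case=3, n_control=3, tag="small")
        meta = combine_datasets([moderated_t(ds1), moderated_t(ds2)])
        assert meta.weights["big"] == pytest.approx(4.0)
        assert meta.weights["small"] == pytest.approx(np.sqrt(6))


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_adjust([0.1, np.nan])

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = bh_adjust(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(ours, ref, atol=1e-12)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(ours[order]) >= -1e-15).all()
        assert (ours >= np.asarray(pvals) - 1e-15).all()


class TestSelectDE:
    def test_threshold_validation(self, rng):
        meta = combine_datasets([moderated_t(make_dataset(rng))])
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                select_de(meta, bad)

    def test_vacuous_threshold_selects_everything_below_one(self, rng):
        meta = combine_datasets([moderated_t(make_dataset(rng, de_shift=2.0))])
        sel = select_de(meta, 1.0)
        assert sel == set(meta.table.index[meta.table["fdr"] < 1.0])

    def test_discoveries_monotone_in_threshold(self, rng):
        meta = combine_datasets([moderated_t(make_dataset(rng, de_shift=1.0))])
        sizes = [len(select_de(meta, t)) for t in (0.01, 0.05, 0.1, 0.5, 1.0)]
        assert sizes == sorted(sizes)

    def test_power_on_planted_signal(self):
        from circenet.simulate import SimulationConfig, simulate_expression
        from circenet.pipeline import gene_meta_analysis

        recalls = []
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed, n_features=400, n_datasets=2, n_case=10, n_control=10,
                effect_mean=1.5, n_mrna=200, n_planted_circ=4, n_pairs_per_circ=3,
            )
            datasets, truth = simulate_expression(cfg)
            sel = select_de(gene_meta_analysis(datasets), 0.05)
            recalls.append(len(sel & truth.de_features) / len(truth.de_features))
        assert np.mean(recalls) >= 0.8
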