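import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from _oracle import oracle_bh, oracle_moderated_t, oracle_prior
from ptmdiff.diffstats import (
    EBayesPrior,
    _trigamma_inverse,
    bh_adjust,
    call_significant,
    differential_analysis,
    estimate_prior,
    fit_features,
    moderated_t,
)
from ptmdiff.io_tables import bind
from ptmdiff.normalization import log2_transform


def two_group_frame(a_rows, b_rows):
    a = np.asarray(a_rows, float)
    b = np.asarray(b_rows, float)
    cols_a = [f"T{i + 1}" for i in range(a.shape[1])]
    cols_b = [f"C{i + 1}" for i in range(b.shape[1])]
    df = pd.DataFrame(np.hstack([a, b]), columns=cols_a + cols_b)
    return df, cols_a, cols_b


class TestFitFeatures:
    def test_noiseless_fold_change(self):
        df, ga, gb = two_group_frame([[1.0, 1.0]], [[3.0, 3.0]])
        fit = fit_features(df, ga, gb)
        assert fit["log2fc"].iloc[0] == -2.0
        assert fit["s2"].iloc[0] == 0.0

    def test_hand_pooled_variance(self):
        # groups (0,2) and (0,2): means 1, ss = 2+2, df = 2, s2 = 2
        df, ga, gb = two_group_frame([[0.0, 2.0]], [[0.0, 2.0]])
        fit = fit_features(df, ga, gb)
        assert fit["log2fc"].iloc[0] == 0.0
        assert fit["s2"].iloc[0] == 2.0
        assert fit["df"].iloc[0] == 2

    def test_missing_value_reduces_df(self):
        df, ga, gb = two_group_frame([[0.0, 2.0, np.nan]], [[1.0, 3.0, 5.0]])
        fit = fit_features(df, ga, gb)
        assert fit["df"].iloc[0] == 3  # (2-1) + (3-1)
        assert fit["n_a"].iloc[0] == 2

    def test_group_entirely_missing_kept_with_nan(self):
        df, ga, gb = two_group_frame(
            [[np.nan, np.nan], [1.0, 2.0]], [[1.0, 2.0], [3.0, 4.0]]
        )
        fit = fit_features(df, ga, gb)
        assert len(fit) == 2
        assert np.isnan(fit["log2fc"].iloc[0])

    def test_small_group_rejected(self):
        df, ga, gb = two_group_frame([[1.0, 2.0]], [[1.0, 2.0]])
        with pytest.raises(ValueError, match=">= 2"):
            fit_features(df, ga, gb[:1])


class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [0.01, 0.5, 1.0, 4.0, 50.0, 1e4])
    def test_inverts_trigamma(self, x):
        y = special.polygamma(1, x)
        assert _trigamma_inverse(float(y)) == pytest.approx(x, rel=1e-6)

    def test_nonpositive_target_is_infinite(self):
        assert math.isinf(_trigamma_inverse(0.0))


class TestEstimatePrior:
    def test_recovers_generative_hyperparameters(self):
        # s2 | sigma2 ~ sigma2 * chi2_df / df with sigma2 ~ s0sq*d0/chi2_d0
        d0_true, s0sq_true, df = 8.0, 4.0, 4
        for seed in (101, 202, 303):
            rng = np.random.default_rng(seed)
            sigma2 = s0sq_true * d0_true / rng.chisquare(d0_true, 5000)
            s2 = sigma2 * rng.chisquare(df, 5000) / df
            prior = estimate_prior(s2, np.full(5000, df))
            assert prior.d0 == pytest.approx(d0_true, rel=0.2)
            assert prior.s0sq == pytest.approx(s0sq_true, rel=0.1)

    def test_matches_oracle_transcription(self, rng):
        s2 = rng.chisquare(4, 200) / 4
        df = np.full(200, 4.0)
        prior = estimate_prior(s2, df)
        d0_ref, s0sq_ref = oracle_prior(list(s2), list(df))
        assert prior.d0 == pytest.approx(d0_ref, abs=1e-6)
        assert prior.s0sq == pytest.approx(s0sq_ref, abs=1e-8)

    def test_identical_variances_hit_infinite_limit(self):
        prior = estimate_prior(np.full(100, 2.0), np.full(100, 1000.0))
        assert math.isinf(prior.d0)
        assert prior.s0sq == pytest.approx(2.0, rel=0.01)

    def test_two_features_minimal_contract(self):
        prior = estimate_prior(np.array([1.0, 2.0]), np.array([3.0, 3.0]))
        assert prior.d0 > 0 and prior.s0sq > 0

    def test_fewer_than_two_usable_is_error(self):
        with pytest.raises(ValueError, match=">= 2 features"):
            estimate_prior(np.array([1.0, 0.0]), np.array([3.0, 3.0]))


class TestModeratedT:
    def test_d0_zero_reduces_to_classical_pooled_t(self, rng):
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 4))
        df, ga, gb = two_group_frame(a, b)
        fits = fit_features(df, ga, gb)
        res = moderated_t(fits, EBayesPrior(d0=0.0, s0sq=1.0))
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_mod"], t_ref, atol=1e-12)
        np.testing.assert_allclose(res["p"], p_ref, atol=1e-12)

    def test_d0_infinite_shares_prior_variance(self, rng):
        df, ga, gb = two_group_frame(rng.normal(size=(10, 3)),
                                     rng.normal(size=(10, 3)))
        fits = fit_features(df, ga, gb)
        res = moderated_t(fits, EBayesPrior(d0=math.inf, s0sq=0.5))
        assert (res["s2_post"] == 0.5).all()
        expected_t = fits["log2fc"] / np.sqrt(0.5 * (1 / 3 + 1 / 3))
        np.testing.assert_allclose(res["t_mod"], expected_t, atol=1e-12)

    def test_matches_scalar_oracle(self, rng):
        df, ga, gb = two_group_frame(rng.normal(size=(30, 3)),
                                     rng.normal(size=(30, 3)))
        fits = fit_features(df, ga, gb)
        prior = estimate_prior(fits["s2"], fits["df"])
        res = moderated_t(fits, prior)
        for i in range(len(fits)):
            t_ref, p_ref = oracle_moderated_t(
                fits["log2fc"].iloc[i], fits["s2"].iloc[i], fits["df"].iloc[i],
                3, 3, prior.d0, prior.s0sq,
            )
            assert res["t_mod"].iloc[i] == pytest.approx(t_ref, abs=1e-10)
            assert res["p"].iloc[i] == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_zero_variance_flagged(self):
        df, ga, gb = two_group_frame([[1.0, 1.0], [1.0, 1.0]],
                                     [[3.0, 3.0], [1.0, 1.0]])
        fits = fit_features(df, ga, gb)
        res = moderated_t(fits, EBayesPrior(d0=0.0, s0sq=0.0))
        assert res["degenerate_se"].all()
        assert res["p"].iloc[0] == 0.0   # nonzero fold change
        assert res["p"].iloc[1] == 1.0   # zero fold change

    def test_zero_df_features_shrunk_to_prior(self):
        df, ga, gb = two_group_frame([[1.0, np.nan]], [[2.0, np.nan]])
        fits = fit_features(df, ga, gb)
        res = moderated_t(fits, EBayesPrior(d0=4.0, s0sq=0.25))
        assert res["shrunk_to_prior"].iloc[0]
        assert res["s2_post"].iloc[0] == 0.25
        assert res["df_total"].iloc[0] == 4.0


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.2])), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust(np.ones(5)), np.ones(5))

    def test_matches_literal_oracle_and_is_monotone(self, rng):
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, oracle_bh(list(p)), atol=1e-12)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_missing_propagated(self):
        adj = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([1.5]))


class TestCallSignificant:
    @pytest.mark.parametrize(
        "p_adj,lfc,expected",
        [(0.04, 1.5, True), (0.04, 0.5, False), (0.06, 3.0, False)],
    )
    def test_dual_gate(self, p_adj, lfc, expected):
        res = pd.DataFrame({"log2fc": [lfc], "p_adj": [p_adj]})
        out = call_significant(res, alpha=0.05, fc_threshold=2.0)
        assert bool(out["significant"].iloc[0]) is expected


class TestCalibration:
    def test_null_type_one_error(self):
        """Raw p < 0.05 at ~5% under the null, pooled over seeds."""
        from ptmdiff.synthetic import simulate_protein

        ps = []
        for seed in range(10):
            m, meta, _ = simulate_protein(
                n_features=400, n_per_group=3, frac_diff=0.0, seed=seed
            )
            lg = log2_transform(bind(m, meta))
            res, _ = differential_analysis(
                lg, meta.group_members("Treatment"), meta.group_members("Control")
            )
            ps.append(res["p"].to_numpy())
        frac = (np.concatenate(ps) < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_moderation_beats_classical_power(self):
        """At n = 3/group the shrunken test finds at least as many planted
        effects as the ordinary t-test at the same FDR, most seeds."""
        from ptmdiff.synthetic import simulate_protein

        wins = 0
        for seed in range(10):
            m, meta, truth = simulate_protein(
                n_features=400, n_per_group=3, frac_diff=0.1,
                log2fc_effect=2.0, seed=seed,
            )
            lg = log2_transform(bind(m, meta))
            ga = meta.group_members("Treatment")
            gb = meta.group_members("Control")
            res, _ = differential_analysis(lg, ga, gb, fc_threshold=1.0)
            t_cls, p_cls = stats.ttest_ind(
                lg[ga].to_numpy(), lg[gb].to_numpy(), axis=1, equal_var=True
            )
            adj_cls = bh_adjust(p_cls)
            truth_idx = truth.table.set_index("feature")["is_differential"]
            mod_hits = int(
                (res["p_adj"] < 0.05)[truth_idx.reindex(res.index)].sum()
            )
            cls_hits = int(
                ((adj_cls < 0.05) & truth_idx.reindex(res.index).to_numpy()).sum()
            )
            wins += mod_hits >= cls_hits
        assert wins >= 8


@pytest.mark.timeout(120)
def test_agrees_with_bioconductor_limma(tmp_path, rng):
    """Cross-check the whole moderated pipeline against limma (lmFit +
    eBayes + BH) on a simulated two-group matrix."""
    n = 120
    x = rng.normal(size=(n, 6)) * rng.chisquare(6, size=(n, 1)) / 6
    x[: n // 10, :3] += 2.0
    mat = pd.DataFrame(
        x, index=[f"f{i}" for i in range(n)],
        columns=["T1", "T2", "T3", "C1", "C2", "C3"],
    )
    mat.to_csv(tmp_path / "mat.csv")
    script = f"""
suppressMessages(library(limma))
x <- read.csv("{tmp_path}/mat.csv", row.names = 1)
design <- model.matrix(~0 + factor(rep(c("T", "C"), each = 3), levels = c("C", "T")))
colnames(design) <- c("C", "T")
fit <- lmFit(as.matrix(x), design)
fit <- contrasts.fit(fit, makeContrasts(T - C, levels = design))
fit <- eBayes(fit)
out <- data.frame(t = fit$t[, 1], p = fit$p.value[, 1],
                  padj = p.adjust(fit$p.value[, 1], method = "BH"))
write.csv(out, "{tmp_path}/limma.csv")
cat(fit$df.prior, fit$s2.prior)
"""
    (tmp_path / "run.R").write_text(script)
    proc = subprocess.run(
        ["Rscript", str(tmp_path / "run.R")], capture_output=True, text=True
    )
    assert proc.returncode == 0, proc.stderr
    d0_ref, s0sq_ref = map(float, proc.stdout.split())
    ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
    res, prior = differential_analysis(mat, ["T1", "T2", "T3"],
                                       ["C1", "C2", "C3"])
    assert prior.d0 == pytest.approx(d0_ref, rel=1e-5)
    assert prior.s0sq == pytest.approx(s0sq_ref, rel=1e-5)
    np.testing.assert_allclose(res["t_mod"], ref["t"], atol=1e-8)
    np.testing.assert_allclose(res["p"], ref["p"], atol=1e-8)
    np.testing.assert_allclose(res["p_adj"], ref["padj"], atol=1e-8)
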