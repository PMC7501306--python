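"""Expression filtering, TMM, log-CPM, paired testing, BH, signatures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stemscreen import de
from stemscreen import synthetic as syn

from conftest import tiny_count_matrix


def bh_bruteforce(p):
    """Textbook step-up definition: adj_i = min_{j: p_(j) >= p_(i)} n p_(j) / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    for rank_pos, i in enumerate(order, start=1):
        candidates = [n * p[order[j - 1]] / j for j in range(rank_pos, n + 1)]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestFilterExpressed:
    def test_rpkm_exactly_one_removed(self):
        # length 1000 bp, library 1e6: RPKM = count => count 1 -> RPKM 1.0
        cm = tiny_count_matrix({"g1": [1, 1, 1, 1], "pad": [999_999] * 4})
        kept = de.filter_expressed(cm, rpkm_min=1.0, min_samples=3)
        assert "g1" not in kept.counts.index  # strict "more than"

    def test_needs_min_samples_above_threshold(self):
        cm = tiny_count_matrix({"g1": [500, 500, 0, 0], "pad": [999_500, 999_500,
                                                                1_000_000, 1_000_000]})
        kept = de.filter_expressed(cm, rpkm_min=1.0, min_samples=3)
        assert "g1" not in kept.counts.index

    def test_all_zero_gene_removed_and_expressed_kept(self):
        cm = tiny_count_matrix({"g0": [0, 0, 0, 0], "g1": [100, 100, 100, 100],
                                "pad": [999_900] * 4})
        kept = de.filter_expressed(cm)
        assert "g0" not in kept.counts.index and "g1" in kept.counts.index


class TestTMM:
    def test_proportional_and_identical_samples_give_unit_factors(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(200, 300).astype(float) + 1
        counts = pd.DataFrame({"A": base, "B": 2 * base})
        np.testing.assert_allclose(de.tmm_factors(counts), 1.0, atol=1e-12)
        counts = pd.DataFrame({"A": base, "B": base})
        np.testing.assert_allclose(de.tmm_factors(counts), 1.0, atol=1e-12)

    def test_matches_edger_reference_on_frozen_fixture(self):
        # independent oracle: Bioconductor edgeR 4.0.16 calcNormFactors
        # (method="TMM") run on this exact matrix; factors frozen below.
        rng = np.random.default_rng(20260101)
        n, s = 200, 4
        mu = np.exp(rng.normal(5, 1.5, n))
        scale = np.array([1.0, 1.6, 0.7, 1.2])
        counts = rng.poisson(np.outer(mu, scale) * np.exp(rng.normal(0, 0.3, (n, s))))
        counts[rng.choice(n, 20, replace=False), 0] = 0
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(n)], columns=list("ABCD"))
        expected = [1.0284057265, 1.0080268705, 0.9642659444, 1.0003836288]
        np.testing.assert_allclose(de.tmm_factors(df).to_numpy(), expected, atol=1e-6)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            de.tmm_factors(counts)


class TestLogCpm:
    def test_analytic_values(self):
        counts = pd.DataFrame({"A": [0, 1]}, index=["g0", "g1"])
        counts.loc["pad", "A"] = 999_999
        out = de.log_cpm(counts)
        assert out.loc["g0", "A"] == 0.0          # log2(0 + 1)
        assert out.loc["g1", "A"] == pytest.approx(1.0)  # CPM 1 -> log2(2)

    def test_invariant_to_doubling_counts(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(100, (50, 3)), columns=list("ABC"))
        pd.testing.assert_frame_equal(de.log_cpm(counts), de.log_cpm(2 * counts))


class TestPairedDE:
    def test_null_identity_pairs(self):
        cm = tiny_count_matrix({f"g{i}": [10 * i + 5] * 4 for i in range(1, 6)})
        expr = de.log_cpm(cm.counts)
        tab = de.paired_de(expr, cm.samples)
        assert np.allclose(tab["log2fc"], 0.0)
        assert np.allclose(tab["p"], 1.0)

    def test_degenerate_constant_differences(self):
        expr = pd.DataFrame({"P1_A": [1.0], "P1_B": [2.0], "P2_A": [3.0],
                             "P2_B": [4.0], "P3_A": [5.0], "P3_B": [6.0]}, index=["g"])
        samples = pd.DataFrame({
            "condition": ["A", "B"] * 3,
            "pair": ["P1", "P1", "P2", "P2", "P3", "P3"],
        }, index=expr.columns)
        tab = de.paired_de(expr, samples)
        assert tab["log2fc"].iloc[0] == 1.0
        assert tab["p"].iloc[0] == 0.0   # all differences equal and nonzero

    def test_fewer_than_two_pairs_rejected(self):
        expr = pd.DataFrame({"P1_A": [1.0], "P1_B": [2.0]}, index=["g"])
        samples = pd.DataFrame({"condition": ["A", "B"], "pair": ["P1", "P1"]},
                               index=expr.columns)
        with pytest.raises(ValueError, match="two complete pairs"):
            de.paired_de(expr, samples)

    def test_recovery_of_planted_fold_changes(self, planted_counts):
        truth, cm = planted_counts
        tab = de.run_de(cm)
        est = tab.set_index("gene")["log2fc"]
        planted = truth.true_lfc[truth.true_lfc != 0]
        shared = planted.index.intersection(est.index)
        r, _ = stats.spearmanr(est.loc[shared], planted.loc[shared])
        assert r >= 0.8

    def test_estimates_unbiased_on_planted_genes(self, planted_counts):
        truth, cm = planted_counts
        tab = de.run_de(cm)
        est = tab.set_index("gene")["log2fc"]
        planted = truth.true_lfc[truth.true_lfc != 0]
        shared = planted.index.intersection(est.index)
        err = (est.loc[shared] - planted.loc[shared]).to_numpy()
        assert abs(err.mean()) <= 3 * err.std(ddof=1) / np.sqrt(len(err))

    def test_gene_order_equivariance(self, planted_counts):
        _, cm = planted_counts
        rng = np.random.default_rng(3)
        perm = rng.permutation(cm.counts.index)
        cm2 = de.CountMatrix(cm.counts.loc[perm], cm.lengths.loc[perm], cm.samples)
        a = de.run_de(cm).set_index("gene").sort_index()
        b = de.run_de(cm2).set_index("gene").sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(de.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.37])[0] == 0.37

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_bruteforce_definition_and_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests
        ours = de.bh_adjust(pvals)
        np.testing.assert_allclose(ours, bh_bruteforce(pvals), atol=1e-12)
        sm = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, sm, atol=1e-12)


class TestSummariesAndSignatures:
    def make_de(self, n_up=600, n_down=400, seed=0):
        rng = np.random.default_rng(seed)
        lfc = np.concatenate([rng.uniform(0.1, 3, n_up), -rng.uniform(0.1, 3, n_down)])
        p = rng.uniform(0, 1, n_up + n_down)
        tab = pd.DataFrame({"gene": [f"g{i}" for i in range(n_up + n_down)],
                            "log2fc": lfc, "mean_log2cpm": 5.0, "p": p})
        tab["fdr"] = de.bh_adjust(tab["p"].to_numpy())
        return tab

    def test_ma_summary_counts_and_strict_zero_exclusion(self):
        tab = pd.DataFrame({"gene": list("abc"), "log2fc": [1.0, -1.0, 0.0],
                            "mean_log2cpm": 5.0, "p": [1e-9, 1e-9, 1e-9],
                            "fdr": [1e-8, 1e-8, 1e-8]})
        out = de.ma_summary(tab, fdr_cut=0.05)
        assert (out["n_up"], out["n_down"]) == (1, 1)  # log2fc == 0 never counted
        none = de.ma_summary(tab.assign(fdr=1.0))
        assert (none["n_up"], none["n_down"]) == (0, 0)

    def test_ma_summary_recovers_planted_direction_counts(self):
        # 100 up / 50 down planted with near-zero dispersion: all reach FDR
        truth = syn.make_de_truth(n_genes=1000, n_pairs=4, de_frac=0.15, lfc=4.0,
                                  dispersion=0.001, seed=21)
        truth.dispersion[:] = 0.001
        n_planted_up = int((truth.true_lfc > 0).sum())
        n_planted_down = int((truth.true_lfc < 0).sum())
        cm = syn.gen_counts(truth, seed=21)
        out = de.ma_summary(de.run_de(cm), fdr_cut=0.05)
        se_up = np.sqrt(n_planted_up)
        se_down = np.sqrt(n_planted_down)
        assert abs(out["n_up"] - n_planted_up) <= 3 * se_up
        assert abs(out["n_down"] - n_planted_down) <= 3 * se_down

    def test_signature_lengths(self):
        tab = self.make_de(600, 400)
        up, down = de.extract_signature(tab, n=500)
        assert (len(up), len(down)) == (500, 400)
        up_all, down_all = de.extract_signature(tab, n=10_000)
        assert (len(up_all), len(down_all)) == (600, 400)

    def test_signature_tie_break_is_deterministic(self):
        tab = pd.DataFrame({"gene": ["b", "a", "c", "d"],
                            "log2fc": [1.0, 2.0, 1.0, 0.5],
                            "mean_log2cpm": 5.0,
                            "p": [0.01, 0.01, 0.01, 0.01],
                            "fdr": [0.01] * 4})
        up1, _ = de.extract_signature(tab, n=2)
        up2, _ = de.extract_signature(tab.sample(frac=1, random_state=1), n=2)
        assert up1 == up2 == ["a", "b"]  # |log2fc| desc, then symbol

    def test_top_up_set(self):
        tab = self.make_de(300, 100)
        top = de.top_up_set(tab, n=250)
        assert len(top) == 250
        small = de.top_up_set(self.make_de(100, 50), n=250)
        assert len(small) == 100
        down_genes = set(tab.loc[tab["log2fc"] < 0, "gene"])
        assert not set(top) & down_genes


class TestConcordance:
    def test_self_and_negated_correlation(self):
        tab = TestSummariesAndSignatures().make_de(50, 50, seed=2)
        assert de.concordance(tab, tab)["r_s"] == pytest.approx(1.0)
        neg = tab.assign(log2fc=-tab["log2fc"])
        assert de.concordance(tab, neg)["r_s"] == pytest.approx(-1.0)

    def test_too_few_shared_genes(self):
        tab = TestSummariesAndSignatures().make_de(5, 4, seed=3)
        with pytest.raises(ValueError, match="shared genes"):
            de.concordance(tab, tab)

    def test_opposed_shared_program_recovers_negative_sign(self):
        # two datasets share a latent program with opposite loadings (the
        # knockdown-vs-stemness situation): r_s must come out negative
        rng = np.random.default_rng(4)
        program = rng.normal(0, 1, 400)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = pd.DataFrame({"gene": [f"g{i}" for i in range(400)],
                              "log2fc": -program + rng.normal(0, 0.8, 400),
                              "mean_log2cpm": 5.0, "p": 0.5, "fdr": 0.5})
            b = a.assign(log2fc=program + rng.normal(0, 0.8, 400))
            assert de.concordance(a, b)["r_s"] < 0

    def test_trend_covers_all_genes(self):
        tab = TestSummariesAndSignatures().make_de(100, 100, seed=5)
        res = de.concordance(tab, tab, window_frac=0.05)
        assert len(res["trend"]) == res["n"] == 200
        assert np.all(np.diff(res["trend"]["x"]) >= 0)


class TestHalflifeBias:
    def test_independent_halflife_not_flagged(self):
        rng = np.random.default_rng(6)
        n = 5000
        tab = pd.DataFrame({"gene": [f"g{i}" for i in range(n)],
                            "log2fc": rng.normal(0, 1, n), "mean_log2cpm": 5.0,
                            "p": 0.5, "fdr": 0.5})
        hl = pd.Series(np.exp(rng.normal(2, 0.8, n)), index=tab["gene"])
        res = de.halflife_bias(tab, hl)
        assert abs(res["r_s"]) < 3 / np.sqrt(n) + 0.01
        assert not res["bias_flag"]

    def test_forced_confounding_flagged(self):
        n = 200
        tab = pd.DataFrame({"gene": [f"g{i}" for i in range(n)],
                            "log2fc": np.linspace(-2, 2, n), "mean_log2cpm": 5.0,
                            "p": 0.5, "fdr": 0.5})
        hl = pd.Series(np.exp(np.linspace(0, 3, n)), index=tab["gene"])
        res = de.halflife_bias(tab, hl)
        assert res["r_s"] == pytest.approx(1.0)
        assert res["bias_flag"]

    def test_quartile_means_average_to_global_mean(self):
        rng = np.random.default_rng(7)
        n = 400
        tab = pd.DataFrame({"gene": [f"g{i}" for i in range(n)],
                            "log2fc": rng.normal(0.3, 1, n), "mean_log2cpm": 5.0,
                            "p": 0.5, "fdr": 0.5})
        hl = pd.Series(rng.uniform(1, 20, n), index=tab["gene"])
        res = de.halflife_bias(tab, hl)
        q = res["quartile_means"]
        weighted = (q["mean"] * q["count"]).sum() / q["count"].sum()
        assert weighted == pytest.approx(tab["log2fc"].mean())

    def test_insufficient_overlap_rejected(self):
        tab = pd.DataFrame({"gene": ["a", "b"], "log2fc": [0, 0],
                            "mean_log2cpm": 5.0, "p": 0.5, "fdr": 0.5})
        with pytest.raises(ValueError):
            de.halflife_bias(tab, pd.Series([1.0], index=["a"]))
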