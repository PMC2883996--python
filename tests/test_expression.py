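"""Normalization and ratio-statistics tests with independent oracles."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dosacomp as dc

from conftest import noiseless_config, null_config, small_config


class TestBackground:
    def test_median_of_constant_controls(self, tiny_matrix_factory):
        m = tiny_matrix_factory(
            {"g1": ("Ch1", 1)},
            np.vstack([np.full(2, 1000.0)] + [np.full(2, 100.0)] * 3),
            n_controls=3, n_replicates=1,
        )
        assert dc.estimate_background(m, "P1") == 100.0

    def test_odd_length_median(self, tiny_matrix_factory):
        ctrl = np.array([50.0, 100.0, 150.0, 200.0, 250.0])
        m = tiny_matrix_factory(
            {"g1": ("Ch1", 1)},
            np.vstack([[900.0, 900.0], np.stack([ctrl, ctrl], axis=1)]),
            n_controls=5, n_replicates=1,
        )
        assert dc.estimate_background(m, "P1") == 150.0

    def test_matches_sort_based_median_oracle(self, tiny_matrix_factory):
        # brute-force oracle: sort and take the middle element(s)
        rng = np.random.default_rng(42)
        ctrl = np.clip(rng.normal(0, 200, size=395), 0, None)
        m = tiny_matrix_factory(
            {"g1": ("Ch1", 1)},
            np.vstack([[900.0, 900.0], np.stack([ctrl, ctrl], axis=1)]),
            n_controls=395, n_replicates=1,
        )
        ordered = np.sort(ctrl)
        n = len(ordered)
        oracle = (
            ordered[n // 2]
            if n % 2
            else 0.5 * (ordered[n // 2 - 1] + ordered[n // 2])
        )
        assert dc.estimate_background(m, "P1") == oracle

    def test_no_controls_is_an_error(self, tiny_matrix_factory):
        m = tiny_matrix_factory({"g1": ("Ch1", 1)}, [[900.0, 900.0]])
        with pytest.raises(ValueError):
            dc.estimate_background(m, "P1")


class TestCorrectAndFilter:
    def test_subtraction_and_threshold(self, tiny_matrix_factory):
        # raw 1000 over background 150 -> corrected 850, above noise;
        # a gene at corrected 150 in one strain is filtered out
        m = tiny_matrix_factory(
            {"bright": ("Ch1", 1), "dim": ("Ch2", 1)},
            np.array([
                [1000.0, 1150.0],   # bright: corrected 850 / 1000
                [300.0, 1150.0],    # dim: corrected 150 in the parent only
                [150.0, 150.0],
            ]),
            n_controls=1, n_replicates=1,
        )
        corrected, above = dc.correct_and_filter(m, noise_threshold=200)
        assert corrected.signals.loc["bright_s1", "P1"] == 850.0
        assert bool(above["bright"]) is True
        assert bool(above["dim"]) is False

    def test_planted_below_noise_count(self):
        # 507 monosomic genes with 37 planted at the background level
        # leave 470 above noise
        cfg = noiseless_config(
            genes_per_chromosome=(60, 40, 40, 40, 40, 507, 40, 40),
            n_lost_genes=0, n_duplicated_genes=0,
        )
        _, truth = dc.simulate_genome(cfg)
        mono = truth.index[truth["chromosome"] == "Ch5"]
        truth.loc[mono[:37], "true_level"] = 50.0  # below the 200 threshold
        m = dc.simulate_expression_chips(truth, cfg)
        _, above = dc.correct_and_filter(m)
        chrom = truth.set_index("gene_id")["chromosome"]
        assert int(above[chrom == "Ch5"].sum()) == 470


class TestScaleChips:
    def test_direct_arithmetic_oracle(self, tiny_matrix_factory):
        # chip totals 1000 and 2000 -> factors 1.5 and 0.75, both -> 1500
        m = tiny_matrix_factory(
            {"a": ("Ch1", 1), "b": ("Ch2", 1), "c": ("Ch5", 1)},
            np.array([[400.0, 800.0], [600.0, 1200.0], [111.0, 222.0]]),
            n_replicates=1,
        )
        scaled, factors = dc.scale_chips(m, "Ch5")
        assert factors.tolist() == [1.5, 0.75]
        ref = scaled.probes[scaled.probes["chromosome"] != "Ch5"]["probe_id"]
        totals = scaled.signals.loc[ref].sum()
        np.testing.assert_allclose(totals.to_numpy(), 1500.0, rtol=1e-12)

    def test_identical_chips_untouched(self, tiny_matrix_factory):
        m = tiny_matrix_factory(
            {"a": ("Ch1", 1), "c": ("Ch5", 1)},
            np.array([[400.0, 400.0], [50.0, 60.0]]),
            n_replicates=1,
        )
        _, factors = dc.scale_chips(m, "Ch5")
        assert factors.tolist() == [1.0, 1.0]

    def test_missing_chromosome_rejected(self, tiny_matrix_factory):
        m = tiny_matrix_factory({"a": ("Ch1", 1)}, [[1.0, 2.0]],
                                n_replicates=1)
        with pytest.raises(ValueError):
            dc.scale_chips(m, "Ch9")

    def test_conservation_on_random_matrices(self, tiny_matrix_factory):
        # invariant: non-excluded totals agree across chips to 1e-6 relative
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_genes = rng.integers(3, 30)
            genes = {
                f"g{i}": (rng.choice(["Ch1", "Ch2", "Ch5"]), 1)
                for i in range(n_genes)
            }
            genes["g_ref"] = ("Ch1", 1)   # reference set never empty
            genes["g_mono"] = ("Ch5", 1)  # excluded chromosome present
            sig = rng.uniform(10, 5000, size=(len(genes), 6))
            m = tiny_matrix_factory(genes, sig)
            scaled, _ = dc.scale_chips(m, "Ch5")
            ref = scaled.probes[
                scaled.probes["chromosome"] != "Ch5"
            ]["probe_id"]
            totals = scaled.signals.loc[ref].sum()
            assert np.ptp(totals.to_numpy()) <= 1e-6 * totals.mean()

    def test_all_gene_normalization_is_close_without_trans_effects(
        self, default_config
    ):
        # with no trans-regulation, normalizing by every gene instead of the
        # off-monosome set shifts each ratio by a common factor of roughly
        # 1 + (1 - mean Ch5 fold) x Ch5 signal share ~ 2%: "very similar"
        _, truth = dc.simulate_genome(default_config)
        m = dc.simulate_expression_chips(truth, default_config)
        t1 = dc.build_gene_table(m, "Ch5", add_bh=False)
        t2 = dc.build_gene_table(m, None, add_bh=False)
        rel = (t2["mean_ratio"] / t1["mean_ratio"] - 1).abs()
        assert rel.max() < 0.03

    def test_scale_equivariance(self, tiny_matrix_factory):
        # multiplying one chip's raw signals by c > 0 must not move any
        # post-scaling ratio (flat zero background case)
        base = np.array([[400.0, 800.0, 500.0, 900.0],
                         [600.0, 300.0, 700.0, 800.0],
                         [120.0, 140.0, 70.0, 90.0]])
        genes = {"a": ("Ch1", 1), "b": ("Ch2", 1), "c": ("Ch5", 1)}

        def ratios(sig):
            m = tiny_matrix_factory(genes, sig)
            scaled, _ = dc.scale_chips(m, "Ch5")
            return dc.gene_ratio_table(scaled)["mean_ratio"]

        boosted = base.copy()
        boosted[:, 1] *= 7.3
        pd.testing.assert_series_equal(ratios(base), ratios(boosted))


class TestGeneRatio:
    def test_hand_arithmetic_oracle(self, tiny_matrix_factory):
        # pairs (200/100, 300/150, 450/150) -> mean 2.33...
        m = tiny_matrix_factory(
            {"g": ("Ch1", 1)},
            np.array([[100.0, 150.0, 150.0, 200.0, 300.0, 450.0]]),
        )
        mean, median = dc.gene_ratio(m, "g")
        assert mean == pytest.approx((2.0 + 2.0 + 3.0) / 3)
        assert median == pytest.approx(2.0)

    def test_identical_strains_give_unity(self, tiny_matrix_factory):
        m = tiny_matrix_factory(
            {"g": ("Ch1", 2)},
            np.array([[5.0, 7.0, 5.0, 7.0], [30.0, 8.0, 30.0, 8.0]]),
        )
        mean, median = dc.gene_ratio(m, "g")
        assert mean == 1.0 and median == 1.0

    def test_negative_signal_becomes_one(self, tiny_matrix_factory):
        # mutant scaled -5 with parent 100 -> that pair contributes 1/100
        m = tiny_matrix_factory(
            {"g": ("Ch1", 1)},
            np.array([[100.0, -5.0]]),
            n_replicates=1,
        )
        mean, _ = dc.gene_ratio(m, "g")
        assert mean == pytest.approx(0.01)

    def test_unknown_gene_raises(self, tiny_matrix_factory):
        m = tiny_matrix_factory({"g": ("Ch1", 1)}, [[1.0, 1.0]],
                                n_replicates=1)
        with pytest.raises(KeyError):
            dc.gene_ratio(m, "nope")

    def test_ratio_symmetry_under_strain_swap(self, tiny_matrix_factory):
        # noiseless gene: swapping strain labels maps r to 1/r
        sig = np.array([[100.0, 120.0, 80.0, 50.0, 60.0, 40.0]])
        swapped = sig[:, [3, 4, 5, 0, 1, 2]]
        m1 = tiny_matrix_factory({"g": ("Ch1", 1)}, sig)
        m2 = tiny_matrix_factory({"g": ("Ch1", 1)}, swapped)
        r1, _ = dc.gene_ratio(m1, "g")
        r2, _ = dc.gene_ratio(m2, "g")
        assert r1 == pytest.approx(0.5)
        assert r2 == pytest.approx(1 / r1)


class TestPerGeneTest:
    def test_identical_pairs_give_p_one(self, tiny_matrix_factory):
        m = tiny_matrix_factory(
            {"g": ("Ch1", 1)},
            np.array([[8.0, 9.0, 10.0, 8.0, 9.0, 10.0]]),
        )
        assert dc.per_gene_test(m, "g") == 1.0

    def test_textbook_paired_t_formula(self, tiny_matrix_factory):
        # log2 differences {1.0, 1.1, 0.9}: compare against the closed-form
        # paired-t statistic and the t CDF, coded independently here
        diffs = np.array([1.0, 1.1, 0.9])
        par = np.array([100.0, 200.0, 400.0])
        mut = par * 2.0 ** diffs
        m = tiny_matrix_factory(
            {"g": ("Ch1", 1)}, np.concatenate([par, mut])[None, :]
        )
        t_stat = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(3))
        expected = 2 * (1 - stats.t.cdf(abs(t_stat), df=2))
        assert dc.per_gene_test(m, "g") == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_nonzero_mean_floors_at_eps(self,
                                                      tiny_matrix_factory):
        m = tiny_matrix_factory(
            {"g": ("Ch1", 1)},
            np.array([[100.0, 200.0, 400.0, 200.0, 400.0, 800.0]]),
        )
        assert dc.per_gene_test(m, "g") == np.finfo(float).eps

    def test_agrees_with_scipy_on_random_instances(self, tiny_matrix_factory):
        # oracle equivalence: 1000 random small instances vs scipy ttest_rel
        rng = np.random.default_rng(7)
        n_rep = 4
        genes = {f"g{i}": ("Ch1", 1) for i in range(1000)}
        sig = rng.uniform(50, 5000, size=(1000, 2 * n_rep))
        m = tiny_matrix_factory(genes, sig)
        mine = dc.per_gene_test_table(m)
        ref = stats.ttest_rel(
            np.log2(sig[:, n_rep:]), np.log2(sig[:, :n_rep]), axis=1
        ).pvalue
        np.testing.assert_allclose(mine.to_numpy(), ref, atol=1e-8)

    def test_single_pair_rejected(self, tiny_matrix_factory):
        m = tiny_matrix_factory({"g": ("Ch1", 1)}, [[10.0, 20.0]],
                                n_replicates=1)
        with pytest.raises(ValueError):
            dc.per_gene_test(m, "g")


class TestChromosomeSummary:
    def test_all_compensated_noiseless_world(self):
        cfg = null_config(
            genes_per_chromosome=(60, 40, 40, 40, 40, 80, 40, 40),
            noise_cv=0.0, background_sd=0.0, background_mean=300.0, seed=2,
        )
        _, truth = dc.simulate_genome(cfg)
        m = dc.simulate_expression_chips(truth, cfg)
        table = dc.build_gene_table(m, "Ch5", add_bh=False)
        summary = dc.chromosome_summary(table).set_index("chromosome")
        np.testing.assert_allclose(summary["mean"].to_numpy(), 1.0,
                                   rtol=1e-9)
        np.testing.assert_allclose(summary["p_value"].to_numpy(), 1.0)

    def test_disomic_chromosomes_show_no_dosage_effect(self, default_run):
        # ratio-space averaging carries a small upward bias (~e^{2 sigma^2}),
        # so disomic chromosomes sit near, not exactly at, 1
        summary = default_run["chromosome_table"].set_index("chromosome")
        disomic = summary.drop(index="Ch5")
        assert (abs(disomic["mean"] - 1.0) < 0.03).all()
        assert (abs(disomic["median"] - 1.0) < 0.02).all()
        assert summary.loc["Ch5", "mean"] < 0.95

    def test_exclusion_bookkeeping(self, default_run):
        # below-noise genes leave mean/median/p but never the gene counts
        summary = default_run["chromosome_table"].set_index("chromosome")
        truth = default_run["truth"]
        counts = truth.groupby("chromosome").size()
        for chrom, row in summary.iterrows():
            assert row["n_genes"] == counts[chrom]
            assert row["n_above_noise"] <= row["n_genes"]

    def test_spot_mode_matches_gene_mode_direction(self, default_run):
        table = default_run["gene_table"]
        genes = dc.chromosome_summary(table, mode="genes")
        spots = dc.chromosome_summary(table, mode="spots")
        ch5_g = genes.set_index("chromosome").loc["Ch5", "p_value"]
        ch5_s = spots.set_index("chromosome").loc["Ch5", "p_value"]
        assert ch5_g < 1e-6 and ch5_s < 1e-6


class TestGcAnova:
    def test_planted_gc_trend_detected(self):
        # power check: a 0.5 log2-unit linear trend across GC must light up
        rng = np.random.default_rng(3)
        gc = rng.uniform(0.3, 0.55, 600)
        ratios = 0.5 * (gc - 0.3) / 0.25 + rng.normal(0, 0.05, 600)
        f, p = dc.gc_anova(gc, ratios)
        assert p < 0.001

    def test_constant_ratios_give_zero_f(self):
        gc = np.linspace(0.3, 0.55, 100)
        f, p = dc.gc_anova(gc, np.zeros(100))
        assert f == 0.0 and p == 1.0

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            dc.gc_anova(np.full(50, 0.4), np.random.default_rng(0).normal(size=50))
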