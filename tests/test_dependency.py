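"""Odds ratios, chi-square, multiple-testing and conditional analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import triomics as t
from triomics.dependency import (
    adjust,
    chi_square_p,
    conditional_dependency,
    make_table,
    odds_ratio,
    pairwise_dependency,
)
from triomics.errors import ValidationError
from triomics.simulate import simulate_dataset, simulate_genome

from conftest import make_call_matrix
import oracles


class TestContingency:
    def test_toy_cross_tabulation(self):
        # 10 genes: 3 gain, 4 over, 2 both -> (2, 1, 2, 5)
        genes = [f"g{i}" for i in range(10)]
        assign = {}
        for g in genes[:2]:
            assign[(g, "s1")] = ["gain", "over"]
        assign[("g2", "s1")] = ["gain"]
        for g in genes[3:5]:
            assign[(g, "s1")] = ["over"]
        calls = make_call_matrix(genes, ["s1"], assign)
        tab = make_table(calls, "s1", "gain", "over")
        assert (tab.a, tab.b, tab.c, tab.d) == (2, 1, 2, 5)

    def test_counts_sum_to_universe(self, small_calls):
        tab = make_table(small_calls, small_calls.samples[0], "gain", "hyper")
        assert tab.n == small_calls.n_genes

    def test_all_zero_channel_gives_empty_b_column(self):
        calls = make_call_matrix(
            [f"g{i}" for i in range(5)], ["s1"], {("g0", "s1"): ["gain"]}
        )
        tab = make_table(calls, "s1", "gain", "over")
        assert tab.a == 0 and tab.c == 0

    def test_same_platform_pair_rejected(self, small_calls):
        with pytest.raises(ValidationError):
            make_table(small_calls, small_calls.samples[0], "gain", "loss")


class TestOddsRatio:
    def test_hand_computed(self):
        assert odds_ratio(t.ContingencyTable(2, 1, 2, 5), "none") == 5.0

    def test_haldane_correction(self):
        or_ = odds_ratio(t.ContingencyTable(0, 1, 1, 8), "haldane")
        assert or_ == pytest.approx((0.5 * 8.5) / (1.5 * 1.5))

    def test_zero_denominator_inf_under_none_policy(self):
        assert np.isinf(odds_ratio(t.ContingencyTable(3, 0, 2, 5), "none"))

    def test_independence_gives_or_near_one(self):
        rng = np.random.default_rng(0)
        a_vec = rng.random(20000) < 0.3
        b_vec = rng.random(20000) < 0.2
        tab = t.ContingencyTable(
            int((a_vec & b_vec).sum()), int((a_vec & ~b_vec).sum()),
            int((~a_vec & b_vec).sum()), int((~a_vec & ~b_vec).sum()),
        )
        assert odds_ratio(tab) == pytest.approx(1.0, abs=0.15)

    def test_symmetry_under_channel_swap(self, small_calls):
        s = small_calls.samples[0]
        t1 = make_table(small_calls, s, "gain", "hyper")
        t2 = make_table(small_calls, s, "hyper", "gain")
        assert odds_ratio(t1) == pytest.approx(odds_ratio(t2))


class TestChiSquare:
    def test_perfect_association(self):
        _, p, degen = chi_square_p(t.ContingencyTable(50, 0, 0, 50))
        assert p < 1e-20 and not degen

    def test_observed_equal_expected_gives_stat_zero(self):
        stat, p, _ = chi_square_p(t.ContingencyTable(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0

    def test_degenerate_margin_flagged(self):
        stat, p, degen = chi_square_p(t.ContingencyTable(0, 0, 3, 7))
        assert degen and p == 1.0

    @pytest.mark.parametrize("cells", [(2, 1, 2, 5), (8, 3, 1, 12), (5, 5, 5, 5)])
    def test_matches_expected_count_oracle(self, cells):
        stat, _, _ = chi_square_p(t.ContingencyTable(*cells))
        assert stat == pytest.approx(oracles.pearson_chi2(*cells))

    def test_transposition_invariance(self):
        s1, _, _ = chi_square_p(t.ContingencyTable(4, 2, 7, 9))
        s2, _, _ = chi_square_p(t.ContingencyTable(4, 7, 2, 9))
        assert s1 == pytest.approx(s2)


class TestAdjust:
    def test_bonferroni_scales_by_family_size(self):
        ps = [0.01] + [0.5] * 11
        adj = adjust(ps, "bonferroni")
        assert adj[0] == pytest.approx(0.12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bh_matches_stepup_oracle(self, ps):
        assert np.allclose(adjust(ps, "bh"), oracles.bh_stepup(ps))

    def test_all_ones_stay_one(self):
        assert (adjust([1.0] * 5, "bh") == 1.0).all()
        assert (adjust([1.0] * 5, "bonferroni") == 1.0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            adjust([], "bh")


class TestExhaustiveTableEquivalence:
    def test_or_and_chi2_on_enumerated_small_tables(self):
        """Sweep all 2x2 tables with n <= 8 against brute-force oracles."""
        for n in range(1, 9):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        tab = t.ContingencyTable(a, b, c, d)
                        a_vec = [True] * (a + b) + [False] * (c + d)
                        b_vec = (
                            [True] * a + [False] * b + [True] * c + [False] * d
                        )
                        assert odds_ratio(tab) == pytest.approx(
                            oracles.odds_ratio_direct(a_vec, b_vec)
                        )
                        arr = tab.as_array()
                        if (arr.sum(axis=0) > 0).all() and (arr.sum(axis=1) > 0).all():
                            stat, _, _ = chi_square_p(tab)
                            assert stat == pytest.approx(
                                oracles.pearson_chi2(a, b, c, d), abs=1e-10
                            )


class TestPairwise:
    def test_twelve_rows_per_sample_with_family_correction(self, small_calls):
        dep = pairwise_dependency(small_calls, method="bh")
        assert (dep.groupby("sample").size() == 12).all()
        for _, grp in dep.groupby("sample"):
            assert np.allclose(
                grp["p_adj"].to_numpy(), oracles.bh_stepup(grp["p"].to_numpy())
            )

    def test_planted_coupling_detected(self, recovery_run):
        """gain+over planting drives OR > 1 in affected samples."""
        _, data, calls = recovery_run
        dep = pairwise_dependency(calls)
        sub = dep[dep["combo"] == "gain+over"]
        assert sub["odds_ratio"].median() > 1.5
        assert (sub["p_adj"] < 0.05).mean() > 0.5


class TestConditional:
    def test_planted_three_way_coupling_in_gain_stratum(self):
        cfg = t.SimulationConfig(
            seed=7, planted=(t.PlantedSet("gain+hyper+under", 40, 10),)
        )
        g = simulate_genome(cfg)
        d = simulate_dataset(cfg, g)
        calls = t.build_call_matrix(
            d.segments, d.beta, d.expression, g.annotation,
            d.meth_probe_map, d.expr_probe_map,
        )
        cond = conditional_dependency(calls)
        gain_under = cond[(cond.stratum == "gain") & (cond.expr_state == "under")]
        estimable = gain_under[~gain_under.not_estimable]
        assert (estimable.odds_ratio > 1).mean() > 0.9
        assert (estimable.p_adj < 0.05).mean() > 0.8
        # no hyper->under coupling planted outside the gain stratum
        loss_under = cond[(cond.stratum == "loss") & (cond.expr_state == "under")]
        ok = loss_under[~loss_under.not_estimable]
        if len(ok):
            assert (ok.p_adj < 0.05).mean() < 0.3

    def test_stratum_tables_sum_to_stratum_size(self, small_calls):
        cond = conditional_dependency(small_calls)
        ok = cond[cond.n_stratum > 0]
        assert ((ok.a + ok.b + ok.c + ok.d) == ok.n_stratum).all()

    def test_empty_stratum_flagged_not_estimable(self):
        calls = make_call_matrix(
            ["g1", "g2"], ["s1"], {("g1", "s1"): ["hyper"]}
        )
        cond = conditional_dependency(calls)
        gain_rows = cond[cond.stratum == "gain"]
        assert gain_rows.not_estimable.all()


class TestNullCalibration:
    def test_null_rejection_fraction_bounded(self):
        """Adjusted p < 0.05 in <= 5% of combos under null data."""
        fracs = {"bh": [], "bonferroni": []}
        ors = []
        for i in range(40):
            cfg = t.SimulationConfig.null(
                seed=5000 + i, n_chromosomes=4, genes_per_chromosome=30,
                tiles_per_chromosome=8, n_case_samples=5,
            )
            g = simulate_genome(cfg)
            d = simulate_dataset(cfg, g)
            calls = t.build_call_matrix(
                d.segments, d.beta, d.expression, g.annotation,
                d.meth_probe_map, d.expr_probe_map,
            )
            for method in fracs:
                dep = pairwise_dependency(calls, method=method)
                fracs[method].append((dep["p_adj"] < 0.05).mean())
                if method == "bh":
                    ors.extend(dep["odds_ratio"].tolist())
        assert np.mean(fracs["bh"]) <= 0.05
        assert np.mean(fracs["bonferroni"]) <= 0.05
        # odds ratios hover around 1 without planted coupling
        assert abs(np.median(ors) - 1.0) < 0.25
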