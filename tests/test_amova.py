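"""Hierarchical AMOVA against a brute-force pairwise-distance oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pyrodiv.genotype_core import MISSING
from pyrodiv.hierarchical_amova import amova, amova_permutation_test
from pyrodiv.synthetic_data import SimConfig, fixture_suite, simulate_population

from conftest import make_table, random_table


# ------------------------------------------------------------------ oracle
# Literal distance-based decomposition: every pairwise squared distance
# between allele copies, cluster SS = sum d^2 / cluster size, nested ANOVA
# coefficients written out with plain loops. No code shared with the
# implementation.


def oracle_amova(table):
    n = table.n_individuals
    loci = range(table.n_loci)
    typed = [(table.calls[i] != MISSING).all(axis=1) for i in range(n)]
    copies = [(i, k) for i in range(n) for k in (0, 1)]

    def d2(u, v):
        (i, ki), (j, kj) = u, v
        total = 0
        for l in loci:
            if typed[i][l] and typed[j][l]:
                if table.calls[i, l, ki] != table.calls[j, l, kj]:
                    total += 1
        return total

    def cluster_ss(members):
        s = 0.0
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                s += d2(members[a], members[b])
        return s / len(members) if members else 0.0

    blocks = table.group_labels("block")
    plots = table.group_labels("plot")
    block_ids = list(dict.fromkeys(blocks))
    plot_ids = list(dict.fromkeys(plots))

    ss_total = cluster_ss(copies)
    ss_wb = sum(
        cluster_ss([c for c in copies if blocks[c[0]] == b]) for b in block_ids
    )
    ss_wp = sum(
        cluster_ss([c for c in copies if plots[c[0]] == p]) for p in plot_ids
    )
    ss_wi = sum(cluster_ss([(i, 0), (i, 1)]) for i in range(n))

    ss = [ss_total - ss_wb, ss_wb - ss_wp, ss_wp - ss_wi, ss_wi]
    df = [len(block_ids) - 1, len(plot_ids) - len(block_ids),
          n - len(plot_ids), n]
    ms = [s / d if d > 0 else float("nan") for s, d in zip(ss, df)]

    # EMS coefficients for the unbalanced nested design (copies as units)
    m_total = 2 * n
    m_plot = {p: 2 * sum(1 for x in plots if x == p) for p in plot_ids}
    m_block = {b: 2 * sum(1 for x in blocks if x == b) for b in block_ids}
    plot_block = {p: blocks[list(plots).index(p)] for p in plot_ids}
    term_pb = sum(
        sum(m_plot[p] ** 2 for p in plot_ids if plot_block[p] == b) / m_block[b]
        for b in block_ids
    )
    term_p = sum(v**2 for v in m_plot.values()) / m_total
    term_b = sum(v**2 for v in m_block.values()) / m_total
    k_b2 = (m_total - term_pb) / df[1] if df[1] > 0 else float("nan")
    k_a2 = (term_pb - term_p) / df[0]
    k_a3 = (m_total - term_b) / df[0]

    var_d = ms[3]
    var_c = (ms[2] - var_d) / 2 if df[2] > 0 else 0.0
    var_b = (ms[1] - var_d - 2 * var_c) / k_b2 if df[1] > 0 else 0.0
    var_a = (ms[0] - var_d - 2 * var_c - k_a2 * var_b) / k_a3
    return {"ss": ss, "df": df, "var": [var_a, var_b, var_c, var_d]}


def structured_table(rng, n_blocks=2, plots_per_block=2, n_per_plot=3, n_loci=3):
    cfg = SimConfig(
        n_blocks=n_blocks, plots_per_block=(plots_per_block,) * n_blocks,
        n_ind_per_plot=n_per_plot, n_loci=n_loci, n_alleles_per_locus=4,
        theta_block=0.2, theta_plot=0.2, selfing_rate=0.5,
        missing_rate=0.1, null_allele_freq=0.0, genotyping_error_rate=0.0,
    )
    return simulate_population(cfg, rng).table


class TestDecomposition:
    def test_identical_individuals_all_zero(self):
        rows = [
            (f"i{i}", f"B{i % 2}", f"B{i % 2}-P{i % 2}", "none") for i in range(6)
        ]
        t = make_table(rows, ["L1", "L2"], np.full((6, 2, 2), 100))
        r = amova(t)
        assert np.allclose(r.levels["ss"], 0)
        assert np.allclose(r.levels["variance"], 0)
        assert all(math.isnan(v) for v in r.f_stats.values())

    def test_two_fixed_blocks_all_variance_among_blocks(self):
        t = fixture_suite(0)["two_fixed_blocks"]
        r = amova(t)
        pct = dict(zip(r.levels["level"], r.levels["percent"]))
        assert pct["among_blocks"] == pytest.approx(100.0)
        assert r.f_stats["f_rt"] == pytest.approx(1.0)
        assert r.f_stats["f_st"] == pytest.approx(1.0)
        assert r.f_stats["f_it"] == pytest.approx(1.0)

    def test_df_totals_match_design(self, rng):
        t = structured_table(rng)
        r = amova(t)
        assert r.levels["df"].sum() == 2 * t.n_individuals - 1

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        """SS, df and variance components equal the pairwise-distance oracle."""
        rng = np.random.default_rng(seed)
        t = structured_table(
            rng,
            n_blocks=int(rng.integers(2, 4)),
            plots_per_block=int(rng.integers(1, 3)),
            n_per_plot=int(rng.integers(2, 5)),
        )
        assert t.n_individuals <= 30
        r = amova(t)
        expect = oracle_amova(t)
        assert list(r.levels["df"]) == expect["df"]
        assert np.allclose(r.levels["ss"], expect["ss"], atol=1e-9)
        assert np.allclose(r.levels["variance"], expect["var"], atol=1e-9)

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_percents_sum_to_100_and_match_components(self, seed):
        t = structured_table(np.random.default_rng(seed))
        r = amova(t)
        assert r.levels["percent"].sum() == pytest.approx(100.0, abs=0.01)
        tot = r.levels["variance"].sum()
        assert np.allclose(
            r.levels["percent"], 100 * r.levels["variance"] / tot, atol=1e-9
        )

    def test_fst_is_block_plus_plot_share(self, rng):
        t = structured_table(rng)
        r = amova(t)
        var = r.variance_components
        tot = sum(var.values())
        assert r.f_stats["f_st"] == pytest.approx(
            (var["among_blocks"] + var["among_plots"]) / tot
        )

    def test_single_block_rejected(self):
        rows = [("i1", "B1", "P1", "none"), ("i2", "B1", "P2", "none")]
        t = make_table(rows, ["L1"], [[[1, 2]], [[1, 1]]])
        with pytest.raises(ValueError, match="two blocks"):
            amova(t)

    def test_truncation_flag(self, rng):
        t = structured_table(rng)
        r = amova(t, truncate_negative=True)
        assert (r.levels["percent"] >= 0).all()
        assert r.levels["percent"].sum() == pytest.approx(100.0, abs=0.01)


class TestThreeLevelCollapse:
    def test_collapsed_equals_pooled_four_level(self, rng):
        t = structured_table(rng)
        four = amova(t, include_within_individual=True)
        three = amova(t, include_within_individual=False)
        v4 = four.variance_components
        v3 = three.variance_components
        assert v3["among_blocks"] == pytest.approx(v4["among_blocks"])
        assert v3["among_plots"] == pytest.approx(v4["among_plots"])
        assert v3["within_plots"] == pytest.approx(
            v4["among_individuals"] + v4["within_individuals"]
        )
        assert set(three.f_stats) == {"f_rt", "f_sr", "f_st"}
        assert three.levels["df"].sum() == 2 * t.n_individuals - 1


class TestPermutationTest:
    def test_deterministic_under_seeding(self, rng):
        t = structured_table(rng)
        r = amova(t)
        p1 = amova_permutation_test(r, t, 30, np.random.default_rng(5))
        p2 = amova_permutation_test(r, t, 30, np.random.default_rng(5))
        assert p1 == p2

    def test_structured_data_rejects(self):
        cfg = SimConfig(
            n_blocks=3, plots_per_block=(2, 2, 2), n_ind_per_plot=8, n_loci=8,
            theta_block=0.3, theta_plot=0.05, selfing_rate=0.0,
            missing_rate=0.0, null_allele_freq=0.0, genotyping_error_rate=0.0,
        )
        t = simulate_population(cfg, np.random.default_rng(21)).table
        r = amova(t)
        p = amova_permutation_test(
            r, t, 99, np.random.default_rng(6), statistics=("f_rt",)
        )
        assert p["f_rt"] <= 0.05

    def test_panmictic_data_does_not_reject(self):
        t = random_table(
            np.random.default_rng(17), n_blocks=3, plots_per_block=2,
            n_ind_per_plot=6, n_loci=6, missing_rate=0.0,
        )
        r = amova(t)
        p = amova_permutation_test(
            r, t, 99, np.random.default_rng(8), statistics=("f_rt", "f_sr")
        )
        assert p["f_rt"] > 0.05 or p["f_sr"] > 0.05
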