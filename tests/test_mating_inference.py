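"""Progeny QC, non-maternal allele counting, and the selfing null."""

import numpy as np
import pandas as pd
import pytest

from pyrodiv.genotype_core import MISSING
from pyrodiv.het_indices import FrequencyReference
from pyrodiv.mating_inference import (
    ProgenyArray,
    build_progeny_arrays,
    build_selfing_null,
    classify_all,
    classify_seeds,
    count_non_maternal,
    mothers_table,
    observed_means,
    qc_progeny,
    seeds_table,
    selfing_test,
    simulate_selfed_dataset,
)
from pyrodiv.synthetic_data import SimConfig, fixture_suite, simulate_progeny_arrays


def arr(mother, seeds, loci=None):
    mother = np.asarray(mother)
    seeds = np.asarray(seeds)
    return ProgenyArray(
        mother_id="M1",
        loci=loci or [f"L{j + 1}" for j in range(mother.shape[0])],
        mother=mother,
        seed_ids=[f"s{k + 1}" for k in range(len(seeds))],
        seeds=seeds,
    )


class TestQC:
    def test_seed_sharing_no_maternal_allele_removed(self):
        a = arr([[1, 2]], [[[3, 4]], [[1, 3]]])
        kept, removed = qc_progeny(a)
        assert removed == ["s1"]
        assert kept.seed_ids == ["s2"]
        assert kept.qc_flags["s1"] == "maternal_mismatch"

    def test_seed_with_no_cotyped_locus_removed_as_failure(self):
        a = arr([[1, 2]], [[[MISSING, MISSING]]])
        kept, removed = qc_progeny(a)
        assert kept.n_seeds == 0 and kept.qc_flags["s1"] == "no_cotyped_loci"

    def test_missing_loci_skipped_not_fatal(self):
        mother = [[1, 2], [MISSING, MISSING]]
        a = arr(mother, [[[1, 3], [5, 6]]])
        kept, removed = qc_progeny(a)
        assert kept.n_seeds == 1  # mismatch only at a maternally untyped locus


class TestNonMaternalCount:
    @pytest.mark.parametrize(
        "mother,seed,expected",
        [
            ([[1, 2]], [[1, 2]], 0),  # both copies explainable
            ([[1, 1]], [[1, 3]], 1),  # one paternal novel allele
            ([[1, 2]], [[3, 3]], 2),  # no maternal copy at all (pre-QC case)
            ([[1, 2]], [[2, 2]], 0),  # homozygous for a maternal allele
            ([[1, 1], [2, 3]], [[1, 4], [3, 5]], 2),  # summed over loci
        ],
    )
    def test_minimal_assignment_rule(self, mother, seed, expected):
        assert count_non_maternal(np.array(mother), np.array(seed)) == expected

    def test_disjoint_locus_sets_undefined(self):
        m = np.array([[1, 2], [MISSING, MISSING]])
        s = np.array([[MISSING, MISSING], [1, 2]])
        assert count_non_maternal(m, s) is None


class TestClassification:
    def test_categories(self):
        a = arr(
            [[1, 2], [3, 3]],
            [
                [[1, 2], [3, 3]],  # maternal only
                [[1, 5], [3, 3]],  # single
                [[1, 5], [3, 6]],  # multi
            ],
        )
        df, totals = classify_seeds(a)
        assert list(df["category"]) == [
            "maternal_only", "single_non_maternal", "multi_non_maternal"
        ]
        assert totals == {
            "maternal_only": 1, "single_non_maternal": 1, "multi_non_maternal": 1
        }

    def test_selfed_fixture_all_maternal_only(self):
        arrays = fixture_suite(3)["selfed_arrays"]
        _, totals = classify_all(arrays)
        assert totals["single_non_maternal"] == 0
        assert totals["multi_non_maternal"] == 0
        assert totals["maternal_only"] == sum(a.n_seeds for a in arrays)


class TestSelfedSimulation:
    def test_homozygous_mother_breeds_true(self, rng):
        a = arr([[1, 1], [2, 2]], np.empty((0, 2, 2), dtype=int))
        sim = simulate_selfed_dataset([a], seeds_per_mother=6, rng=rng)
        assert (sim.calls == np.array([[1, 1], [2, 2]])).all()

    def test_maternal_missing_locus_stays_missing(self, rng):
        a = arr([[1, 2], [MISSING, MISSING]], np.empty((0, 2, 2), dtype=int))
        sim = simulate_selfed_dataset([a], seeds_per_mother=4, rng=rng)
        assert (sim.calls[:, 1] == MISSING).all()

    def test_mendelian_halving_of_pht(self, rng):
        """Selfed-seed mean PHt converges to half the maternal PHt."""
        mother = np.array([[1, 2], [3, 4], [5, 5], [6, 7]])  # PHt = 0.75
        a = arr(mother, np.empty((0, 4, 2), dtype=int))
        n = 4000
        sim = simulate_selfed_dataset([a], seeds_per_mother=n, rng=rng)
        het = (sim.calls[:, :, 0] != sim.calls[:, :, 1]).mean(axis=1)
        se = het.std(ddof=1) / np.sqrt(n)
        assert het.mean() == pytest.approx(0.5 * 0.75, abs=2 * se + 1e-9)

    def test_rejects_nonpositive_counts(self, rng):
        a = arr([[1, 2]], np.empty((0, 1, 2), dtype=int))
        with pytest.raises(ValueError):
            simulate_selfed_dataset([a], seeds_per_mother=0, rng=rng)


class TestSelfingNull:
    def _arrays(self, seed=7, t=0.0):
        cfg = SimConfig(outcross_rate=t, genotyping_error_rate=0.0,
                        missing_rate=0.0, null_allele_freq=0.0, rng_seed=seed)
        arrays, _ = simulate_progeny_arrays(
            cfg, n_mothers=9, seeds_per_mother=5, rng=np.random.default_rng(seed)
        )
        return [qc_progeny(a)[0] for a in arrays]

    def test_deterministic_under_seeding(self):
        arrays = self._arrays()
        n1 = build_selfing_null(arrays, 50, np.random.default_rng(11))
        n2 = build_selfing_null(arrays, 50, np.random.default_rng(11))
        pd.testing.assert_frame_equal(n1.replicate_means, n2.replicate_means)
        assert n1.bands == n2.bands

    def test_degenerate_homozygous_mothers(self, rng):
        a = arr([[1, 1], [2, 2]], np.empty((0, 2, 2), dtype=int))
        a.seeds = np.array([[[1, 1], [2, 2]]] * 3)
        a.seed_ids = ["s1", "s2", "s3"]
        b = arr([[3, 3], [4, 4]], np.empty((0, 2, 2), dtype=int))
        b.mother_id = "M2"
        b.seeds = np.array([[[3, 3], [4, 4]]] * 3)
        b.seed_ids = ["t1", "t2", "t3"]
        null = build_selfing_null([a, b], 25, rng)
        assert (null.replicate_means["pht"] == 0).all()
        assert (null.replicate_means["ir"] == 1).all()
        assert (null.replicate_means["hl"] == 1).all()
        # any observed heterozygosity then falls above the degenerate band
        verdict = selfing_test({"pht": 0.2}, null)
        assert verdict["pht"] == "above_band"

    def test_vectorised_null_matches_per_replicate_simulation(self):
        """The banded null equals explicit simulate-then-score replicates in law.

        Checked by comparing the vectorised replicate means with means
        computed by the per-individual index path on datasets drawn with
        the same generator state.
        """
        from pyrodiv.het_indices import dataset_means, table_index_sets

        arrays = self._arrays(seed=3)
        ref = FrequencyReference.from_table(mothers_table(arrays))
        null = build_selfing_null(arrays, 3, np.random.default_rng(42), ref=ref)
        # the vectorised path consumes rng draws in the same (r, seed, locus,
        # copy) order as sequential per-replicate simulation
        rng = np.random.default_rng(42)
        counts = [a.n_seeds for a in arrays]
        loci = arrays[0].loci
        for r in range(3):
            picks = rng.integers(0, 2, size=(1, sum(counts), len(loci), 2))[0]
            pos = 0
            sims = []
            for a, c in zip(arrays, counts):
                sim = np.take_along_axis(
                    np.broadcast_to(a.mother, (c, *a.mother.shape)),
                    picks[pos:pos + c], axis=2,
                ).copy()
                sim[:, ~(a.mother != MISSING).all(axis=1), :] = MISSING
                sims.append(sim)
                pos += c
            table = seeds_table(
                [ProgenyArray("M", loci, a.mother,
                              [f"x{k}" for k in range(c)], s)
                 for a, c, s in zip(arrays, counts, sims)]
            )
            expect = dataset_means(table_index_sets(table, ref))
            got = null.replicate_means.iloc[r].to_dict()
            for k, v in expect.items():
                assert got[k] == pytest.approx(v, abs=1e-10), k

    def test_observed_selfing_consistent_but_outcrossing_detected(self):
        selfed = self._arrays(seed=5, t=0.0)
        crossed = self._arrays(seed=5, t=0.6)
        ref = FrequencyReference.from_table(mothers_table(selfed))
        null = build_selfing_null(selfed, 300, np.random.default_rng(1), ref=ref)
        obs_cross = observed_means(crossed, ref)
        v = selfing_test(obs_cross, null)
        assert v["ir"] == "below_band" and v["pht"] == "above_band"

    def test_unknown_index_rejected(self):
        arrays = self._arrays()
        null = build_selfing_null(arrays, 10, np.random.default_rng(0))
        with pytest.raises(ValueError, match="absent"):
            selfing_test({"d2": 1.0}, null)

    def test_band_midpoint_is_consistent(self):
        arrays = self._arrays()
        null = build_selfing_null(arrays, 100, np.random.default_rng(0))
        lo, hi = null.bands["ir"]
        assert selfing_test({"ir": (lo + hi) / 2}, null)["ir"] == "consistent"


class TestProgenyPairing:
    def test_build_from_tables(self, rng):
        from conftest import make_table

        mothers = make_table(
            [("M1", "B1", "P1", "none"), ("M2", "B1", "P1", "none")],
            ["L1"],
            [[[1, 2]], [[3, 4]]],
        )
        seeds = make_table(
            [("s1", "M1", "M1", "none"), ("s2", "M2", "M2", "none"),
             ("s3", "M2", "M2", "none")],
            ["L1"],
            [[[1, 1]], [[3, 4]], [[4, 4]]],
        )
        arrays = build_progeny_arrays(mothers, seeds)
        assert [a.mother_id for a in arrays] == ["M1", "M2"]
        assert arrays[1].n_seeds == 2

    def test_locus_mismatch_rejected(self):
        from conftest import make_table

        mothers = make_table([("M1", "B1", "P1", "none")], ["L1"], [[[1, 2]]])
        seeds = make_table([("s1", "M1", "M1", "none")], ["LX"], [[[1, 1]]])
        with pytest.raises(ValueError, match="locus"):
            build_progeny_arrays(mothers, seeds)
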