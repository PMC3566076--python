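"""Downstream community procedures: OTU picking, adjusted tables, the
replicate-specificity rule, V3 excision, rarefaction with clipping and the
end-bias diagnostics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import mutate, random_seq
from oracles import best_window_oracle, greedy_cluster_oracle, rarefy_clip_oracle

from emrec._seqs import revcomp
from emrec.community import (
    OTUTable,
    build_adjusted_table,
    end_bias_profile,
    extract_v3,
    high_specificity_otus,
    pick_otus,
    rarefy_with_clipping,
)


class TestPickOtus:
    def test_identical_sequences_one_otu(self, rng):
        seq = random_seq(300, rng)
        assignment, reps = pick_otus(
            [("s1", seq, 0.5), ("s2", seq, 0.3), ("s3", seq, 0.2)]
        )
        assert set(assignment.values()) == {"s1"}
        assert reps == {"s1": seq}

    def test_identity_boundary(self, rng):
        a = random_seq(1000, rng)
        at96 = mutate(a, 40, rng)
        at98 = mutate(a, 20, rng)
        two, _ = pick_otus([("a", a, 0.6), ("b", at96, 0.4)])
        one, _ = pick_otus([("a", a, 0.6), ("b", at98, 0.4)])
        assert len(set(two.values())) == 2
        assert len(set(one.values())) == 1

    def test_processed_in_decreasing_abundance_order(self, rng):
        a = random_seq(500, rng)
        b = mutate(a, 5, rng)
        # b is more abundant -> b becomes the centroid even though a is first
        assignment, reps = pick_otus([("a", a, 0.2), ("b", b, 0.8)])
        assert set(assignment.values()) == {"b"}

    def test_matches_bruteforce_oracle(self, rng):
        pool = []
        for fam in range(6):
            base = random_seq(150, rng)
            for rep in range(5):
                pool.append(
                    (f"f{fam}r{rep}", mutate(base, int(rng.integers(0, 8)), rng),
                     float(rng.random()))
                )
        assignment, reps = pick_otus(pool, 0.97)
        order = sorted(pool, key=lambda t: (-t[2], t[0]))
        expected = greedy_cluster_oracle([(sid, s) for sid, s, _ in order], 0.97)
        assert sorted(reps) == sorted(expected)
        assert set(assignment) == {sid for sid, _s, _a in pool}

    def test_every_sequence_assigned_exactly_once(self, rng):
        pool = [(f"s{i}", random_seq(120, rng), float(rng.random()))
                for i in range(15)]
        assignment, _ = pick_otus(pool)
        assert set(assignment) == {sid for sid, _, _ in pool}


class TestAdjustedTable:
    def test_full_abundance_single_otu(self):
        table = build_adjusted_table(
            {"s1": [("a", 1.0)]}, {"s1": 1_000_000}, {"a": "a"}, {"a": "ACGT"}
        )
        assert table.counts.loc["a", "s1"] == 1_000_000

    def test_summed_abundances_within_otu(self):
        table = build_adjusted_table(
            {"s1": [("a", 0.25), ("b", 0.25)]},
            {"s1": 1_000_000},
            {"a": "a", "b": "a"},
            {"a": "ACGT"},
        )
        assert table.counts.loc["a", "s1"] == 500_000

    def test_absent_otu_is_zero(self):
        table = build_adjusted_table(
            {"s1": [("a", 1.0)], "s2": []},
            {"s1": 100, "s2": 100},
            {"a": "a"},
            {"a": "ACGT"},
        )
        assert table.counts.loc["a", "s2"] == 0

    def test_missing_assignment_raises(self):
        with pytest.raises(ValueError, match="ghost"):
            build_adjusted_table(
                {"s1": [("ghost", 1.0)]}, {"s1": 100}, {}, {}
            )

    def test_column_sum_conservation(self, rng):
        results = {
            "s1": [("a", 0.4), ("b", 0.3), ("c", 0.2)],
            "s2": [("a", 0.6), ("c", 0.1)],
        }
        totals = {"s1": 1e6, "s2": 8e5}
        assignment = {"a": "a", "b": "a", "c": "c"}
        table = build_adjusted_table(results, totals, assignment, {"a": "A", "c": "C"})
        for s, rows in results.items():
            assert table.counts[s].sum() == pytest.approx(
                totals[s] * sum(ab for _sid, ab in rows)
            )


class TestHighSpecificity:
    def _presence(self, per_group_counts):
        groups = {}
        cols = []
        for g, _count in per_group_counts.items():
            groups[g] = [f"{g}_{i}" for i in range(16)]
            cols += groups[g]
        data = {
            c: [per_group_counts[c.rsplit("_", 1)[0]] > int(c.rsplit("_", 1)[1])]
            for c in cols
        }
        return pd.DataFrame(data, index=["otu1"]), groups

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"bg": 12, "fe": 0, "so4": 0}, {"otu1"}),
            ({"bg": 11, "fe": 11, "so4": 11}, set()),
            ({"bg": 16, "fe": 0, "so4": 0}, {"otu1"}),
        ],
    )
    def test_at_least_12_of_16_rule(self, counts, expected):
        presence, groups = self._presence(counts)
        assert high_specificity_otus(presence, groups) == expected

    def test_wrong_group_size_raises(self):
        presence = pd.DataFrame({"a_0": [True]}, index=["otu1"])
        with pytest.raises(ValueError, match="16"):
            high_specificity_otus(presence, {"a": ["a_0"]})


class TestExtractV3:
    FWD = "CCTACGGGAGGCAGCAG"
    REV = "ATTACCGCGGCTGCTGG"

    def test_perfect_sites_return_region_with_primers(self, rng):
        core = random_seq(130, rng)
        seq = random_seq(300, rng) + self.FWD + core + revcomp(self.REV) \
            + random_seq(400, rng)
        region = extract_v3(seq)
        assert region == self.FWD + core + revcomp(self.REV)
        assert len(region) == 130 + 34

    def test_out_of_bounds_region_rejected(self, rng):
        short_core = random_seq(56, rng)  # region = 90 < 100 -> rejected
        seq = random_seq(200, rng) + self.FWD + short_core + revcomp(self.REV) \
            + random_seq(200, rng)
        assert extract_v3(seq) is None

    def test_windows_match_exhaustive_hamming_scan(self, rng):
        for _ in range(10):
            core = random_seq(int(rng.integers(100, 180)), rng)
            seq = (random_seq(400, rng)
                   + mutate(self.FWD, int(rng.integers(0, 3)), rng)
                   + core
                   + mutate(revcomp(self.REV), int(rng.integers(0, 3)), rng)
                   + random_seq(400, rng))
            f = best_window_oracle(seq, self.FWD)
            r_rel = best_window_oracle(seq[f + 17:], revcomp(self.REV))
            expected = seq[f : f + 17 + r_rel + 17]
            got = extract_v3(seq)
            if 100 <= len(expected) <= 225:
                assert got == expected
            else:
                assert got is None

    def test_mismatched_sites_still_excised(self, rng):
        # Any number of primer mismatches allowed.
        core = random_seq(130, rng)
        seq = (random_seq(300, rng) + mutate(self.FWD, 4, rng) + core
               + mutate(revcomp(self.REV), 4, rng) + random_seq(300, rng))
        assert extract_v3(seq) is not None


class TestRarefy:
    def _table(self, counts, sample="s1"):
        df = pd.DataFrame({sample: counts},
                          index=[f"otu{i}" for i in range(len(counts))])
        return df

    def test_full_depth_draw_applies_only_clipping(self):
        table = self._table([1000, 21, 20])
        reps = rarefy_with_clipping(table, depth=1041, replicates=3, seed=1)
        for rep in reps:
            assert rep["s1"].tolist() == [1000, 21, 0]

    def test_zero_clip_is_noop(self):
        table = self._table([50, 40, 30])
        reps_clip = rarefy_with_clipping(table, depth=120, clip=0, seed=2)
        reps_raw = rarefy_with_clipping(table, depth=120, clip=0, seed=2)
        for a, b in zip(reps_clip, reps_raw):
            assert (a.values == b.values).all()
            assert a["s1"].sum() == 120

    def test_excess_depth_names_sample(self):
        table = self._table([10, 10], sample="mysample")
        with pytest.raises(ValueError, match="mysample"):
            rarefy_with_clipping(table, depth=100)

    def test_observed_otus_match_monte_carlo_oracle(self):
        # 100-OTU geometric community rarefied to 10^4; mean observed OTUs
        # after clipping vs an independent Monte-Carlo estimate.
        raw = 200_000 * 0.93 ** np.arange(100)
        table = self._table(raw)
        ints = np.array([int(x) for x in np.floor(raw)])
        reps = rarefy_with_clipping(table, depth=10_000, replicates=400, seed=3)
        ours = np.mean([(rep["s1"] > 0).sum() for rep in reps])
        # the rounded table differs from floor() by at most the remainders
        oracle = rarefy_clip_oracle(ints, 10_000, 20, 400,
                                    np.random.default_rng(999))
        assert ours == pytest.approx(oracle, rel=0.02)

    def test_largest_remainder_preserves_column_totals(self):
        table = self._table([10.4, 10.4, 10.2])
        reps = rarefy_with_clipping(table, depth=31, clip=0, seed=4)
        assert reps[0]["s1"].sum() == 31

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 30))
    def test_clipping_idempotent_and_monotone(self, seed, clip):
        r = np.random.default_rng(seed)
        counts = r.integers(0, 200, size=12)
        once = counts.copy()
        once[once <= clip] = 0
        twice = once.copy()
        twice[twice <= clip] = 0
        assert (once == twice).all()
        higher = counts.copy()
        higher[higher <= clip + 5] = 0
        assert (higher <= once).all()


class TestEndBiasProfile:
    def test_all_fragments_at_position_zero(self):
        frags = pd.DataFrame(
            {"ref_id": ["r"] * 50, "start": [0] * 50, "end": [275] * 50}
        )
        prof = end_bias_profile(frags, {"r": 1464})
        assert prof.distance_hist.iloc[0] == 1.0

    def test_uniform_library_has_no_enrichment(self, rng):
        starts = rng.integers(0, 1464 - 275 + 1, size=100_000)
        frags = pd.DataFrame(
            {"ref_id": "r", "start": starts, "end": starts + 275}
        )
        prof = end_bias_profile(frags, {"r": 1464})
        assert 0.8 <= prof.enrichment_factor <= 1.25

    def test_out_of_bounds_fragment_rejected(self):
        frags = pd.DataFrame({"ref_id": ["r"], "start": [0], "end": [2000]})
        with pytest.raises(ValueError):
            end_bias_profile(frags, {"r": 1464})

    def test_coverage_curve_tracks_read_placement(self, rng):
        # terminal-only fragments: coverage concentrated in the outer bins
        n = 2000
        starts = np.where(rng.random(n) < 0.5, 0, 1464 - 275)
        frags = pd.DataFrame(
            {"ref_id": "r", "start": starts, "end": starts + 275}
        )
        prof = end_bias_profile(frags, {"r": 1464}, read_len=93, n_bins=16)
        assert prof.coverage_curve[0] > prof.coverage_curve[8]
        assert prof.coverage_curve[-1] > prof.coverage_curve[8]


class TestOTUTableInvariants:
    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            OTUTable(pd.DataFrame({"s1": [-1.0]}, index=["a"]), {}, {"s1": 10})
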