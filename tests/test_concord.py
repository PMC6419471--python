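"""Four-way concordance, consensus MOTUs and adjusted Wallace."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motu_concord.concord import (
    adjusted_wallace,
    classify_concordance,
    concordance_summary,
    consensus_motus,
    wallace_matrix,
)
from motu_concord.datasets import Partition


def P(assignment, name=""):
    return Partition(dict(assignment), method_name=name)


def brute_force_classify(ref: Partition, motus: Partition) -> dict[str, str]:
    """Independent oracle: enumerate the species x MOTU incidence table."""
    out = {}
    species = set(ref.assignment.values())
    for sp in species:
        members = {s for s, v in ref.assignment.items() if v == sp}
        its_motus = {motus.assignment[s] for s in members}
        impure = False
        for m in its_motus:
            motu_members = {s for s, v in motus.assignment.items() if v == m}
            if motu_members - members:
                impure = True
        if len(its_motus) == 1:
            out[sp] = "MERGE" if impure else "MATCH"
        else:
            out[sp] = "MIXTURE" if impure else "SPLIT"
    return out


def brute_force_pair_counts(A: Partition, B: Partition) -> tuple[int, int]:
    """Exhaustive pair enumeration for Wallace's a and b."""
    a = b = 0
    for x, y in combinations(sorted(A.assignment), 2):
        if A.assignment[x] == A.assignment[y]:
            if B.assignment[x] == B.assignment[y]:
                a += 1
            else:
                b += 1
    return a, b


def random_partition_pair(rng, n):
    ids = [f"s{i}" for i in range(n)]
    ka = int(rng.integers(1, max(2, n // 2)))
    kb = int(rng.integers(1, max(2, n // 2)))
    A = P({i: f"a{rng.integers(ka)}" for i in ids})
    B = P({i: f"b{rng.integers(kb)}" for i in ids})
    return A, B


class TestClassifyConcordance:
    def test_match_definitional(self):
        ref = P({"1": "S", "2": "S"})
        motus = P({"1": "m", "2": "m"})
        assert classify_concordance(ref, motus).category == {"S": "MATCH"}

    def test_split_definitional(self):
        ref = P({"1": "S", "2": "S", "3": "S"})
        motus = P({"1": "m1", "2": "m2", "3": "m2"})
        assert classify_concordance(ref, motus).category == {"S": "SPLIT"}

    def test_merge_and_mixture_like_shared_bin_triad(self):
        # species D spans 4 MOTUs, one shared with J and L -> D MIXTURE,
        # J and L MERGE (each in one shared MOTU)
        ref = {}
        motus = {}
        for i in range(4):
            ref[f"d{i}"] = "Ruspolia dubia"
            motus[f"d{i}"] = f"m{i}"  # m0..m3; m0 will be shared
        for i in range(2):
            ref[f"j{i}"] = "Ruspolia jezoensis"
            motus[f"j{i}"] = "m0"
        for i in range(2):
            ref[f"l{i}"] = "Ruspolia liangshanensis"
            motus[f"l{i}"] = "m0"
        rep = classify_concordance(P(ref), P(motus))
        assert rep.category["Ruspolia dubia"] == "MIXTURE"
        assert rep.category["Ruspolia jezoensis"] == "MERGE"
        assert rep.category["Ruspolia liangshanensis"] == "MERGE"

    def test_singleton_can_only_match_or_merge(self):
        rep = classify_concordance(
            P({"1": "A", "2": "B", "3": "B"}), P({"1": "m1", "2": "m1", "3": "m2"})
        )
        assert rep.category["A"] == "MERGE"
        assert "A" in rep.singleton_species

    def test_universe_mismatch_error(self):
        with pytest.raises(ValueError, match="universes differ"):
            classify_concordance(P({"1": "A"}), P({"2": "m"}))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_brute_force_incidence_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        A, B = random_partition_pair(rng, n)
        assert classify_concordance(A, B).category == brute_force_classify(A, B)


class TestConcordanceSummary:
    def abstract_structure_report(self):
        """131 species: 33 SPLIT, 14 MERGE, rest MATCH; 22 singletons."""
        ref = {}
        motus = {}
        sp_idx = 0
        # 22 singleton MATCH species
        for _ in range(22):
            sp_idx += 1
            ref[f"x{sp_idx}"] = f"S{sp_idx}"
            motus[f"x{sp_idx}"] = f"m{sp_idx}"
        # 62 multi-specimen MATCH species
        for _ in range(62):
            sp_idx += 1
            for k in range(2):
                ref[f"x{sp_idx}_{k}"] = f"S{sp_idx}"
                motus[f"x{sp_idx}_{k}"] = f"m{sp_idx}"
        # 14 MERGE species (7 pairs sharing one MOTU)
        for pair in range(7):
            shared = f"shared{pair}"
            for _ in range(2):
                sp_idx += 1
                for k in range(2):
                    ref[f"x{sp_idx}_{k}"] = f"S{sp_idx}"
                    motus[f"x{sp_idx}_{k}"] = shared
        # 33 SPLIT species (two pure MOTUs each)
        for _ in range(33):
            sp_idx += 1
            for k in range(2):
                ref[f"x{sp_idx}_{k}"] = f"S{sp_idx}"
                motus[f"x{sp_idx}_{k}"] = f"m{sp_idx}_{k}"
        assert sp_idx == 131
        return classify_concordance(P(ref), P(motus))

    def test_printed_percentages_from_integer_counts(self):
        rep = self.abstract_structure_report()
        table = concordance_summary(rep).set_index(["denominator", "category"])
        assert table.loc[("all_species", "SPLIT"), "percent"] == 25.19  # 33/131
        assert table.loc[("multi_specimen", "SPLIT"), "percent"] == 30.28  # 33/109
        assert table.loc[("all_species", "MERGE"), "percent"] == 10.69  # 14/131
        assert table.loc[("all_species", "SPLIT"), "count"] == 33
        assert table.loc[("multi_specimen", "SPLIT"), "denom"] == 109

    def test_counts_partition_the_species_set(self):
        rep = self.abstract_structure_report()
        assert sum(rep.counts().values()) == rep.n_species == 131
        assert len(rep.singleton_species) == 22

    def test_all_match_is_hundred_percent(self):
        rep = classify_concordance(
            P({"1": "A", "2": "A", "3": "B"}), P({"1": "m1", "2": "m1", "3": "m2"})
        )
        table = concordance_summary(rep).set_index(["denominator", "category"])
        assert table.loc[("all_species", "MATCH"), "percent"] == 100.0


class TestConsensus:
    def seven_partitions(self, core):
        """m=7 partitions over {a..e}; `core` controls {a,b} support."""
        parts = []
        for i in range(7):
            if i < core:
                parts.append(P({"a": "x", "b": "x", "c": "y", "d": "y", "e": "z"}, f"p{i}"))
            else:
                parts.append(P({"a": f"u{i}", "b": f"v{i}", "c": "y", "d": "y", "e": "z"}, f"p{i}"))
        return parts

    def test_set_kept_at_support_four_of_seven(self):
        res = consensus_motus(self.seven_partitions(4), k=4)
        assert frozenset({"a", "b"}) in res.motus
        idx = res.motus.index(frozenset({"a", "b"}))
        assert res.support[idx] == 4

    def test_set_dropped_below_k(self):
        # {a,b} supported 3 of 7 times; elsewhere a and b sit in
        # ever-different sets, so no set containing them reaches k=4
        rotations = [
            {"a": "1", "b": "2", "c": "2", "d": "3", "e": "3"},
            {"a": "1", "b": "1", "c": "1", "d": "2", "e": "2"},
            {"a": "1", "b": "2", "c": "1", "d": "2", "e": "1"},
            {"a": "1", "b": "2", "c": "2", "d": "1", "e": "2"},
        ]
        parts = [P({"a": "x", "b": "x", "c": "y", "d": "y", "e": "z"}, f"p{i}") for i in range(3)]
        parts += [P(r, f"q{i}") for i, r in enumerate(rotations)]
        res = consensus_motus(parts, k=4)
        assert frozenset({"a", "b"}) not in res.motus
        assert "a" in res.unassigned and "b" in res.unassigned

    def test_overlap_resolved_by_support_then_size(self):
        parts = [
            P({"a": "1", "b": "1", "c": "2"}, "p1"),
            P({"a": "1", "b": "1", "c": "2"}, "p2"),
            P({"a": "1", "b": "1", "c": "2"}, "p3"),
            P({"a": "1", "b": "1", "c": "2"}, "p4"),
            P({"a": "1", "b": "1", "c": "2"}, "p5"),
            P({"a": "1", "b": "1", "c": "1"}, "p6"),
            P({"a": "1", "b": "1", "c": "1"}, "p7"),
        ]
        # {a,b} support 5, {a,b,c} support 2; with k=2 keep {a,b}, then {c}
        res = consensus_motus(parts, k=2)
        assert frozenset({"a", "b"}) in res.motus
        assert frozenset({"a", "b", "c"}) not in res.motus
        assert frozenset({"c"}) in res.motus  # {c} has support 5 on its own

    def test_identical_partitions_return_that_partition(self):
        p = P({"a": "1", "b": "1", "c": "2"}, "p")
        for k in (1, 2, 3):
            res = consensus_motus([p, p, p], k=k)
            assert set(res.motus) == p.sets()
            assert res.unassigned == []

    def test_k_equals_m_keeps_only_unanimous_sets(self):
        parts = self.seven_partitions(7)
        res = consensus_motus(parts, k=7)
        assert set(res.motus) == {
            frozenset({"a", "b"}),
            frozenset({"c", "d"}),
            frozenset({"e"}),
        }

    def test_k_above_m_error(self):
        with pytest.raises(ValueError, match="k"):
            consensus_motus([P({"a": "1"})], k=2)

    def test_consensus_sets_are_disjoint(self):
        rng = np.random.default_rng(8)
        parts = [random_partition_pair(rng, 15)[0] for _ in range(5)]
        res = consensus_motus(parts, k=2)
        seen = set()
        for group in res.motus:
            assert not (group & seen)
            seen |= group


class TestAdjustedWallace:
    def test_identical_partitions_give_aw_one(self):
        A = P({"1": "x", "2": "x", "3": "y", "4": "y"})
        res = adjusted_wallace(A, A, n_boot=0)
        assert res.W == 1.0
        assert res.sid_B == pytest.approx(2.0 / 3.0)
        assert res.AW == pytest.approx(1.0)
        assert (res.a, res.b) == (2, 0)

    def test_single_cluster_reference_is_undefined(self):
        A = P({"1": "x", "2": "x", "3": "y", "4": "y"})
        B = P({"1": "m", "2": "m", "3": "m", "4": "m"})
        res = adjusted_wallace(A, B, n_boot=0)
        assert res.W == 1.0 and res.sid_B == 0.0
        assert math.isnan(res.AW) and res.reason_missing

    def test_independent_partitions_have_near_zero_aw(self):
        rng = np.random.default_rng(123)
        ids = [f"s{i}" for i in range(200)]
        A = P({i: f"a{rng.integers(10)}" for i in ids})
        B = P({i: f"b{rng.integers(10)}" for i in ids})
        res = adjusted_wallace(A, B, exclude_singletons=False, n_boot=0)
        assert abs(res.AW) < 0.1

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_pair_counts_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        A, B = random_partition_pair(rng, n)
        res = adjusted_wallace(A, B, exclude_singletons=False, n_boot=0)
        assert (res.a, res.b) == brute_force_pair_counts(A, B)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_refining_b_never_increases_w(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 25))
        A, B = random_partition_pair(rng, n)
        # split one multi-member B cluster in two
        clusters = [c for c in B.sets() if len(c) > 1]
        if not clusters:
            return
        target = sorted(sorted(c) for c in clusters)[0]
        refined = dict(B.assignment)
        for s in target[: len(target) // 2]:
            refined[s] = "split_off"
        res_before = adjusted_wallace(A, B, exclude_singletons=False, n_boot=0)
        res_after = adjusted_wallace(A, P(refined), exclude_singletons=False, n_boot=0)
        if not (math.isnan(res_before.W) or math.isnan(res_after.W)):
            assert res_after.W <= res_before.W + 1e-12

    def test_singleton_exclusion_drops_lonely_specimens(self):
        A = P({"1": "x", "2": "x", "3": "lonely"})
        B = P({"1": "m", "2": "m", "3": "m"})
        res = adjusted_wallace(A, B, exclude_singletons=True, n_boot=0)
        assert res.n == 2

    def test_bootstrap_ci_is_seeded_and_brackets_estimate(self):
        rng = np.random.default_rng(5)
        ids = [f"s{i}" for i in range(40)]
        A = P({i: f"a{rng.integers(5)}" for i in ids})
        B = P({i: A.assignment[i] if rng.random() < 0.8 else f"b{rng.integers(5)}" for i in ids})
        r1 = adjusted_wallace(A, B, n_boot=200, seed=7)
        r2 = adjusted_wallace(A, B, n_boot=200, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.AW <= r1.ci_high

    def test_matrix_is_directional(self):
        A = P({"1": "x", "2": "x", "3": "y", "4": "y"})
        B = P({"1": "m", "2": "m", "3": "n", "4": "o"})
        wm = wallace_matrix({"A": A, "B": B}, n_boot=0)
        assert wm.loc["A", "B"] != wm.loc["B", "A"]
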