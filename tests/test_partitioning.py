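import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ontcorrect.anchoring import (
    AnchorPair,
    Params,
    PositionalMinimizer,
    build_pair_index,
)
from ontcorrect.partitioning import (
    SupportedInterval,
    compute_support,
    is_similar,
    solve_interval_scheduling,
)
from ontcorrect.seqio import ClusterInput

from conftest import make_read, random_seq


def textbook_edit_distance(a, b):
    """Quadratic Levenshtein DP (oracle for the edlib-backed distances)."""
    dp = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        prev, dp[0] = dp[0], i
        for j, cb in enumerate(b, 1):
            prev, dp[j] = dp[j], min(
                dp[j] + 1, dp[j - 1] + 1, prev + (ca != cb)
            )
    return dp[len(b)]


class TestIsSimilar:
    def test_identical(self):
        assert is_similar("ACGT" * 10, "ACGT" * 10, 1e-6, 1e-6)

    def test_strict_inequality_boundary(self, rng):
        # |s| = 100, eps_s = eps_s' = 0.07 -> threshold 14: ed 14 fails, 13 passes
        s = "A" * 50 + "C" * 50
        s14 = "G" * 14 + "A" * 36 + "C" * 50
        s13 = "G" * 13 + "A" * 37 + "C" * 50
        assert textbook_edit_distance(s, s14) == 14
        assert textbook_edit_distance(s, s13) == 13
        assert not is_similar(s, s14, 0.07, 0.07)
        assert is_similar(s, s13, 0.07, 0.07)

    def test_empty_s_rejected(self):
        with pytest.raises(ValueError):
            is_similar("", "A", 0.1, 0.1)


class TestComputeSupport:
    def params(self):
        return Params(k=5, x_max=40)

    def first_pair(self, read, index):
        for key, occs in sorted(index.occurrences.items()):
            for rid, p, q in occs:
                if rid == read.read_id:
                    return AnchorPair(
                        PositionalMinimizer(key[0], p),
                        PositionalMinimizer(key[1], q),
                        rid,
                    )
        raise AssertionError("no pair found")

    def test_three_identical_reads(self, rng):
        seq = random_seq(rng, 120)
        cl = ClusterInput("c", [make_read(f"r{i}", seq) for i in range(3)])
        idx = build_pair_index(cl, self.params())
        pair = self.first_pair(cl.reads[0], idx)
        iv = compute_support(cl.reads[0], pair, idx, cl)
        assert iv.support == 3
        assert iv.weight == 3 * (iv.end - iv.begin)
        assert iv.begin == pair.left.pos + 5 and iv.end == pair.right.pos

    def test_single_read_supports_itself(self, rng):
        seq = random_seq(rng, 120)
        cl = ClusterInput("c", [make_read("r0", seq)])
        idx = build_pair_index(cl, self.params())
        pair = self.first_pair(cl.reads[0], idx)
        assert compute_support(cl.reads[0], pair, idx, cl).support == 1

    def test_smallest_ed_occurrence_chosen_once(self, rng):
        # partner carries the anchor-pair span twice: an exact copy and a
        # mutated copy; only the exact one may be counted, and only once
        core = random_seq(rng, 30)
        k = 5
        left, right = core[:k], core[-k:]
        mutated = core[:12] + "".join(
            {"A": "C", "C": "G", "G": "T", "T": "A"}[c] for c in core[12:18]
        ) + core[18:]
        spacer = random_seq(rng, 25)
        target = make_read("t", random_seq(rng, 10) + core + random_seq(rng, 10))
        partner = make_read("p", mutated + spacer + core)
        cl = ClusterInput("c", [target, partner])
        idx = build_pair_index(cl, Params(k=k, x_min=2 * k, x_max=70))
        p = target.seq.find(left)
        q = target.seq.find(right, p + k)
        pair = AnchorPair(
            PositionalMinimizer(left, p), PositionalMinimizer(right, q), "t"
        )
        assert (left, right) in idx and len(
            [o for o in idx[(left, right)] if o[0] == "p"]
        ) == 2
        iv = compute_support(target, pair, idx, cl)
        assert iv.support == 2
        # the chosen partner span is the exact copy (smallest edit distance)
        (rid, a, b) = iv.segments[1]
        assert rid == "p" and partner.seq[a:b] == core

    def test_pair_not_on_read_rejected(self, rng):
        seq = random_seq(rng, 120)
        cl = ClusterInput("c", [make_read("r0", seq)])
        idx = build_pair_index(cl, self.params())
        fake = AnchorPair(
            PositionalMinimizer(seq[:5], 0), PositionalMinimizer(seq[50:55], 99), "r0"
        )
        with pytest.raises(ValueError):
            compute_support(cl.reads[0], fake, idx, cl)

    def test_support_monotone_under_read_removal(self, rng):
        seq = random_seq(rng, 150)
        reads = [make_read(f"r{i}", seq) for i in range(4)]
        cl_full = ClusterInput("c", reads)
        idx_full = build_pair_index(cl_full, self.params())
        pair = self.first_pair(reads[0], idx_full)
        full = compute_support(reads[0], pair, idx_full, cl_full).support
        cl_small = ClusterInput("c", reads[:-1])
        idx_small = build_pair_index(cl_small, self.params())
        small = compute_support(reads[0], pair, idx_small, cl_small).support
        assert small <= full


def brute_force_optimum(intervals):
    best = 0.0
    n = len(intervals)
    for mask in itertools.product([0, 1], repeat=n):
        chosen = [iv for iv, m in zip(intervals, mask) if m]
        ok = all(
            a.end <= b.begin or b.end <= a.begin
            for i, a in enumerate(chosen)
            for b in chosen[i + 1 :]
        )
        if ok:
            best = max(best, sum(iv.weight for iv in chosen))
    return best


def iv(begin, end, weight):
    return SupportedInterval("r", begin, end, support=1, weight=weight)


class TestScheduling:
    def test_disjoint_intervals_all_selected(self):
        chosen = solve_interval_scheduling([iv(0, 10, 5), iv(12, 20, 1)])
        assert [(c.begin, c.end) for c in chosen] == [(0, 10), (12, 20)]

    def test_two_small_beat_one_big(self):
        chosen = solve_interval_scheduling(
            [iv(0, 10, 5), iv(5, 15, 5), iv(0, 15, 9)]
        )
        assert sum(c.weight for c in chosen) == 9  # [0,10)+[5,15) overlap!
        # abutting is allowed: [0,5) and [5,15) would not conflict
        chosen2 = solve_interval_scheduling(
            [iv(0, 5, 5), iv(5, 15, 5), iv(0, 15, 9)]
        )
        assert sum(c.weight for c in chosen2) == 10

    def test_empty(self):
        assert solve_interval_scheduling([]) == []

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_exhaustive_enumeration(self, data):
        n = data.draw(st.integers(1, 12))
        ivs = []
        for _ in range(n):
            b = data.draw(st.integers(0, 40))
            e = b + data.draw(st.integers(1, 15))
            w = data.draw(st.integers(1, 20))
            ivs.append(iv(b, e, float(w)))
        chosen = solve_interval_scheduling(ivs)
        # solution is feasible ...
        for a, b in zip(chosen, chosen[1:]):
            assert a.end <= b.begin
        # ... and optimal
        assert sum(c.weight for c in chosen) == pytest.approx(
            brute_force_optimum(ivs)
        )
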