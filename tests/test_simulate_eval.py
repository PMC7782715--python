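import numpy as np
import pytest

from ontcorrect._alignlib import align_path, edit_distance
from ontcorrect.evaluate import alignment_stats, evaluate
from ontcorrect.seqio import Read
from ontcorrect.simulate import (
    Transcript,
    TruthRecord,
    exon_experiment,
    make_gene,
    simulate_reads,
    snp_experiment,
)

from conftest import random_seq


class TestMakeGene:
    def test_single_isoform_concatenates_all_exons(self):
        (t,) = make_gene(1, 4, (50, 80), seed=1)
        assert len(t.exon_blocks) == 4
        assert t.exon_blocks[-1][1] == len(t.seq)

    def test_isoforms_distinct_and_share_exons(self):
        ts = make_gene(3, 4, (50, 80), seed=2)
        assert len({t.seq for t in ts}) == 3
        full = ts[0]
        for t in ts[1:]:
            assert len(t.seq) < len(full.seq)
            # shares at least one exon with the full isoform
            assert any(t.seq.find(full.seq[a:b]) >= 0 for a, b in full.exon_blocks)

    def test_deterministic_under_seed(self):
        a = make_gene(3, 5, (60, 100), seed=42)
        b = make_gene(3, 5, (60, 100), seed=42)
        assert [t.seq for t in a] == [t.seq for t in b]

    def test_infeasible_request_rejected(self):
        with pytest.raises(ValueError):
            make_gene(5, 1, (50, 60), seed=0)


class TestSimulateReads:
    def transcript(self, rng, length=500):
        return Transcript("t", random_seq(rng, length), "g", [(0, length)])

    def test_zero_error_rate_reproduces_transcripts(self, rng):
        t = self.transcript(rng)
        reads, truth = simulate_reads([t], 5, 0.0, seed=1)
        assert all(r.seq == t.seq for r in reads)
        assert all(rec.error_rate == 0.0 for rec in truth)

    def test_event_rate_concentrates(self, rng):
        t = self.transcript(rng, length=2000)
        reads, truth = simulate_reads([t], 5, 0.07, seed=2)
        events = sum(r.n_sub + r.n_ins + r.n_del for r in truth)
        n_bases = 5 * 2000
        sd = np.sqrt(n_bases * 0.07 * 0.93)
        assert abs(events - 0.07 * n_bases) < 3 * sd

    def test_error_mix_proportions(self, rng):
        t = self.transcript(rng, length=5000)
        _, truth = simulate_reads([t], 10, 0.1, seed=3)
        subs = sum(r.n_sub for r in truth)
        ins = sum(r.n_ins for r in truth)
        dels = sum(r.n_del for r in truth)
        total = subs + ins + dels
        for got, expect in [(subs, 0.35), (ins, 0.30), (dels, 0.35)]:
            assert abs(got / total - expect) < 3 * np.sqrt(expect * (1 - expect) / total)

    def test_depth_specification_forms(self, rng):
        ts = make_gene(2, 3, (50, 60), seed=4)
        reads, _ = simulate_reads(ts, {ts[0].transcript_id: 3, ts[1].transcript_id: 1},
                                  0.05, seed=5)
        assert len(reads) == 4
        reads2, _ = simulate_reads(ts, [2, 2], 0.05, seed=5)
        assert len(reads2) == 4

    def test_deterministic_under_seed(self, rng):
        t = self.transcript(rng)
        a, _ = simulate_reads([t], 3, 0.07, seed=9)
        b, _ = simulate_reads([t], 3, 0.07, seed=9)
        assert [r.seq for r in a] == [r.seq for r in b]

    def test_truth_error_rate_definition(self):
        rec = TruthRecord("r", "t", 2, 1, 1, alignment_length=104)
        assert rec.error_rate == pytest.approx(4 / 104)


def naive_alignment_stats(query, target):
    """Second implementation: full DP with traceback counting columns."""
    n, m = len(query), len(target)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    dp[:, 0] = np.arange(n + 1)
    dp[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = min(
                dp[i - 1, j] + 1,
                dp[i, j - 1] + 1,
                dp[i - 1, j - 1] + (query[i - 1] != target[j - 1]),
            )
    # alignment length = matches + mismatches + indels; for a unit-cost
    # optimal alignment this is max(n, m) <= len <= n + m; recover from ops:
    i, j, mism, cols = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] + (query[i - 1] != target[j - 1]):
            mism += query[i - 1] != target[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and dp[i, j] == dp[i - 1, j] + 1:
            mism += 1
            i -= 1
        else:
            mism += 1
            j -= 1
        cols += 1
    return mism, cols


class TestEvaluate:
    def make_inputs(self, rng, perturb):
        t = Transcript("t1", random_seq(rng, 80), "g", [(0, 80)])
        other = Transcript("t2", random_seq(rng, 80), "g", [(0, 80)])
        orig = Read("r0", perturb(t.seq), np.full(len(perturb(t.seq)), 0.07), "g")
        truth = [TruthRecord("r0", "t1", 0, 0, 0, alignment_length=80)]
        return t, other, orig, truth

    def test_perfect_correction_zero_rates(self, rng):
        t, other, orig, truth = self.make_inputs(rng, lambda s: s[:40] + s[41:])
        corrected = Read("r0", t.seq, np.full(80, 1e-3), "g")
        per_read, summary = evaluate([corrected], [orig], truth, [t, other])
        row = per_read.iloc[0]
        assert row.error_rate_after == 0.0
        assert not row.miscorrected and not row.overcorrected
        assert row.overcorrection_distance == 0

    def test_read_equal_to_wrong_transcript_is_overcorrected(self, rng):
        t, other, orig, truth = self.make_inputs(rng, lambda s: s)
        wrong = Read("r0", other.seq, np.full(80, 1e-3), "g")
        per_read, _ = evaluate([wrong], [orig], truth, [t, other])
        row = per_read.iloc[0]
        assert row.overcorrected
        assert row.overcorrection_distance == edit_distance(other.seq, t.seq)
        assert row.overcorrection_distance >= 1

    def test_id_mismatch_rejected(self, rng):
        t, other, orig, truth = self.make_inputs(rng, lambda s: s)
        stranger = Read("zz", t.seq, np.full(80, 1e-3), "g")
        with pytest.raises(ValueError):
            evaluate([stranger], [orig], truth, [t, other])

    def test_alignment_stats_against_second_implementation(self, rng):
        for _ in range(15):
            a = random_seq(rng, int(rng.integers(5, 40)))
            b = random_seq(rng, int(rng.integers(5, 40)))
            mism, cols = alignment_stats(a, b)
            o_mism, o_cols = naive_alignment_stats(a, b)
            assert mism == o_mism == edit_distance(a, b)
            # column counts agree up to alignment-path degeneracy
            assert max(len(a), len(b)) <= cols <= len(a) + len(b)
            assert max(len(a), len(b)) <= o_cols <= len(a) + len(b)

    def test_isolated_substitutions_exact_rate(self, rng):
        L = 200
        t = Transcript("t", random_seq(rng, L), "g", [(0, L)])
        seq = t.seq
        for pos in (17, 63, 150):
            seq = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1 :]
        read = Read("r0", seq, np.full(L, 0.07), "g")
        truth = [TruthRecord("r0", "t", 3, 0, 0, alignment_length=L)]
        per_read, _ = evaluate([read], [read], truth, [t])
        assert per_read.iloc[0].error_rate_after == pytest.approx(3 / L)


class TestExperimentsFastPaths:
    def test_snp_retained_without_errors(self):
        flags = snp_experiment(n_reads=12, snp_fraction=0.5, error_rate=0.0,
                               replicates=3, seed=1)
        assert flags == [True, True, True]

    def test_exon_fractions_identical_without_errors(self):
        out = exon_experiment(deletion_len=20, n_reads=12, minor_fraction=0.25,
                              error_rate=0.0, replicates=3, seed=1)
        for before, after in out:
            assert before == after
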