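"""Synthetic transcripts and reads with controlled depth, errors, SNPs and
exon deletions.

The read model is i.i.d. per base: with probability ``error_rate`` an event
occurs at a base, partitioned among a substitution (to a uniformly chosen
different base), a single-base insertion after the position, or a deletion.
The default event mix (0.35 substitution, 0.30 insertion, 0.35 deletion)
normalizes the measured ONT cDNA profile of 2.5% / 2.2% / 3.0% per-base
substitution/insertion/deletion rates.  Quality strings encode the nominal
error rate.  True event counts are logged per read so error rates can be
measured without alignment ambiguity.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, so every experiment is reproducible and replicates are independent.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from ._alignlib import align_path, edit_distance
from .anchoring import Params
from .corrector import correct_cluster
from .seqio import ClusterInput, Read

__all__ = [
    "Transcript",
    "TruthRecord",
    "make_gene",
    "simulate_reads",
    "snp_experiment",
    "exon_experiment",
    "depth_experiment",
    "DEFAULT_ERROR_MIX",
]

_BASES = "ACGT"

#: (substitution, insertion, deletion) fractions of error events.
DEFAULT_ERROR_MIX = (0.35, 0.30, 0.35)


@dataclass
class Transcript:
    transcript_id: str
    seq: str
    gene_id: str
    exon_blocks: list[tuple[int, int]]

    def __post_init__(self) -> None:
        pos = 0
        for start, end in self.exon_blocks:
            if start != pos or end <= start:
                raise ValueError(
                    f"{self.transcript_id}: exon blocks must tile the sequence"
                )
            pos = end
        if pos != len(self.seq):
            raise ValueError(f"{self.transcript_id}: exon blocks must tile the sequence")


@dataclass
class TruthRecord:
    read_id: str
    transcript_id: str
    n_sub: int
    n_ins: int
    n_del: int
    #: matches + events at generation time (= transcript length + insertions)
    alignment_length: int = 0

    @property
    def error_rate(self) -> float:
        return (self.n_sub + self.n_ins + self.n_del) / self.alignment_length


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[b] for b in rng.integers(0, 4, size=length))


def make_gene(
    n_isoforms: int,
    n_exons: int,
    exon_len_range: tuple[int, int],
    seed: int | np.random.SeedSequence,
    gene_id: str = "gene",
) -> list[Transcript]:
    """A gene as a set of exon-sharing isoforms.

    Exon sequences are uniform over ACGT.  The first isoform contains every
    exon; each further isoform drops a random subset of up to half the exons
    (at least one), so isoforms are distinct ordered exon subsets, any two
    share at least one exon, and siblings differ by realistic amounts of
    sequence rather than a single cassette exon.  Deterministic for a given
    seed.
    """
    if n_isoforms < 1:
        raise ValueError("n_isoforms must be >= 1")
    if n_isoforms > n_exons + 1 or (n_isoforms > 1 and n_exons < 2):
        raise ValueError(
            f"cannot build {n_isoforms} distinct exon-sharing isoforms "
            f"from {n_exons} exons"
        )
    rng = np.random.default_rng(seed)
    lo, hi = exon_len_range
    exons = [_random_seq(rng, int(rng.integers(lo, hi + 1))) for _ in range(n_exons)]
    keeps: list[frozenset[int]] = [frozenset(range(n_exons))]
    max_drop = max(1, n_exons // 2)
    for _ in range(1, n_isoforms):
        for _try in range(1000):
            size = int(rng.integers(1, max_drop + 1))
            drop = set(rng.choice(n_exons, size=size, replace=False).tolist())
            keep = frozenset(range(n_exons)) - drop
            if keep and keep not in keeps and all(keep & other for other in keeps):
                keeps.append(keep)
                break
        else:
            raise ValueError(
                f"cannot build {n_isoforms} distinct exon-sharing isoforms "
                f"from {n_exons} exons"
            )
    transcripts = []
    for iso, keep_set in enumerate(keeps):
        seq_parts = [exons[e] for e in sorted(keep_set)]
        blocks = []
        pos = 0
        for part in seq_parts:
            blocks.append((pos, pos + len(part)))
            pos += len(part)
        transcripts.append(
            Transcript(f"{gene_id}_iso{iso}", "".join(seq_parts), gene_id, blocks)
        )
    return transcripts


def _mutate(
    rng: np.random.Generator,
    seq: str,
    error_rate: float,
    error_mix: tuple[float, float, float],
) -> tuple[str, int, int, int]:
    """Apply the i.i.d. error process; returns (read_seq, n_sub, n_ins, n_del)."""
    if error_rate == 0.0:
        return seq, 0, 0, 0
    L = len(seq)
    hit = rng.random(L) < error_rate
    kinds = rng.choice(3, size=L, p=list(error_mix))
    sub_choice = rng.integers(0, 3, size=L)  # index among the 3 other bases
    ins_choice = rng.integers(0, 4, size=L)
    out = []
    n_sub = n_ins = n_del = 0
    for i, base in enumerate(seq):
        if not hit[i]:
            out.append(base)
            continue
        kind = kinds[i]
        if kind == 0:  # substitution to a different base
            others = [b for b in _BASES if b != base]
            out.append(others[sub_choice[i]])
            n_sub += 1
        elif kind == 1:  # insertion after the position
            out.append(base)
            out.append(_BASES[ins_choice[i]])
            n_ins += 1
        else:  # deletion
            n_del += 1
    return "".join(out), n_sub, n_ins, n_del


def simulate_reads(
    transcripts: list[Transcript],
    depth_or_abundance: int | dict[str, int] | list[int],
    error_rate: float,
    error_mix: tuple[float, float, float] = DEFAULT_ERROR_MIX,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[Read], list[TruthRecord]]:
    """Simulate full-length reads at controlled per-transcript depth.

    ``depth_or_abundance`` is one integer for all transcripts, a list parallel
    to ``transcripts``, or a dict by transcript id.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    if abs(sum(error_mix) - 1.0) > 1e-9:
        raise ValueError("error_mix must sum to 1")
    if isinstance(depth_or_abundance, int):
        depths = {t.transcript_id: depth_or_abundance for t in transcripts}
    elif isinstance(depth_or_abundance, dict):
        depths = depth_or_abundance
    else:
        depths = {
            t.transcript_id: d for t, d in zip(transcripts, depth_or_abundance)
        }
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss)
    qual_value = max(error_rate, 1e-6)
    reads: list[Read] = []
    truth: list[TruthRecord] = []
    for t in transcripts:
        for i in range(depths[t.transcript_id]):
            seq, n_sub, n_ins, n_del = _mutate(rng, t.seq, error_rate, error_mix)
            rid = f"{t.transcript_id}_r{i}"
            reads.append(
                Read(rid, seq, np.full(len(seq), qual_value), cluster_id=t.gene_id)
            )
            truth.append(
                TruthRecord(
                    rid,
                    t.transcript_id,
                    n_sub,
                    n_ins,
                    n_del,
                    alignment_length=len(t.seq) + n_ins,
                )
            )
    return reads, truth


def _base_aligned_at(query: str, target: str, tpos: int) -> str | None:
    """Query base aligned to target position ``tpos`` (None for a deletion)."""
    qp = tp = 0
    for n, op in align_path(query, target):
        if op in ("=", "X"):
            if tp <= tpos < tp + n:
                return query[qp + (tpos - tp)]
            qp += n
            tp += n
        elif op == "I":
            qp += n
        else:  # 'D'
            if tp <= tpos < tp + n:
                return None
            tp += n
    return None


def snp_experiment(
    n_reads: int,
    snp_fraction: float,
    base_seq_len: int = 208,
    snp_pos_range: tuple[int, int] = (50, 150),
    error_rate: float = 0.07,
    replicates: int = 10,
    seed: int | np.random.SeedSequence = 0,
    params: Params | None = None,
) -> list[bool]:
    """Allele-retention experiment for an isolated SNP.

    Each replicate builds two identical copies of a random transcript,
    plants a SNP in one at a uniform position within ``snp_pos_range``,
    simulates ``round(n*f)`` mutant and ``n - round(n*f)`` wild-type reads at
    the given error rate, corrects the cluster, and reports whether any
    corrected read still carries the SNP base at the SNP position (located by
    alignment to the mutant allele).
    """
    if not 0.0 < snp_fraction <= 0.5:
        raise ValueError("snp_fraction must lie in (0, 0.5]")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    retained: list[bool] = []
    for child in ss.spawn(replicates):
        rng = np.random.default_rng(child)
        wild = _random_seq(rng, base_seq_len)
        pos = int(rng.integers(snp_pos_range[0], snp_pos_range[1] + 1))
        snp_base = rng.choice([b for b in _BASES if b != wild[pos]])
        mutant = wild[:pos] + snp_base + wild[pos + 1 :]
        n_mut = round(n_reads * snp_fraction)
        transcripts = [
            Transcript("wild", wild, "snp_gene", [(0, len(wild))]),
            Transcript("mut", mutant, "snp_gene", [(0, len(mutant))]),
        ]
        reads, _ = simulate_reads(
            transcripts,
            {"wild": n_reads - n_mut, "mut": n_mut},
            error_rate,
            seed=child.spawn(1)[0],
        )
        corrected = correct_cluster(ClusterInput("snp_gene", reads), params=params)
        retained.append(
            any(
                _base_aligned_at(r.seq, mutant, pos) == snp_base
                for r in corrected.reads
            )
        )
    return retained


def exon_experiment(
    deletion_len: int,
    n_reads: int,
    minor_fraction: float,
    base_seq_len: int = 208,
    del_pos_range: tuple[int, int] = (50, 150),
    error_rate: float = 0.07,
    replicates: int = 10,
    seed: int | np.random.SeedSequence = 0,
    params: Params | None = None,
) -> list[tuple[float, float]]:
    """Small-exon retention experiment.

    Each replicate deletes a substring of ``deletion_len`` from one of two
    identical transcript copies, simulates reads with ``minor_fraction``
    drawn from the minor (deleted) isoform, and reports the fraction of reads
    assigned to the minor isoform (by strictly smaller edit distance; ties
    excluded) before and after correction.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    out: list[tuple[float, float]] = []
    for child in ss.spawn(replicates):
        rng = np.random.default_rng(child)
        major = _random_seq(rng, base_seq_len)
        pos = int(rng.integers(del_pos_range[0], del_pos_range[1] + 1))
        minor = major[:pos] + major[pos + deletion_len :]
        n_minor = round(n_reads * minor_fraction)
        transcripts = [
            Transcript("major", major, "exon_gene", [(0, len(major))]),
            Transcript("minor", minor, "exon_gene", [(0, len(minor))]),
        ]
        reads, _ = simulate_reads(
            transcripts,
            {"major": n_reads - n_minor, "minor": n_minor},
            error_rate,
            seed=child.spawn(1)[0],
        )
        corrected = correct_cluster(ClusterInput("exon_gene", reads), params=params)

        def minor_frac(rs) -> float:
            n_min = n_assigned = 0
            for r in rs:
                d_minor = edit_distance(r.seq, minor)
                d_major = edit_distance(r.seq, major)
                if d_minor == d_major:
                    continue
                n_assigned += 1
                if d_minor < d_major:
                    n_min += 1
            return n_min / n_assigned if n_assigned else float("nan")

        out.append((minor_frac(reads), minor_frac(corrected.reads)))
    return out


def depth_experiment(
    n_genes: int = 20,
    depth_cycle: tuple[int, ...] = (1, 2, 3, 5, 10, 1, 2, 3, 20, 50),
    exon_count_range: tuple[int, int] = (4, 7),
    exon_len_range: tuple[int, int] = (60, 140),
    max_isoforms: int = 4,
    error_rate: float = 0.07,
    seed: int | np.random.SeedSequence = 0,
    params: Params | None = None,
):
    """Depth-controlled correction experiment over exon-sharing gene families.

    Genes are generated with 1..``max_isoforms`` isoforms; transcript depths
    are assigned by cycling ``depth_cycle`` over all transcripts in order.
    Every gene cluster is simulated at ``error_rate``, corrected, and
    evaluated against its own transcripts.  Returns the per-read metrics
    table (see :func:`ontcorrect.evaluate.evaluate`) with a ``depth`` column.
    """
    from .evaluate import evaluate  # deferred: evaluate imports pandas

    import pandas as pd

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    gene_seeds = ss.spawn(n_genes)
    frames = []
    cursor = 0
    for g, child in enumerate(gene_seeds):
        rng = np.random.default_rng(child)
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        n_iso = int(rng.integers(1, min(max_isoforms, n_exons) + 1))
        transcripts = make_gene(
            n_iso, n_exons, exon_len_range, child.spawn(1)[0], gene_id=f"g{g}"
        )
        depths = {}
        for t in transcripts:
            depths[t.transcript_id] = depth_cycle[cursor % len(depth_cycle)]
            cursor += 1
        reads, truth = simulate_reads(
            transcripts, depths, error_rate, seed=child.spawn(2)[1]
        )
        cluster = ClusterInput(f"g{g}", reads)
        corrected = correct_cluster(cluster, params=params)
        per_read, _ = evaluate(corrected.reads, reads, truth, transcripts)
        tid_depth = {tid: d for tid, d in depths.items()}
        per_read["depth"] = per_read["transcript_id"].map(tid_depth)
        frames.append(per_read)
    return pd.concat(frames, ignore_index=True)


def write_transcripts_fasta(transcripts: list[Transcript], path: str | os.PathLike):
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id} gene={t.gene_id}\n{t.seq}\n")


def write_truth_tsv(truth: list[TruthRecord], path: str | os.PathLike):
    with open(path, "w") as fh:
        fh.write("read_id\ttranscript_id\tn_sub\tn_ins\tn_del\n")
        for t in truth:
            fh.write(
                f"{t.read_id}\t{t.transcript_id}\t{t.n_sub}\t{t.n_ins}\t{t.n_del}\n"
            )
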