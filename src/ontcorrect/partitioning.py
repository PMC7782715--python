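"""Interval support and optimal read partitioning.

Each anchor pair ``((m1, p), (m2, q))`` on a read defines the candidate
interval ``[p + k, q)`` (anchors excluded).  Its *support* ``a`` is the number
of reads — the read itself included — whose occurrence of the same anchor pair
spans a segment passing the quality-aware similarity test
``ed(s, s') < |s| * (eps_s + eps_s')``.  The interval weight is
``a * (q - p - k)``: support times span.  The read is then partitioned by
solving weighted interval scheduling exactly over all candidates, which
prefers combinations of highly supported intervals covering as much of the
read as possible.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from ._alignlib import edit_distance
from .anchoring import AnchorPair, PairIndex
from .seqio import ClusterInput, Read, mean_error_rate

__all__ = [
    "SupportedInterval",
    "is_similar",
    "compute_support",
    "solve_interval_scheduling",
]


@dataclass
class SupportedInterval:
    """A candidate scheduling unit on one read.

    ``begin``/``end`` are the half-open interval bounds ``[p + k, q)``
    (anchors excluded); ``segments`` lists the supporting spans
    ``(read_id, start, end)`` *including* both anchor k-mers, target read
    first.
    """

    read_id: str
    begin: int
    end: int
    support: int
    weight: float = 0.0
    segments: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.begin >= self.end:
            raise ValueError(f"empty interval [{self.begin}, {self.end})")
        if not self.weight:
            self.weight = self.support * (self.end - self.begin)


def is_similar(s: str, s_prime: str, eps_s: float, eps_s_prime: float) -> bool:
    """Quality-aware similarity: ``ed(s, s') < |s| * (eps_s + eps_s')``.

    The threshold is the expected number of differences if both segments
    carry independent errors at their mean per-base rates; the inequality is
    strict.
    """
    if not s:
        raise ValueError("s must be nonempty")
    # the 1e-9 guard keeps the strict inequality exact at representable
    # boundaries (e.g. ed = 14 vs |s|(0.07 + 0.07))
    return edit_distance(s, s_prime) < len(s) * (eps_s + eps_s_prime) - 1e-9


def compute_support(
    read: Read,
    pair: AnchorPair,
    index: PairIndex,
    cluster: ClusterInput,
) -> SupportedInterval:
    """Support of one anchor-pair interval, by direct per-segment alignment.

    For every other read carrying the same ``(m1, m2)`` key, only its
    occurrence with the smallest edit distance to the target segment is
    considered, and it counts iff it passes :func:`is_similar`.  The target
    read always supports itself, so support is at least 1.

    This is the reference (exhaustive) implementation; the batch engine in
    :mod:`ontcorrect.corrector` computes the same quantities from cached
    whole-read alignments.
    """
    k = index.k
    p, q = pair.left.pos, pair.right.pos
    occs = index.get(pair.key)
    if occs is None or not any(r == read.read_id and a == p and b == q for r, a, b in occs):
        raise ValueError(
            f"anchor pair {pair.key} at ({p}, {q}) not indexed for read {read.read_id!r}"
        )
    s = read.seq[p : q + k]
    eps_s = mean_error_rate(read, p, q + k)
    by_id = {r.read_id: r for r in cluster.reads}

    # group occurrences per read, keep the smallest-ed one for each
    per_read: dict[str, tuple[int, int, int]] = {}
    for rid, a, b in occs:
        if rid == read.read_id:
            continue
        other = by_id[rid]
        d = edit_distance(s, other.seq[a : b + k])
        best = per_read.get(rid)
        if best is None or d < best[0]:
            per_read[rid] = (d, a, b)

    segments = [(read.read_id, p, q + k)]
    for rid in (r.read_id for r in cluster.reads):  # stable cluster order
        if rid not in per_read:
            continue
        d, a, b = per_read[rid]
        other = by_id[rid]
        eps_sp = mean_error_rate(other, a, b + k)
        if d < len(s) * (eps_s + eps_sp):
            segments.append((rid, a, b + k))

    return SupportedInterval(
        read_id=read.read_id,
        begin=p + k,
        end=q,
        support=len(segments),
        segments=segments,
    )


def solve_interval_scheduling(
    intervals: list[SupportedInterval],
) -> list[SupportedInterval]:
    """Exact weighted interval scheduling by dynamic programming.

    Returns a maximum-total-weight subset of pairwise non-overlapping
    intervals (half-open semantics: two intervals conflict iff they share a
    position), ordered by ``begin``.  On ties the DP includes the
    later-sorted interval, so among equally optimal schedules the one whose
    rightmost interval starts later is preferred.  ``O(n log n)``.
    """
    if not intervals:
        return []
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].end, intervals[i].begin))
    ends = [intervals[i].end for i in order]
    n = len(order)
    # pred[j]: number of intervals (in sorted order) ending at or before begin_j
    preds = [bisect_right(ends, intervals[order[j]].begin) for j in range(n)]
    dp = [0.0] * (n + 1)
    take = [False] * n
    for j in range(n):
        w = intervals[order[j]].weight + dp[preds[j]]
        if w >= dp[j]:  # '>=': prefer including the later interval on ties
            dp[j + 1] = w
            take[j] = True
        else:
            dp[j + 1] = dp[j]
    chosen: list[SupportedInterval] = []
    j = n
    while j > 0:
        if take[j - 1]:
            chosen.append(intervals[order[j - 1]])
            j = preds[j - 1]
        else:
            j -= 1
    chosen.sort(key=lambda iv: iv.begin)
    return chosen
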