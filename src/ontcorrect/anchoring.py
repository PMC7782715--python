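"""Minimizer anchors and the cross-read anchor-pair index.

A *positional minimizer* ``(m, p)`` is the lexicographically smallest k-mer in
a sliding window of k-mer start positions; two minimizers on the same read
separated by a bounded distance form an *anchor pair*, which delimits a
candidate correction interval.  The index maps each k-mer pair to every read
position where it occurs, which is how a read finds the homologous segments of
its cluster siblings without whole-read alignment.

Plain byte-lexicographic order is used for k-mer comparison; ``N`` sorts
between ``G`` and ``T``, so all-``N`` windows never outcompete ACGT k-mers.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import NamedTuple

from .seqio import ClusterInput

__all__ = [
    "PositionalMinimizer",
    "AnchorPair",
    "Params",
    "PairIndex",
    "minimizers",
    "anchor_pairs",
    "mask_polya",
    "adaptive_window",
    "build_pair_index",
]


class PositionalMinimizer(NamedTuple):
    kmer: str
    pos: int


class AnchorPair(NamedTuple):
    left: PositionalMinimizer
    right: PositionalMinimizer
    read_id: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.left.kmer, self.right.kmer)


@dataclass
class Params:
    """Tunable parameters of the correction algorithm.

    ``w`` defaults to ``k`` (every k-mer is an anchor candidate) and is raised
    adaptively with cluster size; ``x_min``/``x_max`` bound the anchor-pair
    span; ``T`` is the trusted-variant frequency parameter.
    """

    k: int = 9
    w: int | None = None
    x_min: int | None = None
    x_max: int = 80
    T: float = 0.1
    exact_instance_limit: int = 50
    max_seq_to_spoa: int = 200
    max_seq: int = 1000

    def __post_init__(self) -> None:
        if self.w is None:
            self.w = self.k
        if self.x_min is None:
            self.x_min = 2 * self.k
        if not (1 <= self.k <= self.w):
            raise ValueError(f"require 1 <= k <= w, got k={self.k}, w={self.w}")
        if self.x_min < self.k:
            raise ValueError("x_min must be >= k so paired anchors cannot overlap")
        if not (0.0 < self.T < 1.0):
            raise ValueError("T must lie in (0, 1)")


def minimizers(seq: str, k: int, w: int) -> list[PositionalMinimizer]:
    """Ordered set of positional minimizers of ``seq``.

    For every window start ``p`` in ``[0, len(seq) - k]`` the lexicographically
    smallest k-mer starting in ``[p, p + w - k + 1)`` (clipped to valid starts)
    is a minimizer; ties go to the leftmost position.  Duplicate ``(kmer, pos)``
    pairs from overlapping windows are collapsed.  A sequence shorter than
    ``k`` yields an empty list.
    """
    n = len(seq) - k + 1
    if n <= 0:
        return []
    kmers = [seq[i : i + k] for i in range(n)]
    span = w - k + 1
    dq: deque[int] = deque()
    out: list[PositionalMinimizer] = []
    last = -1
    pushed = 0
    for p in range(n):
        hi = min(p + span, n)
        while pushed < hi:
            # strict '>' keeps the earlier position on ties (leftmost wins)
            while dq and kmers[dq[-1]] > kmers[pushed]:
                dq.pop()
            dq.append(pushed)
            pushed += 1
        while dq[0] < p:
            dq.popleft()
        pos = dq[0]
        if pos != last:
            out.append(PositionalMinimizer(kmers[pos], pos))
            last = pos
    return out


def anchor_pairs(
    minis: list[PositionalMinimizer], x_min: int, x_max: int, read_id: str = ""
) -> list[AnchorPair]:
    """All minimizer pairs separated by ``x_min <= p_j - p_i <= x_max``.

    Output is ordered by ``(p_i, p_j)``.
    """
    out: list[AnchorPair] = []
    n = len(minis)
    j0 = 0
    for i in range(n):
        pi = minis[i].pos
        while j0 < n and minis[j0].pos < pi + x_min:
            j0 += 1
        j = j0
        while j < n and minis[j].pos <= pi + x_max:
            out.append(AnchorPair(minis[i], minis[j], read_id))
            j += 1
    return out


def mask_polya(pairs: list[AnchorPair]) -> list[AnchorPair]:
    """Drop pairs whose *both* anchors are pure-A k-mers (polyA tail artifacts)."""
    return [
        p
        for p in pairs
        if not (
            set(p.left.kmer) == {"A"} and set(p.right.kmer) == {"A"}
        )
    ]


def adaptive_window(cluster_size: int, k: int) -> int:
    """Window length grown with cluster size: ``w = k + floor(|C| / 500)``."""
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    return k + cluster_size // 500


@dataclass
class PairIndex:
    """Lookup from a ``(kmer, kmer)`` anchor pair to its occurrences.

    Each occurrence is ``(read_id, p, q)`` — the start positions of the two
    anchors on that read.  Occurrences are stored in read order, then position
    order; the same key may occur several times on one read.
    """

    k: int
    occurrences: dict[tuple[str, str], list[tuple[str, int, int]]] = field(
        default_factory=dict
    )

    def __getitem__(self, key: tuple[str, str]) -> list[tuple[str, int, int]]:
        return self.occurrences[key]

    def get(self, key, default=None):
        return self.occurrences.get(key, default)

    def __contains__(self, key) -> bool:
        return key in self.occurrences

    def __len__(self) -> int:
        return len(self.occurrences)


def build_pair_index(cluster: ClusterInput, params: Params) -> PairIndex:
    """Index every (polyA-masked) anchor pair occurrence across the cluster."""
    index = PairIndex(k=params.k)
    occ = index.occurrences
    for read in cluster.reads:
        minis = minimizers(read.seq, params.k, params.w)
        for pair in mask_polya(anchor_pairs(minis, params.x_min, params.x_max)):
            occ.setdefault(pair.key, []).append(
                (read.read_id, pair.left.pos, pair.right.pos)
            )
    return index
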