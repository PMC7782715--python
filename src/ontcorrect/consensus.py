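"""Segment consensus, alignment matrix, and trusted-variant correction.

Supporting segments of an interval are condensed into a consensus, every
segment is aligned back to the consensus to form a column matrix, and each
column is scanned for *trusted* (context, variant) pairs: row windows around
the column that occur often enough relative to their distance from the
consensus context.  A segment is corrected column by column to the trusted
variant whose context is nearest its own.

The consensus here is a star-alignment majority vote: segments are aligned to
a center segment of median length, and each column takes its most frequent
symbol.  This satisfies the two contract properties the correction step needs
— unanimity (identical segments reproduce themselves) and majority recovery
(an isolated minority difference is voted out) — and serves the same role as
a partial-order-alignment heaviest-bundle consensus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._alignlib import align_path, edit_distance
from .anchoring import Params

__all__ = [
    "GAP",
    "hc",
    "build_consensus",
    "build_matrix",
    "trusted_threshold",
    "trusted_sets",
    "correct_row",
    "AlignmentMatrix",
    "TrustedVariant",
]

GAP = "-"


def hc(s: str) -> str:
    """Homopolymer compression: collapse runs of identical characters.

    ``hc("ATTTCAA") == "ATCA"``; idempotent.
    """
    return "".join(c for i, c in enumerate(s) if i == 0 or s[i - 1] != c)


def _rows_against_center(segments: list[str], center: str) -> list[str]:
    """Align each segment to ``center`` and merge into equal-length rows.

    Insertions relative to the center open new columns shared across rows
    (left-justified, padded with gaps); the center's own row is included at
    its original index.
    """
    ncp = len(center) + 1
    # per segment: syms[j] for center position j, ins[j] strings before pos j
    parsed: list[tuple[list[str], dict[int, str]]] = []
    max_ins = [0] * ncp
    for seg in segments:
        syms = [GAP] * len(center)
        ins: dict[int, str] = {}
        qp = tp = 0
        for n, op in align_path(seg, center):
            if op == "=" or op == "X":
                for t in range(n):
                    syms[tp + t] = seg[qp + t]
                qp += n
                tp += n
            elif op == "D":  # center-only: gap in segment row
                tp += n
            else:  # 'I': segment-only bases inserted before center position tp
                ins[tp] = ins.get(tp, "") + seg[qp : qp + n]
                qp += n
        for j, s in ins.items():
            if len(s) > max_ins[j]:
                max_ins[j] = len(s)
        parsed.append((syms, ins))

    rows = []
    for syms, ins in parsed:
        parts = []
        for j in range(len(center)):
            if max_ins[j]:
                s = ins.get(j, "")
                parts.append(s + GAP * (max_ins[j] - len(s)))
            parts.append(syms[j])
        if max_ins[len(center)]:
            s = ins.get(len(center), "")
            parts.append(s + GAP * (max_ins[len(center)] - len(s)))
        rows.append("".join(parts))
    return rows


def _center_index(segments: list[str]) -> int:
    lens = sorted(len(s) for s in segments)
    median = lens[len(lens) // 2]
    for i, s in enumerate(segments):
        if len(s) == median:
            return i
    return 0


def build_consensus(segments: list[str], max_seq_to_spoa: int = 200) -> str:
    """Majority consensus of the segments (at most ``max_seq_to_spoa`` used).

    Segments are taken in support order, so when the pool is capped the
    earliest (target-first) segments form the consensus.  If all used
    segments are identical the consensus equals them.
    """
    if not segments:
        raise ValueError("cannot build a consensus from zero segments")
    segs = segments[:max_seq_to_spoa]
    first = segs[0]
    if all(s == first for s in segs):
        return first
    ci = _center_index(segs)
    rows = _rows_against_center(segs, segs[ci])
    center_row = rows[ci]
    out = []
    for j in range(len(center_row)):
        counts = Counter(r[j] for r in rows)
        top = max(counts.values())
        best = [sym for sym, c in counts.items() if c == top]
        if len(best) == 1:
            sym = best[0]
        elif center_row[j] in best:  # tie: prefer the center's symbol
            sym = center_row[j]
        else:
            sym = min(best)  # residual tie: deterministic lexicographic
        if sym != GAP:
            out.append(sym)
    cons = "".join(out)
    return cons if cons else first


@dataclass
class AlignmentMatrix:
    """Segments aligned against a consensus, as equal-length symbol rows.

    ``consensus_row`` carries the consensus with gaps at insertion columns;
    stripping gaps from any row reproduces its source segment.
    """

    consensus_row: str
    rows: list[str]
    row_origins: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def consensus(self) -> str:
        return self.consensus_row.replace(GAP, "")

    @property
    def n_cols(self) -> int:
        return len(self.consensus_row)

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def build_matrix(
    segments: list[str],
    consensus: str,
    origins: list[tuple[str, int, int]] | None = None,
) -> AlignmentMatrix:
    """Pairwise-align every segment to the consensus and merge into a matrix.

    Insertions relative to the consensus open new all-gap columns (gap in the
    consensus row and in every row lacking the insertion), ordered by
    consensus coordinate then insertion order.
    """
    if not consensus:
        raise ValueError("consensus must be nonempty")
    rows = _rows_against_center(list(segments) + [consensus], consensus)
    return AlignmentMatrix(
        consensus_row=rows[-1],
        rows=rows[:-1],
        row_origins=list(origins) if origins is not None else [],
    )


@dataclass
class TrustedVariant:
    """A trusted (context window, center symbol) pair for one matrix column."""

    context: str
    variant: str
    count: int
    is_consensus: bool = False


def trusted_threshold(
    m_rows: int, T: float, c_prime: str, b: str
) -> float | None:
    """Occurrence threshold for a non-consensus context ``b``.

    Returns ``max(3, m*T / min(ed(c', b), ed(hc(c'), hc(b))))`` as a real
    number, or ``None`` when ``b`` and the consensus context are identical
    under homopolymer compression (a pure homopolymer-length variation, which
    is never trusted).  Gap symbols are stripped before the edit distances.
    """
    cp = c_prime.replace(GAP, "")
    bb = b.replace(GAP, "")
    hcp, hbb = hc(cp), hc(bb)
    if hcp == hbb:
        return None
    denom = min(edit_distance(cp, bb), edit_distance(hcp, hbb))
    return max(3.0, m_rows * T / denom)


def _window(j: int, n_cols: int, half: int) -> tuple[int, int]:
    return max(0, j - half), min(n_cols, j + half + 1)


def trusted_sets(A: AlignmentMatrix, params: Params) -> list[list[TrustedVariant]]:
    """Per-column trusted contexts and variants.

    The context window spans ``2*floor(k/2) + 1`` matrix columns centered on
    the column (truncated at matrix edges).  The consensus context is always
    trusted; any other row window is trusted if it occurs in at least three
    rows and at least ``trusted_threshold`` times.  Within a column the
    non-consensus contexts are ordered by decreasing count (ties
    lexicographic) for deterministic downstream tie-breaking.
    """
    half = params.k // 2
    m = A.n_rows
    out: list[list[TrustedVariant]] = []
    for j in range(A.n_cols):
        lo, hi = _window(j, A.n_cols, half)
        cctx = A.consensus_row[lo:hi]
        counts = Counter(r[lo:hi] for r in A.rows)
        col = [
            TrustedVariant(cctx, A.consensus_row[j], counts.get(cctx, 0), True)
        ]
        extras = []
        for b, cnt in counts.items():
            if b == cctx or cnt < 3:
                continue
            thr = trusted_threshold(m, params.T, cctx, b)
            if thr is None or cnt < thr:
                continue
            extras.append(TrustedVariant(b, b[j - lo], cnt))
        extras.sort(key=lambda tv: (-tv.count, tv.context))
        col.extend(extras)
        out.append(col)
    return out


def _nearest_variant(window: str, candidates: list[TrustedVariant]) -> TrustedVariant:
    """Trusted variant whose (gap-stripped) context is nearest the row window.

    Ties: smaller edit distance first, then higher count, then the consensus
    context.
    """
    if len(candidates) == 1:
        return candidates[0]
    aw = window.replace(GAP, "")
    best = None
    best_key = None
    for rank, tv in enumerate(candidates):
        ctx = tv.context.replace(GAP, "")
        d = 0 if ctx == aw else edit_distance(ctx, aw)
        key = (d, -tv.count, 0 if tv.is_consensus else 1, rank)
        if best_key is None or key < best_key:
            best, best_key = tv, key
    return best


def correct_row(
    a: str,
    column_trust: list[list[TrustedVariant]],
    half: int,
    active: tuple[int, int] | None = None,
) -> str:
    """Correct one matrix row against the per-column trusted variants.

    Every column's decision is made against the *original* row (no cascading
    within a pass): the trusted variant with the nearest context replaces the
    row's symbol.  ``active`` optionally restricts correction to a half-open
    column range (symbols outside it are kept verbatim); gaps are stripped
    from the result.
    """
    n = len(a)
    lo_a, hi_a = active if active is not None else (0, n)
    out = []
    for j in range(n):
        if j < lo_a or j >= hi_a:
            out.append(a[j])
            continue
        lo, hi = _window(j, n, half)
        chosen = _nearest_variant(a[lo:hi], column_trust[j])
        out.append(chosen.variant)
    return "".join(out).replace(GAP, "")
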