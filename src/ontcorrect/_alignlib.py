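"""Thin wrappers around edlib: edit distances, extended-cigar parsing, and
per-position prefix arrays along a global alignment path.

edlib's extended cigar uses ``=`` (match), ``X`` (mismatch), ``I`` (base
present only in the *query*, i.e. the first argument), and ``D`` (base present
only in the *target*).  That convention is relied upon below and pinned by a
unit test.
"""

from __future__ import annotations

import re

import edlib
import numpy as np

__all__ = ["edit_distance", "align_path", "path_prefix_arrays"]

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def align_path(query: str, target: str) -> list[tuple[int, str]]:
    """Global (NW) alignment path as a list of ``(length, op)`` cigar runs."""
    if not query:
        return [(len(target), "D")] if target else []
    if not target:
        return [(len(query), "I")]
    cigar = edlib.align(query, target, task="path", mode="NW")["cigar"]
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def path_prefix_arrays(
    path: list[tuple[int, str]], query_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Prefix arrays over the query coordinate of a global alignment path.

    Returns ``(E, P)`` of length ``query_len + 1`` where ``E[i]`` is the number
    of edit operations (X, I, D) on the path before the query has consumed
    ``i`` characters, and ``P[i]`` is the number of target characters consumed
    at that point.  The edit cost of the sub-alignment induced by a query span
    ``[a, b)`` is then ``E[b] - E[a]``, and the corresponding target span is
    ``[P[a], P[b])``.

    Target-only runs (``D``) are charged to the position *before* the next
    query character, so a deletion sitting between query positions a and b
    contributes to any span containing both.
    """
    E = np.zeros(query_len + 1, dtype=np.int32)
    P = np.zeros(query_len + 1, dtype=np.int32)
    qp = 0
    tp = 0
    e = 0
    for n, op in path:
        if op == "=":
            E[qp + 1 : qp + n + 1] = e
            P[qp + 1 : qp + n + 1] = tp + np.arange(1, n + 1)
            qp += n
            tp += n
        elif op == "X":
            E[qp + 1 : qp + n + 1] = e + np.arange(1, n + 1)
            P[qp + 1 : qp + n + 1] = tp + np.arange(1, n + 1)
            qp += n
            tp += n
            e += n
        elif op == "I":  # query-only bases
            E[qp + 1 : qp + n + 1] = e + np.arange(1, n + 1)
            P[qp + 1 : qp + n + 1] = tp
            qp += n
            e += n
        else:  # 'D': target-only bases
            e += n
            tp += n
    E[qp] = e
    P[qp] = tp
    return E, P
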