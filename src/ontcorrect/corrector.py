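"""Per-read and per-cluster correction orchestration.

The exact algorithm, per read: enumerate anchor-pair candidate intervals,
weight each by support x span, solve weighted interval scheduling, and for
every selected interval build a consensus from the supporting segments,
derive per-column trusted variants, correct the read's segment to the nearest
trusted context, and splice the corrected cores back between the (unchanged)
anchor k-mers.

The approximate mode adds the shared-work heuristic: whenever an interval is
corrected, the sibling rows of its alignment matrix are corrected too and
cached per read.  A later read whose candidate interval exactly matches a
cached span reuses the corrected substring (skipping consensus and matrix
construction); candidates merely overlapping a cached span reuse its support
(skipping the support computation).

Support is computed in bulk: one whole-read alignment per read pair is cached
and each candidate's segment edit cost is read off the induced sub-alignment
between its anchors, which are exact-match k-mers shared by both reads.  The
per-segment reference implementation lives in
:func:`ontcorrect.partitioning.compute_support`.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from ._alignlib import align_path, edit_distance, path_prefix_arrays
from .anchoring import (
    AnchorPair,
    PairIndex,
    Params,
    PositionalMinimizer,
    adaptive_window,
    build_pair_index,
)
from .consensus import GAP, build_consensus, build_matrix, correct_row, trusted_sets
from .seqio import ClusterInput, Read

__all__ = ["CorrectionCache", "correct_read", "correct_cluster"]

logger = logging.getLogger("ontcorrect")

#: Error probability assigned to bases of corrected reads (Phred 30).
_CORRECTED_PROB = 1e-3


@dataclass
class CorrectionCache:
    """Corrected segments stored per read during approximate-mode correction.

    Maps ``read_id`` to ``{(start, end): (corrected_substring, support)}``
    where ``[start, end)`` is the anchor-free core span on that read.  Spans
    may overlap; on repeated writes the higher-support entry is kept.
    """

    by_read: dict[str, dict[tuple[int, int], tuple[str, int]]] = field(
        default_factory=dict
    )

    def put(self, read_id: str, start: int, end: int, seq: str, support: int) -> None:
        spans = self.by_read.setdefault(read_id, {})
        old = spans.get((start, end))
        if old is None or support > old[1]:
            spans[(start, end)] = (seq, support)

    def get_read(self, read_id: str) -> dict[tuple[int, int], tuple[str, int]]:
        return self.by_read.get(read_id, {})


# byte -> base-5 code in lexicographic (ASCII) order A < C < G < N < T
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGNT"):
    _CODE[_b] = _i


class _ClusterEngine:
    """Shared state for correcting the reads of one cluster batch.

    Anchor k-mers are integer-encoded in base 5 (preserving lexicographic
    order, N included), anchor-pair keys are packed into one int64, and all
    occurrence tables are flat numpy arrays grouped per key, so the index
    and per-pair support work are vectorized.  Requires ``k <= 13``.
    """

    def __init__(
        self,
        cluster: ClusterInput,
        params: Params,
        mode: str,
        index: PairIndex | None = None,
        cache: CorrectionCache | None = None,
    ):
        if mode not in ("exact", "approximate"):
            raise ValueError(f"unknown mode {mode!r}")
        if params.k > 13:
            raise ValueError("anchor k-mers longer than 13 are not supported")
        self.cluster = cluster
        self.reads = cluster.reads
        self.params = params
        self.mode = mode
        self.k = params.k
        self.n = len(self.reads)
        self.id2idx = {r.read_id: i for i, r in enumerate(self.reads)}
        self.cache = cache if mode == "approximate" else None
        if self.mode == "approximate" and self.cache is None:
            self.cache = CorrectionCache()

        self._build_pair_tables()

        # quality prefix sums, padded to a common length
        max_len = max((len(r) for r in self.reads), default=0)
        self.qprefix = np.zeros((self.n, max_len + 1))
        for i, r in enumerate(self.reads):
            self.qprefix[i, 1 : len(r) + 1] = np.cumsum(r.qual)
            self.qprefix[i, len(r) + 1 :] = self.qprefix[i, len(r)]

        self._aln: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._ctx_read: int | None = None
        self._ctx = None

    def _minimizer_positions(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(positions, kmer codes) of the positional minimizers of one read."""
        k, w = self.k, self.params.w
        nk = len(codes) - k + 1
        if nk <= 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        powers = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        kmers = np.lib.stride_tricks.sliding_window_view(codes, k) @ powers
        if w == k:  # every k-mer is its own window's minimizer
            return np.arange(nk, dtype=np.int64), kmers
        span = w - k + 1
        dq: deque[int] = deque()
        pos_list: list[int] = []
        last = -1
        pushed = 0
        for p in range(nk):
            hi = min(p + span, nk)
            while pushed < hi:
                while dq and kmers[dq[-1]] > kmers[pushed]:
                    dq.pop()
                dq.append(pushed)
                pushed += 1
            while dq[0] < p:
                dq.popleft()
            if dq[0] != last:
                pos_list.append(dq[0])
                last = dq[0]
        pos = np.asarray(pos_list, dtype=np.int64)
        return pos, kmers[pos]

    def _build_pair_tables(self) -> None:
        k = self.k
        x_min, x_max = self.params.x_min, self.params.x_max
        polya = 0  # base-5 code of the all-A k-mer
        all_key, all_read, all_p, all_q = [], [], [], []
        for i, r in enumerate(self.reads):
            codes = _CODE[np.frombuffer(r.seq.encode(), dtype=np.uint8)]
            if len(codes) and codes.min() < 0:
                bad = set(r.seq) - set("ACGNT")
                raise ValueError(f"read {r.read_id!r}: unsupported symbols {bad}")
            pos, kmers = self._minimizer_positions(codes)
            if len(pos) < 2:
                continue
            lo = np.searchsorted(pos, pos + x_min, side="left")
            hi = np.searchsorted(pos, pos + x_max, side="right")
            counts = np.maximum(hi - lo, 0)
            left = np.repeat(np.arange(len(pos)), counts)
            right = np.concatenate(
                [np.arange(a, b) for a, b in zip(lo, hi) if b > a]
            ) if counts.sum() else np.empty(0, dtype=np.int64)
            keep = ~((kmers[left] == polya) & (kmers[right] == polya))
            left, right = left[keep], right[keep]
            all_key.append(kmers[left] * (5**k) + kmers[right])
            all_read.append(np.full(len(left), i, dtype=np.int64))
            all_p.append(pos[left])
            all_q.append(pos[right])

        if all_key:
            occ_key = np.concatenate(all_key)
            occ_read = np.concatenate(all_read)
            occ_p = np.concatenate(all_p)
            occ_q = np.concatenate(all_q)
        else:
            occ_key = occ_read = occ_p = occ_q = np.empty(0, dtype=np.int64)

        # factorize keys and group occurrences per kid
        uniq, kid_all = np.unique(occ_key, return_inverse=True)
        order = np.lexsort((occ_q, occ_p, occ_read, kid_all))
        self.occ_kid = kid_all[order]
        self.occ_read = occ_read[order]
        self.occ_p = occ_p[order]
        self.occ_q = occ_q[order]
        self.n_kids = len(uniq)
        self.kid_occ_start = np.searchsorted(self.occ_kid, np.arange(self.n_kids))
        self.kid_occ_end = np.searchsorted(
            self.occ_kid, np.arange(self.n_kids), side="right"
        )
        # kid -> unique read list (CSR)
        pair_code = self.occ_kid * self.n + self.occ_read
        uniq_pairs = np.unique(pair_code)
        self.kidread_kid = uniq_pairs // self.n
        self.kidread_read = uniq_pairs % self.n
        self.kid_read_start = np.searchsorted(self.kidread_kid, np.arange(self.n_kids))
        self.kid_read_end = np.searchsorted(
            self.kidread_kid, np.arange(self.n_kids), side="right"
        )

        # per-read candidate-pair arrays, ordered by (p, q)
        order2 = np.lexsort((self.occ_q, self.occ_p, self.occ_read))
        r2 = self.occ_read[order2]
        starts = np.searchsorted(r2, np.arange(self.n))
        ends = np.searchsorted(r2, np.arange(self.n), side="right")
        self.pair_p = [self.occ_p[order2[s:e]] for s, e in zip(starts, ends)]
        self.pair_q = [self.occ_q[order2[s:e]] for s, e in zip(starts, ends)]
        self.pair_kid = [self.occ_kid[order2[s:e]] for s, e in zip(starts, ends)]

    def kid_occurrences_on_read(self, kid: int, ridx: int) -> list[tuple[int, int]]:
        """(p, q) occurrences of key ``kid`` on read ``ridx``."""
        s, e = self.kid_occ_start[kid], self.kid_occ_end[kid]
        sel = self.occ_read[s:e] == ridx
        return list(zip(self.occ_p[s:e][sel], self.occ_q[s:e][sel]))

    # ------------------------------------------------------------------ #
    # pairwise whole-read alignments

    def _aln_arrays(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Edit/position prefix arrays of reads i vs j, oriented on read i."""
        got = self._aln.get((i, j))
        if got is not None:
            return got
        path = align_path(self.reads[i].seq, self.reads[j].seq)
        Ei, Pi = path_prefix_arrays(path, len(self.reads[i]))
        flipped = [
            (n, "I" if op == "D" else "D" if op == "I" else op) for n, op in path
        ]
        Ej, Pj = path_prefix_arrays(flipped, len(self.reads[j]))
        self._aln[(i, j)] = (Ei, Pi)
        self._aln[(j, i)] = (Ej, Pj)
        return Ei, Pi

    # ------------------------------------------------------------------ #
    # support

    def _read_context(self, i: int):
        """Per-read working matrices, cached for the read most recently used.

        Returns ``(Dmat, Pmat, present)``: edit/position prefix arrays of
        every partner read oriented on read i, and a boolean
        (candidate-pair x read) matrix marking reads that carry each pair's
        key.
        """
        if self._ctx_read == i:
            return self._ctx
        kids = self.pair_kid[i]
        L = len(self.reads[i])
        ukids, inv = np.unique(kids, return_inverse=True)
        starts = self.kid_read_start[ukids]
        counts = self.kid_read_end[ukids] - starts
        total = int(counts.sum())
        # flatten the per-kid [start, end) ranges into one gather index
        offs = np.cumsum(counts) - counts
        flat = np.arange(total) - np.repeat(offs, counts) + np.repeat(starts, counts)
        partner_all = self.kidread_read[flat]
        present_by_kid = np.zeros((len(ukids), self.n), dtype=bool)
        present_by_kid[np.repeat(np.arange(len(ukids)), counts), partner_all] = True
        present = present_by_kid[inv]
        present[:, i] = False

        Dmat = np.zeros((self.n, L + 1), dtype=np.int64)
        Pmat = np.zeros((self.n, L + 1), dtype=np.int64)
        for j in np.unique(partner_all):
            j = int(j)
            if j == i:
                continue
            E, P = self._aln_arrays(i, j)
            Dmat[j] = E
            Pmat[j] = P
        self._ctx_read = i
        self._ctx = (Dmat, Pmat, present)
        return self._ctx

    def support_for_pairs(
        self, i: int, sel: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Support counts and passing-read matrix for selected candidate pairs.

        Returns ``(support, passing)`` with ``passing`` boolean of shape
        ``(len(sel), n_reads)``; supporting reads are those whose induced
        segment edit cost passes the quality-aware similarity test.
        """
        k = self.k
        p = self.pair_p[i][sel]
        qk = self.pair_q[i][sel] + k
        Dmat, Pmat, present_all = self._read_context(i)
        present = present_all[sel]

        E = Dmat[:, qk].T - Dmat[:, p].T
        a = Pmat[:, p].T
        b = Pmat[:, qk].T
        span = b - a
        jj = np.arange(self.n)[None, :]
        qa = self.qprefix[jj, a]
        qb = self.qprefix[jj, b]
        with np.errstate(invalid="ignore", divide="ignore"):
            eps_sp = np.where(span > 0, (qb - qa) / np.maximum(span, 1), np.inf)
        s_len = qk - p
        eps_s = (self.qprefix[i, qk] - self.qprefix[i, p]) / s_len
        thr = s_len[:, None] * (eps_s[:, None] + eps_sp) - 1e-9
        passing = present & (span > 0) & (E < thr)
        support = 1 + passing.sum(axis=1)
        return support, passing

    # ------------------------------------------------------------------ #
    # scheduling

    @staticmethod
    def _schedule(begin: np.ndarray, end: np.ndarray, weight: np.ndarray) -> list[int]:
        """Exact weighted interval scheduling; returns chosen indices by begin."""
        m = len(begin)
        if m == 0:
            return []
        order = np.lexsort((begin, end))
        e_sorted = end[order]
        b_sorted = begin[order]
        w_sorted = weight[order]
        preds = np.searchsorted(e_sorted, b_sorted, side="right")
        dp = np.zeros(m + 1)
        take = np.zeros(m, dtype=bool)
        for j in range(m):
            w = w_sorted[j] + dp[preds[j]]
            if w >= dp[j]:  # ties include the later-sorted interval
                dp[j + 1] = w
                take[j] = True
            else:
                dp[j + 1] = dp[j]
        chosen = []
        j = m
        while j > 0:
            if take[j - 1]:
                chosen.append(int(order[j - 1]))
                j = int(preds[j - 1])
            else:
                j -= 1
        chosen.sort(key=lambda t: int(begin[t]))
        return chosen

    # ------------------------------------------------------------------ #
    # segment correction

    def _passing_to_segments(
        self, i: int, t: int, passing_row: np.ndarray
    ) -> tuple[list[str], list[tuple[str, int, int]]]:
        """Collect supporting segments (target first) for candidate pair t."""
        k = self.k
        p = int(self.pair_p[i][t])
        q = int(self.pair_q[i][t])
        kid = int(self.pair_kid[i][t])
        s = self.reads[i].seq[p : q + k]
        segments = [s]
        origins = [(self.reads[i].read_id, p, q + k)]
        os_, oe_ = self.kid_occ_start[kid], self.kid_occ_end[kid]
        occ_by_read: dict[int, list[tuple[int, int]]] = {}
        for ridx, a, b in zip(
            self.occ_read[os_:oe_], self.occ_p[os_:oe_], self.occ_q[os_:oe_]
        ):
            occ_by_read.setdefault(int(ridx), []).append((int(a), int(b)))
        for j in np.flatnonzero(passing_row):
            j = int(j)
            occs = occ_by_read.get(j)
            if not occs:
                continue
            if len(occs) == 1:
                a, b = occs[0]
            else:  # several occurrences on one read: keep the closest segment
                a, b = min(
                    occs,
                    key=lambda ab: (
                        edit_distance(s, self.reads[j].seq[ab[0] : ab[1] + k]),
                        ab,
                    ),
                )
            segments.append(self.reads[j].seq[a : b + k])
            origins.append((self.reads[j].read_id, a, b + k))
        return segments, origins

    @staticmethod
    def _core_columns(row: str, seg_len: int, k: int) -> tuple[int, int]:
        """Half-open column range whose row positions fall in [k, seg_len - k)."""
        lo = hi = len(row)
        cnt = 0
        for j, sym in enumerate(row):
            if cnt >= k and lo == len(row):
                lo = j
            if cnt >= seg_len - k:
                hi = j
                break
            if sym != GAP:
                cnt += 1
        if lo > hi:
            lo = hi
        return lo, hi

    def _correct_interval(self, i: int, t: int, passing_row: np.ndarray) -> str:
        """Correct one selected interval of read i; returns the corrected core.

        In approximate mode all sibling rows are corrected as well and cached
        against their own reads.
        """
        k = self.k
        segments, origins = self._passing_to_segments(i, t, passing_row)
        consensus = build_consensus(segments, self.params.max_seq_to_spoa)
        A = build_matrix(segments, consensus, origins)
        trust = trusted_sets(A, self.params)
        half = k // 2
        m = len(segments)

        def corrected_core(row_idx: int) -> str:
            row = A.rows[row_idx]
            seg_len = origins[row_idx][2] - origins[row_idx][1]
            active = self._core_columns(row, seg_len, k)
            full = correct_row(row, trust, half, active=active)
            # strip the (unchanged) anchor flanks to recover the core
            return full[k : len(full) - k]

        core = corrected_core(0)
        if self.cache is not None:
            for r_idx in range(1, m):
                rid, start, end = origins[r_idx]
                self.cache.put(rid, start + k, end - k, corrected_core(r_idx), m)
            rid0, start0, end0 = origins[0]
            self.cache.put(rid0, start0 + k, end0 - k, core, m)
        return core

    # ------------------------------------------------------------------ #
    # whole-read correction

    def correct_read_idx(self, i: int) -> Read:
        read = self.reads[i]
        k = self.k
        p_arr = self.pair_p[i]
        q_arr = self.pair_q[i]
        m = len(p_arr)
        if m == 0:
            logger.info("read %s: no anchor pairs; returned unchanged", read.read_id)
            return Read(read.read_id, read.seq, read.qual.copy(), read.cluster_id)

        begin = p_arr + k
        end = q_arr

        support = np.zeros(m, dtype=np.int64)
        cached_exact: dict[int, str] = {}
        need = np.ones(m, dtype=bool)
        if self.cache is not None:
            spans = self.cache.get_read(read.read_id)
            if spans:
                # a candidate whose span matches a processed region reuses the
                # stored support and, if selected, the corrected substring;
                # all other candidates are supported from scratch (partial
                # overlaps are not trusted: substituting their support was
                # found to distort the scheduling instance badly)
                for t in range(m):
                    hit = spans.get((int(begin[t]), int(end[t])))
                    if hit is not None:
                        cached_exact[t] = hit[0]
                        support[t] = hit[1]
                        need[t] = False

        to_compute = np.flatnonzero(need)
        if len(to_compute):
            # chunk to bound the (pairs x reads) working matrices
            chunk = max(1, 2_000_000 // max(1, self.n))
            for lo in range(0, len(to_compute), chunk):
                sub = to_compute[lo : lo + chunk]
                sup, _ = self.support_for_pairs(i, sub)
                support[sub] = sup

        weight = support.astype(np.float64) * (end - begin)
        chosen = self._schedule(begin, end, weight)

        pieces: list[str] = []
        cursor = 0
        for t in chosen:
            b, e = int(begin[t]), int(end[t])
            if t in cached_exact:
                core = cached_exact[t]
            else:
                _, passing = self.support_for_pairs(i, np.asarray([t]))
                core = self._correct_interval(i, t, passing[0])
            pieces.append(read.seq[cursor:b])
            pieces.append(core)
            cursor = e
        pieces.append(read.seq[cursor:])
        new_seq = "".join(pieces)
        return Read(
            read.read_id,
            new_seq,
            np.full(len(new_seq), _CORRECTED_PROB),
            read.cluster_id,
        )


def correct_read(
    read: Read,
    cluster: ClusterInput,
    index: PairIndex,
    params: Params,
    mode: str = "exact",
    cache: CorrectionCache | None = None,
) -> Read:
    """Correct a single read against its cluster (see module docstring)."""
    if read.read_id not in {r.read_id for r in cluster.reads}:
        raise ValueError(f"read {read.read_id!r} does not belong to the cluster")
    engine = _ClusterEngine(cluster, params, mode, index=index, cache=cache)
    return engine.correct_read_idx(engine.id2idx[read.read_id])


def correct_cluster(
    cluster: ClusterInput,
    params: Params | None = None,
    mode: str = "auto",
    set_w_dynamically: bool = True,
) -> ClusterInput:
    """Correct every read of a cluster, preserving input order.

    Mode ``auto`` selects the exact algorithm for clusters of at most
    ``exact_instance_limit`` reads and the approximate (cached) algorithm
    otherwise.  Reads are processed in batches of at most ``max_seq``; the
    anchor-pair index and the correction cache are per batch.  With
    ``set_w_dynamically`` the minimizer window grows with cluster size
    (``w = k + floor(|C|/500)``).
    """
    if params is None:
        params = Params()
    if not cluster.reads:
        return ClusterInput(cluster.cluster_id, [])
    if set_w_dynamically:
        params = replace(params, w=adaptive_window(len(cluster.reads), params.k))
    if mode == "auto":
        mode = (
            "exact"
            if len(cluster.reads) <= params.exact_instance_limit
            else "approximate"
        )
    logger.info(
        "cluster %s: %d reads, mode=%s, w=%d",
        cluster.cluster_id,
        len(cluster.reads),
        mode,
        params.w,
    )
    corrected: list[Read] = []
    for lo in range(0, len(cluster.reads), params.max_seq):
        batch = ClusterInput(
            cluster.cluster_id, cluster.reads[lo : lo + params.max_seq]
        )
        engine = _ClusterEngine(batch, params, mode)
        corrected.extend(engine.correct_read_idx(i) for i in range(len(batch.reads)))
    return ClusterInput(cluster.cluster_id, corrected)
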