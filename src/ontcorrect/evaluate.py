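"""Evaluation of corrected reads against known true transcripts.

Error rates follow the mismatch-rate convention: the number of insertions,
deletions and substitutions in a unit-cost global alignment, divided by the
alignment length (matches + mismatches + indels).  A read is *miscorrected*
if it has more mismatches to its true transcript after correction than
before, and *overcorrected* if its corrected sequence has a strictly smaller
edit distance to some transcript other than its true one; the overcorrection
distance is ``ed(true) - ed(closest)``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from ._alignlib import align_path, edit_distance
from .seqio import Read
from .simulate import Transcript, TruthRecord

__all__ = ["alignment_stats", "evaluate", "write_metrics", "write_summary"]


def alignment_stats(query: str, target: str) -> tuple[int, int]:
    """(mismatches, alignment_length) of a unit-cost global alignment."""
    n_mis = 0
    n_cols = 0
    for n, op in align_path(query, target):
        n_cols += n
        if op != "=":
            n_mis += n
    return n_mis, n_cols


def evaluate(
    corrected: list[Read],
    original: list[Read],
    truth: list[TruthRecord],
    transcripts: list[Transcript],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-read metrics and a summary over a simulated, corrected dataset.

    Inputs are matched by read id; a mismatch between the corrected and
    original id sets raises ``ValueError``.  Returns ``(per_read, summary)``
    where ``per_read`` has one row per read (error rate before/after,
    miscorrected and overcorrected flags, overcorrection distance) and
    ``summary`` aggregates by true read depth (median error rates, fraction
    miscorrected / overcorrected).
    """
    orig_by_id = {r.read_id: r for r in original}
    corr_by_id = {r.read_id: r for r in corrected}
    if set(orig_by_id) != set(corr_by_id):
        raise ValueError("corrected and original read ids do not match")
    tr_by_id = {t.transcript_id: t for t in transcripts}
    depth = {}
    for rec in truth:
        depth[rec.transcript_id] = depth.get(rec.transcript_id, 0) + 1

    rows = []
    for rec in truth:
        if rec.read_id not in orig_by_id:
            raise ValueError(f"truth record for unknown read {rec.read_id!r}")
        true_t = tr_by_id[rec.transcript_id]
        before = orig_by_id[rec.read_id].seq
        after = corr_by_id[rec.read_id].seq
        mis_b, len_b = alignment_stats(before, true_t.seq)
        mis_a, len_a = alignment_stats(after, true_t.seq)
        ed_true = edit_distance(after, true_t.seq)
        ed_others = [
            edit_distance(after, t.seq)
            for t in transcripts
            if t.transcript_id != rec.transcript_id
        ]
        over = bool(ed_others) and min(ed_others) < ed_true
        rows.append(
            {
                "read_id": rec.read_id,
                "transcript_id": rec.transcript_id,
                "depth": depth[rec.transcript_id],
                "error_rate_before": mis_b / len_b if len_b else 0.0,
                "error_rate_after": mis_a / len_a if len_a else 0.0,
                "mismatches_before": mis_b,
                "mismatches_after": mis_a,
                "miscorrected": mis_a > mis_b,
                "overcorrected": over,
                "overcorrection_distance": (ed_true - min(ed_others)) if over else 0,
            }
        )
    per_read = pd.DataFrame(rows)
    summary = (
        per_read.groupby("depth")
        .agg(
            n_reads=("read_id", "size"),
            median_error_before=("error_rate_before", "median"),
            median_error_after=("error_rate_after", "median"),
            frac_miscorrected=("miscorrected", "mean"),
            frac_overcorrected=("overcorrected", "mean"),
        )
        .reset_index()
    )
    return per_read, summary


def write_metrics(per_read: pd.DataFrame, path: str | os.PathLike) -> None:
    per_read.to_csv(path, sep="\t", index=False)


def write_summary(summary: pd.DataFrame, path: str | os.PathLike) -> None:
    summary.to_csv(path, sep="\t", index=False)
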