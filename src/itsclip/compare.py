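"""Trim-agreement analysis between two trimmings of the same reads.

Reads trimmed identically are counted without aligning; otherwise the two
trimmed products are globally aligned under an affine-gap scheme (match +2,
mismatch -1, gap open -0.5, gap extend -0.1; the first base of a gap costs
the open penalty only, subsequent bases the extend penalty) and the start
and stop offsets are the signed overhangs at the alignment ends.  The
summary reports the fraction of reads whose start and stop both agree within
a window of k bases (k = 0, 1, 2, 5 by default).

When per-read trim-coordinate tables on the same original coordinate system
are available (e.g. from the simulator's ground truth), offsets can instead
be taken as direct coordinate differences, which is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align

from .fastq_io import FastqRecord

SUMMARY_WINDOWS = (0, 1, 2, 5)


@dataclass
class ScoringScheme:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -0.5
    gap_extend: float = -0.1

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


@dataclass
class TrimComparison:
    read_id: str
    start_offset: int
    stop_offset: int
    identical: bool

    def __post_init__(self) -> None:
        if self.identical and (self.start_offset or self.stop_offset):
            raise ValueError("identical reads must have zero offsets")

    def within(self, window: int) -> bool:
        return max(abs(self.start_offset), abs(self.stop_offset)) <= window


@dataclass
class ComparisonSummary:
    n_common: int
    n_only_a: int
    n_only_b: int
    n_identical: int
    fraction_within: dict[int, float]
    window: int

    @property
    def agreement(self) -> float:
        """Fraction of common reads agreeing within the configured window."""
        return self.fraction_within[self.window]


def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def global_align(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> tuple[float, str, str]:
    """Optimal global affine-gap alignment of two sequences.

    Returns (score, gapped a, gapped b); ties are broken deterministically by
    taking the first alignment in the aligner's enumeration.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    scheme = scheme or ScoringScheme()
    alignments = _aligner(scheme).align(a, b)
    top = alignments[0]
    return float(top.score), top[0], top[1]


def _end_gaps(row: str) -> tuple[int, int]:
    lead = len(row) - len(row.lstrip("-"))
    trail = len(row) - len(row.rstrip("-"))
    return lead, trail


def compare_reads(
    read_a: str, read_b: str, read_id: str, scheme: ScoringScheme | None = None
) -> TrimComparison:
    """Offsets of trimming B relative to trimming A for one read.

    start_offset > 0 means B's trim starts downstream of A's (B lost bases at
    the front); stop_offset > 0 means B's trim ends downstream of A's.
    """
    if read_a == read_b:
        return TrimComparison(read_id=read_id, start_offset=0, stop_offset=0, identical=True)
    _, row_a, row_b = global_align(read_a, read_b, scheme)
    lead_a, trail_a = _end_gaps(row_a)
    lead_b, trail_b = _end_gaps(row_b)
    return TrimComparison(
        read_id=read_id,
        start_offset=lead_b - lead_a,
        stop_offset=trail_a - trail_b,
        identical=False,
    )


def compare_trim_tables(
    coords_a: Mapping[str, tuple[int, int]],
    coords_b: Mapping[str, tuple[int, int]],
) -> list[TrimComparison]:
    """Exact offsets from two (start, stop) tables on the same coordinates."""
    out = []
    for read_id in coords_a.keys() & coords_b.keys():
        (sa, ea), (sb, eb) = coords_a[read_id], coords_b[read_id]
        out.append(
            TrimComparison(
                read_id=read_id,
                start_offset=sb - sa,
                stop_offset=eb - ea,
                identical=(sa, ea) == (sb, eb),
            )
        )
    return out


def _index_records(records: Iterable[FastqRecord], label: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise ValueError(f"duplicate read id {rec.id!r} in set {label}")
        seqs[rec.id] = rec.sequence
    return seqs


def summarize(
    comparisons: Sequence[TrimComparison],
    n_only_a: int = 0,
    n_only_b: int = 0,
    window: int = 2,
) -> ComparisonSummary:
    n = len(comparisons)
    windows = sorted(set(SUMMARY_WINDOWS) | {window})
    fractions = {
        w: (sum(c.within(w) for c in comparisons) / n if n else float("nan"))
        for w in windows
    }
    return ComparisonSummary(
        n_common=n,
        n_only_a=n_only_a,
        n_only_b=n_only_b,
        n_identical=sum(c.identical for c in comparisons),
        fraction_within=fractions,
        window=window,
    )


def compare_trim_sets(
    set_a: Iterable[FastqRecord],
    set_b: Iterable[FastqRecord],
    window: int = 2,
    scheme: ScoringScheme | None = None,
) -> tuple[list[TrimComparison], ComparisonSummary]:
    """Per-read offsets plus the within-k-bases summary for two trimmings."""
    seqs_a = _index_records(set_a, "A")
    seqs_b = _index_records(set_b, "B")
    common = sorted(seqs_a.keys() & seqs_b.keys())
    comparisons = [
        compare_reads(seqs_a[rid], seqs_b[rid], rid, scheme) for rid in common
    ]
    summary = summarize(
        comparisons,
        n_only_a=len(seqs_a.keys() - seqs_b.keys()),
        n_only_b=len(seqs_b.keys() - seqs_a.keys()),
        window=window,
    )
    return comparisons, summary


def report_text(summary: ComparisonSummary) -> str:
    lines = [
        "trim agreement report",
        f"  reads compared: {summary.n_common}",
        f"  only in A: {summary.n_only_a}",
        f"  only in B: {summary.n_only_b}",
        f"  identical: {summary.n_identical}",
    ]
    for w in sorted(summary.fraction_within):
        frac = summary.fraction_within[w]
        lines.append(f"  within {w} bases: {frac:.5f}")
    return "\n".join(lines) + "\n"
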