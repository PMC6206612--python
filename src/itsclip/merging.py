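"""Overlap-based merging of paired-end reads into consensus sequences.

The reverse read is reverse-complemented and slid against the forward read;
the placement maximising the number of matching bases (ties broken toward the
longer overlap) is accepted if the overlap is at least ``min_overlap`` bases
and its mismatch rate is at most ``max_mismatch_rate``.  Read-through pairs
(insert shorter than a read) are handled by clipping the overhangs, so the
merged length always equals the insert length.

Consensus rules inside the overlap: agreeing bases get quality
min(q1+q2, cap); disagreements take the higher-quality base with quality
|q1-q2| (ties: forward base, quality 2).  N never counts as a match and never
wins a disagreement.  Outside the overlap, bases and qualities are copied
from their source read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from .fastq_io import FastqRecord, ReadPair, PHRED_OFFSET

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MergeParams:
    min_overlap: int = 12
    max_mismatch_rate: float = 0.25
    quality_cap: int = 41

    def __post_init__(self) -> None:
        if self.min_overlap < 4:
            raise ValueError("min_overlap must be >= 4")
        if not 0.0 <= self.max_mismatch_rate < 0.5:
            raise ValueError("max_mismatch_rate must be in [0, 0.5)")


@dataclass
class MergedRead:
    record: FastqRecord
    overlap_length: int
    source_id: str


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_N = ord("N")


def _best_placement(
    fwd_seq: np.ndarray, rc_seq: np.ndarray, params: MergeParams
) -> Optional[tuple[int, int]]:
    """Best (offset, overlap_length) of the reverse-complement against the
    forward read, or None.

    ``offset`` is the start of the RC read relative to the start of the
    forward read; negative offsets mean read-through (R extends left of F).
    """
    lf, lr = len(fwd_seq), len(rc_seq)
    best: Optional[tuple[int, int, int]] = None  # (matches, overlap, offset)
    for offset in range(-(lr - params.min_overlap), lf - params.min_overlap + 1):
        lo = max(0, offset)
        hi = min(lf, offset + lr)
        ov = hi - lo
        if ov < params.min_overlap:
            continue
        f_win = fwd_seq[lo:hi]
        r_win = rc_seq[lo - offset : hi - offset]
        informative = (f_win != _N) & (r_win != _N)
        matches = int(np.count_nonzero((f_win == r_win) & informative))
        mismatches = int(np.count_nonzero((f_win != r_win) & informative))
        if mismatches > params.max_mismatch_rate * ov:
            continue
        key = (matches, ov, offset)
        if best is None or key[:2] > best[:2]:
            best = key
    if best is None:
        return None
    return best[2], best[1]


def find_overlap(
    forward: FastqRecord, reverse: FastqRecord, params: MergeParams | None = None
) -> Optional[int]:
    """Overlap length between a pair after reverse-complementing the reverse
    read, or None when no placement satisfies the length and mismatch bounds."""
    params = params or MergeParams()
    placement = _best_placement(
        _encode(forward.sequence), _encode(reverse_complement(reverse.sequence)), params
    )
    return None if placement is None else placement[1]


def merge_pair(pair: ReadPair, params: MergeParams | None = None) -> Optional[MergedRead]:
    params = params or MergeParams()
    fwd = pair.forward
    rc_seq = reverse_complement(pair.reverse.sequence)
    rc_qual = pair.reverse.quality[::-1]
    placement = _best_placement(_encode(fwd.sequence), _encode(rc_seq), params)
    if placement is None:
        return None
    offset, overlap = placement
    insert_len = offset + len(rc_seq)  # clip F overhang past the insert end
    lo, hi = max(0, offset), min(len(fwd.sequence), offset + len(rc_seq))

    bases: list[str] = []
    quals: list[str] = []
    for pos in range(0, insert_len):
        in_f = pos < len(fwd.sequence)
        in_r = offset <= pos
        if in_f and in_r and lo <= pos < hi:
            fb, fq = fwd.sequence[pos], ord(fwd.quality[pos]) - PHRED_OFFSET
            rb, rq = rc_seq[pos - offset], ord(rc_qual[pos - offset]) - PHRED_OFFSET
            if fb == rb:
                base, q = fb, min(fq + rq, params.quality_cap)
            elif fb == "N":
                base, q = rb, rq
            elif rb == "N":
                base, q = fb, fq
            elif fq == rq:
                base, q = fb, 2
            else:
                base, q = (fb, fq - rq) if fq > rq else (rb, rq - fq)
            bases.append(base)
            quals.append(chr(q + PHRED_OFFSET))
        elif in_f and not in_r:
            bases.append(fwd.sequence[pos])
            quals.append(fwd.quality[pos])
        elif in_r:
            bases.append(rc_seq[pos - offset])
            quals.append(rc_qual[pos - offset])
    merged = FastqRecord(
        id=pair.id,
        sequence="".join(bases),
        quality="".join(quals),
        description="merged",
    )
    return MergedRead(record=merged, overlap_length=overlap, source_id=pair.id)


def merge_pairs(
    pairs: Iterable[ReadPair], params: MergeParams | None = None
) -> tuple[list[MergedRead], list[str]]:
    """Merge a stream of pairs; returns (merged reads, unmergeable pair ids).

    Unmergeable pairs are reported, never silently dropped.
    """
    params = params or MergeParams()
    merged: list[MergedRead] = []
    failed: list[str] = []
    for pair in pairs:
        result = merge_pair(pair, params)
        if result is None:
            failed.append(pair.id)
        else:
            merged.append(result)
    return merged, failed
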