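"""Exact dereplication and greedy abundance-ordered centroid clustering.

Merged reads are collapsed to unique sequences with abundances, sorted by
descending abundance (ties broken lexicographically), then scanned greedily:
each sequence joins the first existing cluster whose representative is within
the identity threshold, else founds a new cluster.  The permitted threshold
range is 98-100% identity (default 99.5%), mirroring the trimmer's contract.

Identity between two sequences is computed on a minimum-edit-distance global
alignment as (alignment columns - edits) / alignment columns, so gap columns
count in the denominator.  A shared 8-mer count bound (q-gram lemma) screens
out pairs that provably cannot reach the threshold before any alignment is
attempted.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

from .merging import MergedRead

THRESHOLD_RANGE = (0.98, 1.00)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class DereplicatedSequence:
    sequence: str
    abundance: int
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.abundance != len(self.member_ids):
            raise ValueError("abundance must equal the number of member ids")


@dataclass
class Cluster:
    representative: DereplicatedSequence
    members: list[DereplicatedSequence]
    identity_threshold: float


def dereplicate_exact(reads: Iterable[MergedRead]) -> list[DereplicatedSequence]:
    """Collapse identical sequences, sorted by descending abundance then
    lexicographically by sequence."""
    members: dict[str, list[str]] = defaultdict(list)
    for read in reads:
        members[read.record.sequence].append(read.record.id)
    uniques = [
        DereplicatedSequence(sequence=seq, abundance=len(ids), member_ids=ids)
        for seq, ids in members.items()
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


def _alignment_columns(cigar: str) -> int:
    return sum(int(n) for n, _ in _CIGAR_RE.findall(cigar))


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matching columns over total columns of a
    minimum-edit-distance alignment (terminal gap columns included)."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    result = edlib.align(a, b, mode="NW", task="path")
    cols = _alignment_columns(result["cigar"])
    return (cols - result["editDistance"]) / cols


def max_edits_for_threshold(len_a: int, len_b: int, threshold: float) -> int:
    """Largest edit distance still compatible with ``identity >= threshold``.

    identity = (cols - d)/cols >= t implies d <= (1-t)*cols, and
    cols <= max(len_a, len_b) + d/2, giving d <= 2(1-t)max / (1+t).
    """
    m = max(len_a, len_b)
    return int(2 * (1 - threshold) * m / (1 + threshold))


def _kmer_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def shared_kmer_lower_bound(len_a: int, len_b: int, max_edits: int, k: int) -> int:
    """q-gram lemma: a sequence pair within ``max_edits`` edits shares at
    least (min_kmers - k*max_edits) k-mers (counting multiplicity)."""
    return min(len_a, len_b) - k + 1 - k * max_edits


def _shared_kmers(ca: Counter, cb: Counter) -> int:
    return sum((ca & cb).values())


def identity_at_least(a: str, b: str, threshold: float) -> bool:
    """True iff pairwise_identity(a, b) >= threshold (early-exits via a
    banded edit-distance computation)."""
    if a == b:
        return True
    e_max = max_edits_for_threshold(len(a), len(b), threshold)
    result = edlib.align(a, b, mode="NW", task="path", k=e_max)
    if result["editDistance"] == -1:
        return False
    cols = _alignment_columns(result["cigar"])
    return (cols - result["editDistance"]) / cols >= threshold


def cluster_greedy(
    uniques: Sequence[DereplicatedSequence],
    threshold: float,
    kmer_prescreen: bool = True,
    k: int = 8,
) -> list[Cluster]:
    """Greedy first-fit centroid clustering of abundance-sorted uniques.

    At threshold 1.00 the result is one cluster per distinct sequence.
    Representatives are created in scan (descending-abundance) order.
    """
    lo, hi = THRESHOLD_RANGE
    if not lo <= threshold <= hi:
        raise ValueError(f"identity threshold {threshold} outside [{lo}, {hi}]")
    clusters: list[Cluster] = []
    rep_kmers: list[Counter] = []
    for unique in uniques:
        placed = False
        if threshold < 1.0:
            kc = _kmer_counts(unique.sequence, k) if kmer_prescreen else None
            for idx, cluster in enumerate(clusters):
                rep = cluster.representative
                if kmer_prescreen:
                    e_max = max_edits_for_threshold(
                        len(unique.sequence), len(rep.sequence), threshold
                    )
                    bound = shared_kmer_lower_bound(
                        len(unique.sequence), len(rep.sequence), e_max, k
                    )
                    if bound > 0 and _shared_kmers(kc, rep_kmers[idx]) < bound:
                        continue
                if identity_at_least(unique.sequence, rep.sequence, threshold):
                    cluster.members.append(unique)
                    placed = True
                    break
        if not placed:
            clusters.append(
                Cluster(representative=unique, members=[unique], identity_threshold=threshold)
            )
            rep_kmers.append(_kmer_counts(unique.sequence, k) if kmer_prescreen else Counter())
    return clusters


def cluster_map_rows(clusters: Sequence[Cluster]) -> list[tuple[str, str, int]]:
    """(read_id, representative_id, cluster_index) rows for the TSV map."""
    rows = []
    for idx, cluster in enumerate(clusters):
        rep_id = cluster.representative.member_ids[0]
        for member in cluster.members:
            for read_id in member.member_ids:
                rows.append((read_id, rep_id, idx))
    return rows
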