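"""Applying a cluster representative's boundary call to every member read.

The representative's (start, stop) coordinates are applied *unmodified* to
each member sequence — no re-alignment.  Substitutions between a member and
its representative therefore do not move the trim point, but insertions or
deletions do; that positional drift is bounded by the clustering identity
threshold and is an accepted property of the method.  The stop coordinate is
clipped to each member's length; members whose clipped window collapses are
excluded with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .boundary import BoundaryCall
from .dereplication import Cluster
from .fastq_io import FastqRecord

TRIM_STATUSES = ("trimmed", "excluded_no_hit", "excluded_empty", "excluded_unmerged")


@dataclass
class TrimOutcome:
    read_id: str
    status: str
    start: Optional[int] = None
    stop: Optional[int] = None

    def __post_init__(self) -> None:
        if self.status not in TRIM_STATUSES:
            raise ValueError(f"unknown trim status {self.status!r}")
        if self.status == "trimmed" and not (
            self.start is not None and self.stop is not None and 0 <= self.start < self.stop
        ):
            raise ValueError(f"trimmed outcome for {self.read_id!r} needs 0 <= start < stop")


def propagate_trim(cluster: Cluster, call: Optional[BoundaryCall]) -> list[TrimOutcome]:
    """Trim outcomes for every read in the cluster under the representative's
    call (None call: the whole cluster is excluded_no_hit)."""
    outcomes: list[TrimOutcome] = []
    for member in cluster.members:
        stop = None if call is None else min(call.stop, len(member.sequence))
        for read_id in member.member_ids:
            if call is None:
                outcomes.append(TrimOutcome(read_id=read_id, status="excluded_no_hit"))
            elif stop is not None and stop <= call.start:
                outcomes.append(TrimOutcome(read_id=read_id, status="excluded_empty"))
            else:
                outcomes.append(
                    TrimOutcome(read_id=read_id, status="trimmed", start=call.start, stop=stop)
                )
    return outcomes


def trim_record(record: FastqRecord, start: int, stop: int) -> FastqRecord:
    """Slice sequence and quality identically; id and description unchanged."""
    if not 0 <= start < stop <= len(record.sequence):
        raise ValueError(
            f"trim window [{start}, {stop}) invalid for read {record.id!r} "
            f"of length {len(record.sequence)}"
        )
    return FastqRecord(
        id=record.id,
        sequence=record.sequence[start:stop],
        quality=record.quality[start:stop],
        description=record.description,
    )


def apply_trims(
    records: Iterable[FastqRecord],
    outcomes: Sequence[TrimOutcome],
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Apply per-read outcomes to records (in input order).

    Returns (trimmed records, excluded records); excluded records carry the
    exclusion reason appended to their description for auditability.
    """
    by_id = {o.read_id: o for o in outcomes}
    trimmed: list[FastqRecord] = []
    excluded: list[FastqRecord] = []
    for record in records:
        outcome = by_id.get(record.id)
        if outcome is None or outcome.status != "trimmed":
            reason = outcome.status if outcome is not None else "excluded_no_hit"
            tagged = FastqRecord(
                id=record.id,
                sequence=record.sequence,
                quality=record.quality,
                description=(record.description + " " + reason).strip(),
            )
            excluded.append(tagged)
        else:
            trimmed.append(trim_record(record, outcome.start, outcome.stop))
    return trimmed, excluded


def outcome_rows(outcomes: Sequence[TrimOutcome]) -> list[tuple[str, str, str, str]]:
    """(read_id, status, start, stop) rows for the TSV outcome log."""
    return [
        (
            o.read_id,
            o.status,
            "" if o.start is None else str(o.start),
            "" if o.stop is None else str(o.stop),
        )
        for o in outcomes
    ]
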