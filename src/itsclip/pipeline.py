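"""End-to-end trimming pipeline.

read -> (merge if paired) -> dereplicate -> greedy cluster at the chosen
identity -> profile-HMM boundary call per cluster representative ->
propagate the representative's coordinates to every member read -> write
trimmed FASTQ.  Every stage's counts are collected into a reproducible run
summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from . import boundary as bd
from . import dereplication as derep
from . import fastq_io as fio
from . import merging as mg
from . import trimming as tr
from .synthetic_data import default_flank_alignments, read_alignment_fasta

logger = logging.getLogger("itsclip")

DEFAULT_CLUSTER_ID = 0.995


@dataclass
class RunConfig:
    """Parameters of one trimming run; the log echoes all of them."""

    input_path: Union[str, Path]
    output_path: Union[str, Path]
    layout: str = "single"  # paired2file | interleaved | single
    input_path2: Optional[Union[str, Path]] = None
    region: str = "ITS1"
    cluster_id: float = DEFAULT_CLUSTER_ID
    thresholds: bd.HeuristicThresholds = field(default_factory=bd.HeuristicThresholds)
    merge: mg.MergeParams = field(default_factory=mg.MergeParams)
    seed: int = 42
    use_prefilter: bool = True
    keep_excluded: Optional[Union[str, Path]] = None
    outcome_tsv: Optional[Union[str, Path]] = None
    flank_alignment_dir: Optional[Union[str, Path]] = None
    calibration_n: int = 1000
    calibration_length: int = 400

    def __post_init__(self) -> None:
        if self.layout not in fio.LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.layout == "paired2file" and self.input_path2 is None:
            raise ValueError("paired2file layout requires input_path2")
        if self.layout != "paired2file" and self.input_path2 is not None:
            raise ValueError(f"layout {self.layout!r} takes a single input file")
        if self.region not in bd.REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        lo, hi = derep.THRESHOLD_RANGE
        if not lo <= self.cluster_id <= hi:
            raise ValueError(f"cluster_id must be in [{lo}, {hi}]")


@dataclass
class RunSummary:
    n_input: int
    n_merged: int
    n_unmerged: int
    n_unique: int
    n_clusters: int
    n_trimmed: int
    n_excluded_no_hit: int
    n_excluded_empty: int
    outcomes: list[tr.TrimOutcome]
    calls: dict[str, Optional[bd.BoundaryCall]]  # representative read id -> call

    def as_log_lines(self, config: RunConfig) -> list[str]:
        return [
            f"region={config.region} cluster_id={config.cluster_id} seed={config.seed}",
            f"thresholds f1={config.thresholds.f1} f2={config.thresholds.f2} "
            f"f3={config.thresholds.f3} prefilter={config.use_prefilter}",
            f"merge min_overlap={config.merge.min_overlap} "
            f"max_mismatch_rate={config.merge.max_mismatch_rate} "
            f"quality_cap={config.merge.quality_cap}",
            f"input reads/pairs: {self.n_input}",
            f"merged: {self.n_merged}  unmerged (excluded): {self.n_unmerged}",
            f"unique sequences: {self.n_unique}",
            f"clusters at {config.cluster_id}: {self.n_clusters}",
            f"trimmed: {self.n_trimmed}  excluded_no_hit: {self.n_excluded_no_hit}  "
            f"excluded_empty: {self.n_excluded_empty}",
        ]


def load_profiles(
    flank_alignment_dir: Optional[Union[str, Path]],
    seed: int,
    calibration_n: int = 1000,
    calibration_length: int = 400,
) -> list[bd.ProfileHMM]:
    """Build and calibrate the three flank profiles.

    Alignments come from ``flank_alignment_dir`` (files SSU_tail.afa,
    R5_8S.afa, LSU_head.afa) or, by default, the bundled seeded synthetic
    flank families.
    """
    if flank_alignment_dir is None:
        alignments = default_flank_alignments()
    else:
        root = Path(flank_alignment_dir)
        alignments = {
            name: read_alignment_fasta(root / f"{name.replace('.', '_')}.afa")
            for name in bd.FLANK_NAMES
        }
    profiles = []
    for i, name in enumerate(bd.FLANK_NAMES):
        profile = bd.build_profile(alignments[name], name=name)
        profiles.append(
            bd.calibrate_profile(
                profile, seed=seed + i, n=calibration_n, length=calibration_length
            )
        )
    return profiles


def trim_merged_reads(
    merged: Sequence[mg.MergedRead],
    profiles: Sequence[bd.ProfileHMM],
    region: str,
    cluster_id: float,
    thresholds: bd.HeuristicThresholds | None = None,
    use_prefilter: bool = True,
) -> tuple[list[tr.TrimOutcome], dict[str, Optional[bd.BoundaryCall]], int, int]:
    """Cluster merged reads, call boundaries on representatives and propagate.

    Returns (outcomes, calls keyed by representative's first read id,
    n_unique, n_clusters).
    """
    thresholds = thresholds or bd.HeuristicThresholds()
    uniques = derep.dereplicate_exact(merged)
    clusters = derep.cluster_greedy(uniques, cluster_id)
    outcomes: list[tr.TrimOutcome] = []
    calls: dict[str, Optional[bd.BoundaryCall]] = {}
    for cluster in clusters:
        rep = cluster.representative
        rep_id = rep.member_ids[0]
        hits = bd.scan_read(
            profiles,
            rep.sequence,
            seq_id=rep_id,
            thresholds=thresholds,
            use_prefilter=use_prefilter,
        )
        call = bd.call_boundaries(hits, region, len(rep.sequence), seq_id=rep_id)
        calls[rep_id] = call
        outcomes.extend(tr.propagate_trim(cluster, call))
    return outcomes, calls, len(uniques), len(clusters)


def run_trim(config: RunConfig) -> RunSummary:
    """Execute the full pipeline described by ``config``.

    On any fatal error partial outputs are removed and the exception
    propagates to the caller (the CLI maps it to a nonzero exit).
    """
    output_path = Path(config.output_path)
    created: list[Path] = []
    try:
        paired = config.layout in ("paired2file", "interleaved")
        if paired:
            pairs = list(
                fio.read_records(config.input_path, config.layout, config.input_path2)
            )
            n_input = len(pairs)
            merged, failed = mg.merge_pairs(pairs, config.merge)
            original = [m.record for m in merged]
        else:
            records = list(fio.read_records(config.input_path, "single"))
            n_input = len(records)
            merged = [
                mg.MergedRead(record=rec, overlap_length=len(rec), source_id=rec.id)
                for rec in records
            ]
            failed = []
            original = records
        for read_id in failed:
            logger.info("unmerged pair excluded: %s", read_id)

        profiles = load_profiles(
            config.flank_alignment_dir,
            seed=config.seed,
            calibration_n=config.calibration_n,
            calibration_length=config.calibration_length,
        )
        outcomes, calls, n_unique, n_clusters = trim_merged_reads(
            merged,
            profiles,
            config.region,
            config.cluster_id,
            config.thresholds,
            config.use_prefilter,
        )
        outcomes.extend(
            tr.TrimOutcome(read_id=rid, status="excluded_unmerged") for rid in failed
        )
        trimmed, excluded = tr.apply_trims(original, outcomes)

        created.append(output_path)
        fio.write_records(trimmed, output_path)
        if config.keep_excluded is not None:
            path = Path(config.keep_excluded)
            created.append(path)
            fio.write_records(excluded, path)
        if config.outcome_tsv is not None:
            path = Path(config.outcome_tsv)
            created.append(path)
            with open(path, "w") as handle:
                handle.write("read_id\tstatus\tstart\tstop\n")
                for row in tr.outcome_rows(outcomes):
                    handle.write("\t".join(row) + "\n")

        by_status = {s: 0 for s in tr.TRIM_STATUSES}
        for o in outcomes:
            by_status[o.status] += 1
        summary = RunSummary(
            n_input=n_input,
            n_merged=len(merged),
            n_unmerged=len(failed),
            n_unique=n_unique,
            n_clusters=n_clusters,
            n_trimmed=by_status["trimmed"],
            n_excluded_no_hit=by_status["excluded_no_hit"],
            n_excluded_empty=by_status["excluded_empty"],
            outcomes=outcomes,
            calls=calls,
        )
        for line in summary.as_log_lines(config):
            logger.info("%s", line)
        # accounting invariant: every input read lands in exactly one bucket
        assert n_input == sum(by_status.values()), "read accounting mismatch"
        return summary
    except Exception:
        for path in created:
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        raise
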