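"""Simulator for ITS-like amplicons with known boundary ground truth.

Each taxon's insert is built as SSU_tail + ITS1 + 5.8S + ITS2 + LSU_head:
the conserved flanks are drawn from seeded default multiple alignments
(substitution-mutated per taxon at ``substitution_rate_taxa``), while the
ITS1/ITS2 spacers are taxon-specific uniform-random DNA with lengths drawn
from the configured ranges.  Reads carry independent per-base substitution
errors and Phred qualities from a discretised truncated normal; paired mode
emits a forward read from the 5' end and a reverse-complemented read from
the 3' end of the insert.

The default flank alignments are generated (seeded), not copied from any
rRNA database — they mimic the conservation structure of real SSU/5.8S/LSU
flanks (a mostly conserved core with a few polymorphic and gapped columns)
but are synthetic sequences.  Ground truth is reported on the error-free
insert coordinate system, 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .fastq_io import FastqRecord, ReadPair, write_records, interleave
from .merging import reverse_complement

BASES = np.array(list("ACGT"))

DEFAULT_FLANK_SEED = 20180906  # fixed so the bundled profiles are stable
FLANK_LENGTHS = {"SSU_tail": 50, "R5.8S": 155, "LSU_head": 50}
FLANK_ALIGNMENT_DEPTH = 12


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def default_flank_alignments(
    seed: int = DEFAULT_FLANK_SEED,
    depth: int = FLANK_ALIGNMENT_DEPTH,
    divergence: float = 0.05,
) -> dict[str, list[str]]:
    """Seeded synthetic aligned FASTA-style flank families.

    Each family is ``depth`` sequences derived from a random ancestor at the
    given substitution divergence, with two mostly-gapped columns inserted so
    profile construction exercises insert states.
    """
    rng = np.random.default_rng(seed)
    alignments: dict[str, list[str]] = {}
    for name, length in FLANK_LENGTHS.items():
        ancestor = _random_dna(rng, length)
        rows = [_mutate_substitutions(rng, ancestor, divergence) for _ in range(depth)]
        # two insert columns: a minority of sequences carry a residue there
        positions = sorted(rng.choice(np.arange(5, length - 5), size=2, replace=False))
        for offset, pos in enumerate(positions):
            col = pos + offset
            carriers = set(rng.choice(depth, size=max(1, depth // 6), replace=False))
            rows = [
                r[:col] + (_random_dna(rng, 1) if i in carriers else "-") + r[col:]
                for i, r in enumerate(rows)
            ]
        alignments[name] = rows
    return alignments


def consensus_from_alignment(alignment: list[str]) -> str:
    """Ungapped majority-rule consensus of an aligned family."""
    out = []
    for col in zip(*alignment):
        counts = {}
        for c in col:
            if c not in "-.":
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            continue
        if sum(counts.values()) * 2 <= len(col):
            continue  # majority-gap column: not part of the consensus
        out.append(max(sorted(counts), key=counts.get))
    return "".join(out)


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults emulate a 2x300 bp MiSeq fungal ITS run: modest taxon panels,
    5% divergence among taxon flanks, 0.5% per-base sequencing error, and
    spacer lengths chosen so paired reads always overlap.
    """

    seed: int
    n_taxa: int = 8
    reads_per_taxon: int = 50
    its1_length_range: tuple[int, int] = (120, 160)
    its2_length_range: tuple[int, int] = (120, 160)
    substitution_rate_taxa: float = 0.05
    per_base_error_rate: float = 0.005
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    read_length: int = 300
    paired: bool = False
    min_overlap: int = 12
    flank_seed: int = DEFAULT_FLANK_SEED

    def __post_init__(self) -> None:
        for name in ("substitution_rate_taxa", "per_base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("its1_length_range", "its2_length_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be a non-empty positive range")
        if self.n_taxa < 1 or self.reads_per_taxon < 1:
            raise ValueError("n_taxa and reads_per_taxon must be >= 1")
        if self.paired:
            max_insert = (
                FLANK_LENGTHS["SSU_tail"]
                + self.its1_length_range[1]
                + FLANK_LENGTHS["R5.8S"]
                + self.its2_length_range[1]
                + FLANK_LENGTHS["LSU_head"]
            )
            if 2 * self.read_length - max_insert < self.min_overlap:
                raise ValueError(
                    "read_length too short for paired reads to overlap: "
                    f"2*{self.read_length} < {max_insert} + {self.min_overlap}"
                )


@dataclass
class SimTruth:
    read_id: str
    taxon: int
    its1_start: int
    its1_stop: int
    its2_start: int
    its2_stop: int

    def __post_init__(self) -> None:
        if not self.its1_start < self.its1_stop <= self.its2_start < self.its2_stop:
            raise ValueError("truth coordinates out of order")


@dataclass
class SimResult:
    reads: list[FastqRecord]  # merged-style single reads (paired=False)
    pairs: list[ReadPair]  # populated when paired=True
    truth: list[SimTruth]
    inserts: dict[str, str]  # read_id -> error-free insert
    flank_alignments: dict[str, list[str]]
    config: SimConfig

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "read_id": t.read_id,
                    "taxon": t.taxon,
                    "its1_start": t.its1_start,
                    "its1_stop": t.its1_stop,
                    "its2_start": t.its2_start,
                    "its2_stop": t.its2_stop,
                }
                for t in self.truth
            ]
        )


def _quality_string(rng: np.random.Generator, length: int, mean: float, sd: float) -> str:
    q = rng.normal(mean, sd, size=length)
    q = np.clip(np.rint(q), 2, 41).astype(int)
    return "".join(chr(int(v) + 33) for v in q)


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    return _mutate_substitutions(rng, seq, rate)


def simulate_amplicons(config: SimConfig) -> SimResult:
    """Generate reads, ground truth and the flank alignments used.

    Identical seeds give identical output bytes.
    """
    rng = np.random.default_rng(config.seed)
    alignments = default_flank_alignments(config.flank_seed)
    consensi = {name: consensus_from_alignment(aln) for name, aln in alignments.items()}

    taxa: list[tuple[str, SimTruth]] = []
    for t in range(config.n_taxa):
        ssu = _mutate_substitutions(rng, consensi["SSU_tail"], config.substitution_rate_taxa)
        r58 = _mutate_substitutions(rng, consensi["R5.8S"], config.substitution_rate_taxa)
        lsu = _mutate_substitutions(rng, consensi["LSU_head"], config.substitution_rate_taxa)
        its1 = _random_dna(rng, int(rng.integers(*config.its1_length_range, endpoint=True)))
        its2 = _random_dna(rng, int(rng.integers(*config.its2_length_range, endpoint=True)))
        insert = ssu + its1 + r58 + its2 + lsu
        coords = (
            len(ssu),
            len(ssu) + len(its1),
            len(ssu) + len(its1) + len(r58),
            len(ssu) + len(its1) + len(r58) + len(its2),
        )
        taxa.append((insert, coords))

    reads: list[FastqRecord] = []
    pairs: list[ReadPair] = []
    truth: list[SimTruth] = []
    inserts: dict[str, str] = {}
    for t, (insert, coords) in enumerate(taxa):
        for r in range(config.reads_per_taxon):
            read_id = f"taxon{t}_read{r}"
            truth.append(
                SimTruth(
                    read_id=read_id,
                    taxon=t,
                    its1_start=coords[0],
                    its1_stop=coords[1],
                    its2_start=coords[2],
                    its2_stop=coords[3],
                )
            )
            inserts[read_id] = insert
            if config.paired:
                fwd_true = insert[: config.read_length]
                rev_true = reverse_complement(insert[-config.read_length :])
                fwd_seq = _add_errors(rng, fwd_true, config.per_base_error_rate)
                rev_seq = _add_errors(rng, rev_true, config.per_base_error_rate)
                fwd = FastqRecord(
                    id=read_id,
                    sequence=fwd_seq,
                    quality=_quality_string(
                        rng, len(fwd_seq), config.quality_mean, config.quality_sd
                    ),
                    description="1:N:0:1",
                )
                rev = FastqRecord(
                    id=read_id,
                    sequence=rev_seq,
                    quality=_quality_string(
                        rng, len(rev_seq), config.quality_mean, config.quality_sd
                    ),
                    description="2:N:0:1",
                )
                pairs.append(ReadPair(fwd, rev))
            else:
                seq = _add_errors(rng, insert, config.per_base_error_rate)
                reads.append(
                    FastqRecord(
                        id=read_id,
                        sequence=seq,
                        quality=_quality_string(
                            rng, len(seq), config.quality_mean, config.quality_sd
                        ),
                        description="merged",
                    )
                )
    return SimResult(
        reads=reads,
        pairs=pairs,
        truth=truth,
        inserts=inserts,
        flank_alignments=alignments,
        config=config,
    )


def write_alignment_fasta(alignment: list[str], name: str, path) -> None:
    with open(path, "w") as handle:
        for i, row in enumerate(alignment):
            handle.write(f">{name}_{i}\n{row}\n")


def read_alignment_fasta(path) -> list[str]:
    rows: list[str] = []
    current: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line.startswith(">"):
                if current:
                    rows.append("".join(current))
                    current = []
            elif line:
                current.append(line)
    if current:
        rows.append("".join(current))
    return rows


def write_simulation(result: SimResult, out_dir, gzip_out: bool = False) -> dict[str, Path]:
    """Write FASTQ (single or paired), truth TSV and flank alignments."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzip_out else ".fastq"
    paths: dict[str, Path] = {}
    if result.config.paired:
        paths["fastq_r1"] = out_dir / f"reads_R1{ext}"
        paths["fastq_r2"] = out_dir / f"reads_R2{ext}"
        write_records((p.forward for p in result.pairs), paths["fastq_r1"], gzip_out)
        write_records((p.reverse for p in result.pairs), paths["fastq_r2"], gzip_out)
    else:
        paths["fastq"] = out_dir / f"reads{ext}"
        write_records(result.reads, paths["fastq"], gzip_out)
    paths["truth"] = out_dir / "truth.tsv"
    result.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    for name, aln in result.flank_alignments.items():
        key = f"alignment_{name}"
        paths[key] = out_dir / f"{name.replace('.', '_')}.afa"
        write_alignment_fasta(aln, name, paths[key])
    return paths
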