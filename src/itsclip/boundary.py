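"""Locating conserved rRNA flanks (SSU tail, 5.8S, LSU head) on reads with
profile HMMs, and converting flank hits into ITS trim coordinates.

The ITS1 region lies between the end of the SSU (18S) gene and the start of
the 5.8S gene; ITS2 lies between the end of the 5.8S and the start of the LSU
(28S).  Each flank is modelled as a profile HMM with match/insert/delete
states built from a multiple alignment; the best local (Smith-Waterman-style
entry/exit) Viterbi match of each profile on a read gives the flank's
envelope, and the envelopes' inner edges are the trim coordinates.

Scoring model
-------------
Paths enter any match state M_j with log2(1/M) and may exit after any match
state at no cost; match and insert emissions are scored as log2-odds against
a background base distribution, so the bit score of a hit is the log2 odds of
the matched subsequence under the profile versus background.  Bit scores are
converted to per-sequence P-values via a Gumbel (EVD) calibration fitted by
maximum likelihood on the Viterbi scores of seeded random background
sequences; ``HmmHit.e_value`` is that per-sequence P-value (the expected hit
count for a single random sequence of the calibration length).

A single ungapped-diagonal prefilter gated by the F1 threshold short-circuits
the full Viterbi (gated by F3).  The staged MSV/Viterbi/Forward cascade of
full HMMER is deliberately not reproduced; F2 is accepted for interface
compatibility and ignored (a warning is emitted when it differs from the
default).  All coordinates are 0-based half-open internally; conversion to
and from 1-based inclusive happens only at the HMMER domain-table boundary.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from numba import njit
from scipy.stats import gumbel_r

FLANK_NAMES = ("SSU_tail", "R5.8S", "LSU_head")
REGIONS = ("ITS1", "ITS2", "ALL")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

NEG_INF = float("-inf")


@dataclass
class HeuristicThresholds:
    """Significance thresholds in the spirit of HMMER's F1/F2/F3 heuristics.

    f1 gates the ungapped prefilter, f3 gates the final Viterbi P-value; f2
    exists only for interface compatibility and is ignored.
    """

    f1: float = 1e-6
    f2: float = 1e-6
    f3: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("f1", "f2", "f3"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.f2 != 1e-6:
            warnings.warn(
                "f2 is accepted for compatibility but ignored: this "
                "implementation uses a single prefilter (f1) plus a final "
                "Viterbi threshold (f3)",
                stacklevel=2,
            )


@dataclass
class HmmHit:
    """A scored local match of one flank profile on one read."""

    profile: str
    seq_id: str
    seq_start: int  # 0-based half-open envelope on the read
    seq_end: int
    profile_start: int  # 0-based half-open on the model
    profile_end: int
    bit_score: float
    e_value: float
    profile_length: int = 0  # 0 when unknown; enables edge extrapolation

    def __post_init__(self) -> None:
        if not 0 <= self.seq_start < self.seq_end:
            raise ValueError(f"invalid envelope [{self.seq_start}, {self.seq_end})")
        if not math.isfinite(self.bit_score):
            raise ValueError("bit score must be finite")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass
class BoundaryCall:
    """Per-read ITS trim coordinates (0-based half-open)."""

    seq_id: str
    region: str
    start: int
    stop: int
    left_flank_found: bool
    right_flank_found: bool


@dataclass
class ProfileHMM:
    """A flank profile: match emissions, pooled insert emissions, per-node
    transitions and an optional Gumbel score calibration.

    Transition arrays are indexed by 0-based node j (match state j+1); entry
    j of ``t_mm`` is P(M_{j+1} -> M_{j+2}) and so on.  The final node has no
    outgoing transitions (local exit is free after any match state).
    """

    name: str
    match_emissions: np.ndarray  # (M, 4) probabilities
    insert_emissions: np.ndarray  # (4,) probabilities
    transitions: dict[str, np.ndarray]  # keys: mm, mi, md, im, ii, dm, dd; each (M-1,)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    calibration: Optional[tuple[float, float]] = None  # (lambda, mu) for Viterbi bits
    prefilter_calibration: Optional[tuple[float, float]] = None  # for ungapped bits
    calibration_length: int = 0

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        m = self.length
        if m < 1:
            raise ValueError("profile must have at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not np.isclose(self.insert_emissions.sum(), 1.0, atol=1e-9):
            raise ValueError("insert emissions must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        for key in ("mm", "mi", "md", "im", "ii", "dm", "dd"):
            arr = np.asarray(self.transitions[key], dtype=float)
            if arr.shape != (max(m - 1, 0),):
                raise ValueError(f"transition {key} must have length M-1")
            self.transitions[key] = arr
        if m > 1:
            for group in (("mm", "mi", "md"), ("im", "ii"), ("dm", "dd")):
                total = sum(self.transitions[k] for k in group)
                if not np.allclose(total, 1.0, atol=1e-9):
                    raise ValueError(f"transition group {group} must sum to 1")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    # -- score tables ------------------------------------------------------

    def _log_odds_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(match score table (M,5), insert score row (5,), transition log2
        table (7, max(M-1,1))); N (index 4) scores 0 everywhere."""
        m = self.length
        with np.errstate(divide="ignore"):
            ms = np.full((m, 5), 0.0)
            ms[:, :4] = np.log2(self.match_emissions) - np.log2(self.background)
            ins = np.zeros(5)
            ins[:4] = np.log2(self.insert_emissions) - np.log2(self.background)
            tr = np.full((7, max(m - 1, 1)), NEG_INF)
            for row, key in enumerate(("mm", "mi", "md", "im", "ii", "dm", "dd")):
                if m > 1:
                    tr[row] = np.log2(self.transitions[key])
        return ms, ins, tr

    # -- serialization -----------------------------------------------------

    def to_text(self) -> str:
        payload = {
            "format": "itsclip-profile-1",
            "name": self.name,
            "length": self.length,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": {k: v.tolist() for k, v in self.transitions.items()},
            "background": self.background.tolist(),
            "calibration": list(self.calibration) if self.calibration else None,
            "prefilter_calibration": (
                list(self.prefilter_calibration) if self.prefilter_calibration else None
            ),
            "calibration_length": self.calibration_length,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_text(cls, text: str) -> "ProfileHMM":
        payload = json.loads(text)
        if payload.get("format") != "itsclip-profile-1":
            raise ValueError("not an itsclip profile file")
        return cls(
            name=payload["name"],
            match_emissions=np.array(payload["match_emissions"]),
            insert_emissions=np.array(payload["insert_emissions"]),
            transitions={k: np.array(v) for k, v in payload["transitions"].items()},
            background=np.array(payload["background"]),
            calibration=tuple(payload["calibration"]) if payload["calibration"] else None,
            prefilter_calibration=(
                tuple(payload["prefilter_calibration"])
                if payload["prefilter_calibration"]
                else None
            ),
            calibration_length=payload.get("calibration_length", 0),
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "ProfileHMM":
        return cls.from_text(Path(path).read_text())


def encode_sequence(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-DNA character {exc.args[0]!r} in sequence") from exc


# ---------------------------------------------------------------------------
# profile construction from a multiple alignment
# ---------------------------------------------------------------------------

def build_profile(
    alignment: Sequence[str],
    name: str = "profile",
    pseudocount: float = 0.5,
    background: Optional[np.ndarray] = None,
    max_gap_fraction: float = 0.5,
) -> ProfileHMM:
    """Estimate a profile HMM from a gapped DNA multiple alignment.

    Columns with more than ``max_gap_fraction`` gap characters become insert
    states; the rest are match columns.  Emissions and transitions are
    maximum-likelihood estimates with an additive pseudocount.  The returned
    profile is uncalibrated; see :func:`calibrate_profile`.
    """
    if len(alignment) == 0:
        raise ValueError("alignment is empty")
    if len(alignment) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    ncol = len(alignment[0])
    if any(len(s) != ncol for s in alignment):
        raise ValueError("aligned sequences must have equal length")
    rows = [s.upper() for s in alignment]
    nseq = len(rows)

    gap_frac = [sum(r[c] in "-." for r in rows) / nseq for c in range(ncol)]
    is_match = [f <= max_gap_fraction for f in gap_frac]
    m = sum(is_match)
    if m == 0:
        raise ValueError("no match columns in alignment")
    match_cols = [c for c in range(ncol) if is_match[c]]

    em = np.full((m, 4), pseudocount, dtype=float)
    ins_em = np.full(4, pseudocount, dtype=float)
    # transition counts per node j (between match states j+1 and j+2)
    tcounts = {k: np.full(max(m - 1, 1), pseudocount, dtype=float) for k in
               ("mm", "mi", "md", "im", "ii", "dm", "dd")}

    for row in rows:
        # emissions
        for j, c in enumerate(match_cols):
            ch = row[c]
            if ch in _BASE_INDEX and ch != "N":
                em[j, _BASE_INDEX[ch]] += 1.0
        for c in range(ncol):
            if not is_match[c]:
                ch = row[c]
                if ch in _BASE_INDEX and ch != "N":
                    ins_em[_BASE_INDEX[ch]] += 1.0
        # state path for transitions: M or D at match columns, I at insert
        # columns holding a residue (attributed to the preceding node)
        path: list[tuple[str, int]] = []
        node = -1
        for c in range(ncol):
            if is_match[c]:
                node += 1
                path.append(("M" if row[c] not in "-." else "D", node))
            elif row[c] not in "-.":
                path.append(("I", node))
        for (s1, n1), (s2, n2) in zip(path, path[1:]):
            if n1 < 0 or n1 >= m - 1:
                continue  # inserts before the first / after the last node
            key = (s1 + s2).lower()
            if key in ("id", "di"):
                continue  # not representable; rare and ignored
            step_ok = (n2 == n1) if s2 == "I" else (n2 == n1 + 1)
            if step_ok:
                tcounts[key][n1] += 1.0

    em /= em.sum(axis=1, keepdims=True)
    if ins_em.sum() == 0:
        ins_em = np.full(4, 0.25)  # no insert observations, no pseudocount
    else:
        ins_em /= ins_em.sum()
    transitions = {}
    for group in (("mm", "mi", "md"), ("im", "ii"), ("dm", "dd")):
        total = sum(tcounts[k] for k in group)
        safe = np.where(total > 0, total, 1.0)
        uniform = 1.0 / len(group)
        for k in group:
            transitions[k] = np.where(total > 0, tcounts[k] / safe, uniform)[
                : max(m - 1, 0)
            ]
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return ProfileHMM(
        name=name,
        match_emissions=em,
        insert_emissions=ins_em,
        transitions=transitions,
        background=bg,
    )


# ---------------------------------------------------------------------------
# Viterbi and prefilter kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _viterbi_kernel(ms, ins, tr, seq, entry):  # pragma: no cover - numba
    L = seq.shape[0]
    M = ms.shape[0]
    vm = np.full((L + 1, M), -np.inf)
    vi = np.full((L + 1, M), -np.inf)
    vd = np.full((L + 1, M), -np.inf)
    pm = np.zeros((L + 1, M), dtype=np.int8)  # 0 entry, 1 M, 2 I, 3 D
    pi = np.zeros((L + 1, M), dtype=np.int8)
    pd_ = np.zeros((L + 1, M), dtype=np.int8)
    best = -np.inf
    bi = -1
    bj = -1
    for i in range(1, L + 1):
        x = seq[i - 1]
        for j in range(M):
            # match state
            sc = entry
            ptr = 0
            if j > 0:
                a = vm[i - 1, j - 1] + tr[0, j - 1]
                if a > sc:
                    sc = a
                    ptr = 1
                a = vi[i - 1, j - 1] + tr[3, j - 1]
                if a > sc:
                    sc = a
                    ptr = 2
                a = vd[i - 1, j - 1] + tr[5, j - 1]
                if a > sc:
                    sc = a
                    ptr = 3
            vm[i, j] = ms[j, x] + sc
            pm[i, j] = ptr
            if vm[i, j] > best:
                best = vm[i, j]
                bi = i
                bj = j
            # insert state (node j; only meaningful for j < M-1)
            if j < M - 1:
                a = vm[i - 1, j] + tr[1, j]
                b = vi[i - 1, j] + tr[4, j]
                if a >= b:
                    vi[i, j] = ins[x] + a
                    pi[i, j] = 1
                else:
                    vi[i, j] = ins[x] + b
                    pi[i, j] = 2
            # delete state
            if j > 0:
                a = vm[i, j - 1] + tr[2, j - 1]
                b = vd[i, j - 1] + tr[6, j - 1]
                if a >= b:
                    vd[i, j] = a
                    pd_[i, j] = 1
                else:
                    vd[i, j] = b
                    pd_[i, j] = 3
    # traceback from (bi, bj) in match state
    si = bi
    sj = bj
    if bi >= 0:
        i = bi
        j = bj
        state = 1  # 1 M, 2 I, 3 D
        while True:
            if state == 1:
                ptr = pm[i, j]
                si = i
                sj = j
                if ptr == 0:
                    break
                i -= 1
                j -= 1
                state = ptr
            elif state == 2:
                ptr = pi[i, j]
                i -= 1
                state = ptr
            else:
                ptr = pd_[i, j]
                j -= 1
                state = ptr
    return best, bi, bj, si, sj


@njit(cache=False)
def _ungapped_kernel(ms, seq):  # pragma: no cover - numba
    L = seq.shape[0]
    M = ms.shape[0]
    prev = np.zeros(M)
    cur = np.zeros(M)
    best = -np.inf
    for i in range(L):
        x = seq[i]
        for j in range(M):
            carry = prev[j - 1] if j > 0 else 0.0
            if carry < 0.0:
                carry = 0.0
            cur[j] = ms[j, x] + carry
            if cur[j] > best:
                best = cur[j]
        prev, cur = cur, prev
    return best


def viterbi_score(profile: ProfileHMM, read: str) -> float:
    """Raw best local Viterbi bit score (no significance gating)."""
    ms, ins, tr = profile._log_odds_tables()
    seq = encode_sequence(read)
    entry = -math.log2(profile.length)
    best, *_ = _viterbi_kernel(ms, ins, tr, seq, entry)
    return float(best)


def ungapped_score(profile: ProfileHMM, read: str) -> float:
    """Best ungapped-diagonal match-state bit score (prefilter statistic)."""
    ms, _, _ = profile._log_odds_tables()
    return float(_ungapped_kernel(ms, encode_sequence(read)))


def gumbel_pvalue(score: float, calibration: tuple[float, float]) -> float:
    """P(S >= score) under a fitted Gumbel: 1 - exp(-exp(-lambda (s - mu)))."""
    lam, mu = calibration
    x = lam * (score - mu)
    if x > 700:
        return 0.0
    return -math.expm1(-math.exp(-x))


def random_background_sequences(
    profile: ProfileHMM, n: int, length: int, rng: np.random.Generator
) -> list[str]:
    bases = np.array(list("ACGT"))
    draws = rng.choice(4, size=(n, length), p=profile.background)
    return ["".join(bases[row]) for row in draws]


def calibrate_profile(
    profile: ProfileHMM,
    seed: int,
    n: int = 1000,
    length: int = 400,
) -> ProfileHMM:
    """Fit Gumbel (lambda, mu) calibrations for the Viterbi and ungapped
    prefilter scores on ``n`` random background sequences of ``length``."""
    if n < 100:
        raise ValueError("calibration needs at least 100 sequences")
    rng = np.random.default_rng(seed)
    seqs = random_background_sequences(profile, n, length, rng)
    ms, ins, tr = profile._log_odds_tables()
    entry = -math.log2(profile.length)
    v_scores = np.empty(n)
    u_scores = np.empty(n)
    for i, s in enumerate(seqs):
        enc = encode_sequence(s)
        v_scores[i] = _viterbi_kernel(ms, ins, tr, enc, entry)[0]
        u_scores[i] = _ungapped_kernel(ms, enc)
    v_loc, v_scale = gumbel_r.fit(v_scores)
    u_loc, u_scale = gumbel_r.fit(u_scores)
    return replace(
        profile,
        transitions=dict(profile.transitions),
        calibration=(float(1.0 / v_scale), float(v_loc)),
        prefilter_calibration=(float(1.0 / u_scale), float(u_loc)),
        calibration_length=length,
    )


def prefilter(
    profile: ProfileHMM, read: str, thresholds: HeuristicThresholds | None = None
) -> bool:
    """Cheap ungapped screen: True iff the read may contain a significant hit.

    Gated by f1 on the Gumbel P-value of the best ungapped diagonal score.
    Conservative by construction for near-ungapped hits; the trimming
    pipeline can disable it entirely (``use_prefilter=False``) as a fallback.
    """
    thresholds = thresholds or HeuristicThresholds()
    if profile.prefilter_calibration is None:
        return True
    score = ungapped_score(profile, read)
    return gumbel_pvalue(score, profile.prefilter_calibration) <= thresholds.f1


def viterbi_local(
    profile: ProfileHMM,
    read: str,
    seq_id: str = "",
    thresholds: HeuristicThresholds | None = None,
) -> Optional[HmmHit]:
    """Best local Viterbi hit of the profile on the read, or None when the
    hit's P-value exceeds f3.  Uncalibrated profiles are gated only on a
    positive bit score and report e_value 0."""
    if len(read) < 1:
        raise ValueError("read must be non-empty")
    thresholds = thresholds or HeuristicThresholds()
    ms, ins, tr = profile._log_odds_tables()
    seq = encode_sequence(read)
    entry = -math.log2(profile.length)
    best, bi, bj, si, sj = _viterbi_kernel(ms, ins, tr, seq, entry)
    if bi < 0:
        return None
    if profile.calibration is not None:
        pval = gumbel_pvalue(best, profile.calibration)
        if pval > thresholds.f3:
            return None
    else:
        # uncalibrated profile: no significance gating, positive score only
        if best <= 0:
            return None
        pval = 0.0
    return HmmHit(
        profile=profile.name,
        seq_id=seq_id,
        seq_start=si - 1,
        seq_end=bi,
        profile_start=sj,
        profile_end=bj + 1,
        bit_score=float(best),
        e_value=float(pval),
        profile_length=profile.length,
    )


def scan_read(
    profiles: Iterable[ProfileHMM],
    read: str,
    seq_id: str = "",
    thresholds: HeuristicThresholds | None = None,
    use_prefilter: bool = True,
) -> list[HmmHit]:
    """Run prefilter + local Viterbi for each profile; best hit per profile."""
    thresholds = thresholds or HeuristicThresholds()
    hits = []
    for profile in profiles:
        if use_prefilter and not prefilter(profile, read, thresholds):
            continue
        hit = viterbi_local(profile, read, seq_id=seq_id, thresholds=thresholds)
        if hit is not None:
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# boundary calling
# ---------------------------------------------------------------------------

def _best_hit(hits: Sequence[HmmHit], profile_name: str) -> Optional[HmmHit]:
    candidates = [h for h in hits if h.profile == profile_name]
    if not candidates:
        return None
    return max(candidates, key=lambda h: (h.bit_score, -h.seq_start))


def _full_span_end(hit: HmmHit, read_length: int) -> int:
    """Envelope end extrapolated to the profile's last column (assumed
    ungapped beyond the scored envelope)."""
    if hit.profile_length > 0:
        return min(read_length, hit.seq_end + (hit.profile_length - hit.profile_end))
    return hit.seq_end


def _full_span_start(hit: HmmHit) -> int:
    return max(0, hit.seq_start - hit.profile_start) if hit.profile_length > 0 else hit.seq_start


def call_boundaries(
    hits: Sequence[HmmHit], region: str, read_length: int, seq_id: str = ""
) -> Optional[BoundaryCall]:
    """Convert flank hits to trim coordinates for the requested region.

    The inner edge of each flank hit is the trim point; when the scored
    envelope stops short of the profile edge (a diverged or low-scoring edge
    base), the missing model columns are extrapolated as ungapped sequence so
    the trim point tracks the full flank span.  A missing flank falls back to
    the read edge with its found-flag False; when no flank relevant to the
    region was found, or the coordinates collapse (stop <= start), the read
    is excluded (None).
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    left_name = {"ITS1": "SSU_tail", "ITS2": "R5.8S", "ALL": "SSU_tail"}[region]
    right_name = {"ITS1": "R5.8S", "ITS2": "LSU_head", "ALL": "LSU_head"}[region]
    left = _best_hit(hits, left_name)
    right = _best_hit(hits, right_name)
    if left is None and right is None:
        return None
    start = _full_span_end(left, read_length) if left is not None else 0
    stop = _full_span_start(right) if right is not None else read_length
    if stop <= start:
        return None
    if not seq_id:
        for h in (left, right):
            if h is not None:
                seq_id = h.seq_id
                break
    return BoundaryCall(
        seq_id=seq_id,
        region=region,
        start=start,
        stop=min(stop, read_length),
        left_flank_found=left is not None,
        right_flank_found=right is not None,
    )


# ---------------------------------------------------------------------------
# HMMER3 domain table (domtblout) interop
# ---------------------------------------------------------------------------

def parse_domtblout(
    path, profile_names: Optional[dict[str, str]] = None
) -> list[HmmHit]:
    """Read hits from a HMMER3 per-domain table.

    Envelope columns ("env from"/"env to", 1-based inclusive) become the
    0-based half-open read envelope.  ``profile_names`` optionally maps the
    query names in the file to the flank names used here.
    """
    profile_names = profile_names or {}
    hits: list[HmmHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(
                    f"{path}: malformed domtblout line {lineno}: "
                    f"expected >= 22 fields, got {len(fields)}"
                )
            try:
                hit = HmmHit(
                    profile=profile_names.get(fields[3], fields[3]),
                    seq_id=fields[0],
                    seq_start=int(fields[19]) - 1,
                    seq_end=int(fields[20]),
                    profile_start=int(fields[15]) - 1,
                    profile_end=int(fields[16]),
                    bit_score=float(fields[13]),
                    e_value=float(fields[12]),
                    profile_length=int(fields[5]),
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: malformed domtblout line {lineno}: {exc}"
                ) from exc
            hits.append(hit)
    return hits


def write_domtblout(hits: Sequence[HmmHit], path) -> None:
    """Write hits as a minimal HMMER3-style per-domain table (round-trippable
    by :func:`parse_domtblout`)."""
    with open(path, "w") as handle:
        handle.write("# target name        accession   tlen query name           "
                     "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                     "i-Evalue  score  bias  from    to  from    to  from    to  acc description of target\n")
        handle.write("#" + "-" * 30 + "\n")
        for k, h in enumerate(hits, start=1):
            handle.write(
                f"{h.seq_id} - {h.seq_end} {h.profile} - {h.profile_length or h.profile_end} "
                f"{h.e_value:.3g} {h.bit_score:.2f} 0.0 1 1 {h.e_value:.3g} "
                f"{h.e_value!r} {h.bit_score!r} 0.0 "
                f"{h.profile_start + 1} {h.profile_end} "
                f"{h.seq_start + 1} {h.seq_end} "
                f"{h.seq_start + 1} {h.seq_end} 0.90 -\n"
            )
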