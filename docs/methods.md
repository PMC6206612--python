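# Methods

## Problem and overall model

Fungal ITS amplicons are sequenced with primers sitting in the conserved
rRNA genes, so each merged read is (up to sequencing error) a window over

    SSU tail · ITS1 · 5.8S · ITS2 · LSU head

where the flanks are strongly conserved across taxa and the spacers are
hypervariable in both sequence and length. Trimming to ITS1 or ITS2 means
locating the inner edges of the conserved flanks on each read. `itsclip`
does this with one profile HMM per flank, but scans only cluster
representatives and propagates their coordinates, exploiting the high
duplication of amplicon data. All coordinates are 0-based half-open
internally; 1-based inclusive conversion happens only at the HMMER
domain-table boundary.

## Pair merging

The reverse read is reverse-complemented and slid across the forward read;
every placement with overlap ≥ `min_overlap` (default 12 nt) and mismatch
rate ≤ `max_mismatch_rate` (default 0.25) is scored by its number of
matching bases, and the best placement wins (ties toward the longer
overlap, which favours full-length merging and is deterministic). Negative
placements (insert shorter than a read) are read-through: both overhangs
are clipped, so the merged length always equals the insert length.
Consensus rules: agreement gives `min(q1+q2, 41)`; disagreement keeps the
higher-quality base with quality `|q1−q2|`; quality ties keep the forward
base at quality 2; `N` never counts as a match and never wins. These
parameters are this package's own defaults — the published workflow this
follows delegates merging to BBMerge without printing its settings — and
byte-level equivalence with BBMerge is a non-goal. Posterior-probability
quality recomputation is deliberately not attempted; the capped-sum rule is
the whole model.

## Dereplication and greedy clustering

Identical sequences are collapsed with abundances and member id lists,
sorted by descending abundance (ties broken lexicographically so runs are
reproducible). Clustering is centroid-based first-fit in scan order: a
sequence joins the first representative (in creation order) whose identity
is at or above the threshold, else founds a new cluster. First-fit rather
than best-fit was chosen because it matches the greedy, abundance-ordered
behaviour of the VSEARCH family of tools and is O(n·k); a consequence is
that a later, heavier sequence may attach to an earlier, lighter
representative, so no abundance ordering within clusters is guaranteed
(only that representatives were founded in descending-abundance order).

Identity between two sequences is `(columns − edits) / columns` on a
minimum-edit-distance global alignment (edlib), terminal gaps included in
the denominator. Among co-optimal alignments the column count can differ
slightly; the value used is the one for the alignment edlib reports, and
the test suite verifies it is attained by some minimum-edit alignment
(exhaustive enumeration at short lengths). With this convention a 600 nt
pair differing by 3 substitutions has identity 597/600 = 0.995, exactly the
default threshold. The permitted threshold range is [0.98, 1.00]; at 1.00
clustering degenerates to exact dereplication and the whole pipeline equals
per-read trimming.

Before aligning, a shared 8-mer multiset bound screens candidate pairs: if
identity ≥ t then the edit distance is at most `2(1−t)·max(|a|,|b|)/(1+t)`
(since columns ≤ max length + d/2), and by the q-gram lemma a pair within
d edits shares at least `min(|a|,|b|) − k + 1 − k·d` k-mers. Pairs below
the bound cannot reach the threshold and are skipped; the bound is provably
lossless and the tests additionally assert that disabling it changes no
clustering.

## Flank profiles and boundary calling

### Profile construction

Profiles are estimated from gapped DNA multiple alignments: columns with
more than 50% gaps become insert states, the rest match states. Match
emissions, the pooled insert emission, and per-node transition
probabilities (M→M/I/D, I→M/I, D→M/D) are maximum-likelihood counts with an
additive pseudocount (default 0.5); groups with no observations fall back
to uniform. The background distribution is uniform (0.25 per base) — the
flanks' composition is close to uniform and a fixed background keeps bit
scores comparable across profiles.

### Local Viterbi

Scoring is log2-odds against background. A path enters any match state
M_j with cost log2(1/M) (uniform local entry), moves through
match/insert/delete states under the profile's transition probabilities,
and may exit after any match state at no cost — Smith–Waterman-style local
alignment over a profile, so the model is a scoring scheme rather than a
normalised generative model, as is standard for local sequence search. `N`
bases score 0 (odds-neutral) in every state. The Viterbi recursion is a
numba kernel with full traceback, giving the envelope on the read and on
the model. An exhaustive path-enumeration oracle verifies the kernel for
all profiles with M ≤ 4 on reads ≤ 6 nt.

### Significance and the F1/F3 heuristics

Each profile is calibrated once per run: Viterbi bit scores of 1,000 (400
nt) seeded background sequences are fitted with a maximum-likelihood Gumbel
(λ, μ), and `P(S ≥ s) = 1 − exp(−exp(−λ(s−μ)))` converts a score to a
per-sequence P-value. `HmmHit.e_value` stores this per-sequence P-value
(the expected count for a database of one); a hit is kept when it passes
F3 = 1e-6. The same machinery calibrates the prefilter statistic: the best
ungapped-diagonal sum of match log-odds (a Kadane scan over diagonals),
gated by F1 = 1e-6. The three-stage MSV/Viterbi/Forward cascade of full
HMMER is intentionally not reproduced — the thresholds, not the cascade
internals, define the behaviour — so F2 is accepted for interface
compatibility and ignored with a warning. The prefilter is conservative for
near-ungapped hits (real flank matches under substitution-dominated error);
a heavily indel-ed hit could in principle fail it, so the pipeline exposes
`--no-prefilter` as the maximally sensitive fallback, and the tests verify
on the bundled profiles that no prefilter-rejected read carries a passing
Viterbi hit. Calibration is length-specific (400 nt default, matching
typical merged amplicons); P-values for much longer reads are mildly
anti-conservative and the calibration length is configurable.

### From hits to trim coordinates

Per profile, the best hit (highest bit score, ties to the leftmost) is
kept. ITS1 spans from the end of the SSU-tail hit to the start of the
5.8S hit; ITS2 from the end of the 5.8S hit to the start of the LSU-head
hit; ALL from the SSU-tail end to the LSU-head start. Because local
alignment drops edge columns whose emission score is negative (e.g. a
diverged final flank base), the scored envelope can stop one or two model
columns short of the profile edge; the trim conversion therefore
extrapolates the missing columns as ungapped sequence
(`seq_end + (M − profile_end)`, symmetrically at the start), clipped to the
read. This keeps error-free trims exact instead of off by the number of
diverged edge bases. If exactly one relevant flank is found, the other
coordinate falls back to the read edge and the corresponding
`*_flank_found` flag is False, letting strict users filter; if neither
relevant flank is found, or the interval collapses, the read is excluded
with a logged reason.

## Trim propagation

The representative's (start, stop) applies unmodified to every member —
no re-alignment, by design, since this is exactly the behaviour that makes
clustering cheap: substitutions between a member and its representative
cannot move the trim point, while indels shift it by at most their summed
length, bounded by the identity threshold. `stop` is clipped to each
member's length; collapsed windows become `excluded_empty`. Accounting is
exact: every input read ends in exactly one of trimmed / excluded_no_hit /
excluded_empty / excluded_unmerged, asserted at run time and reported in
the log.

## Synthetic data

The simulator emulates a 2×300 bp MiSeq ITS run. Defaults: 8 taxa × 50
reads; flank lengths 50/155/50 nt (SSU tail / 5.8S / LSU head); spacer
lengths uniform in [120, 160] nt (so maximum insert 575 nt and paired
2×300 reads always overlap by ≥ 12 nt, checked at config validation);
taxon flank divergence 5% substitutions; per-base sequencing error 0.5%
substitutions; Phred qualities from a truncated normal (mean 35, sd 3,
clipped to [2, 41]).

Simplifications, deliberate and documented:

- Sequencing errors and taxon divergence are substitutions only, so truth
  coordinates live on the insert coordinate system unchanged. Real reads
  contain rare indels, which shift propagated trim points (that mechanism
  is exercised structurally by the clustering tests, not by the error
  model). Boundary-recovery results on this simulator are therefore an
  upper bound on real-data accuracy.
- Errors are independent of the quality string; the qualities exercise the
  consensus rules and I/O, not a realistic error-quality correlation.
- The bundled flank alignments are seeded synthetic families (12 sequences,
  5% divergence, two minority-gap columns so insert states are exercised) —
  generated, not copied from any rRNA database, keeping the repository
  self-contained and licence-clean. They mimic the conservation structure
  of real flanks but are not biological sequences: trimming real reads
  requires building profiles from real SSU/5.8S/LSU alignments via
  `itsclip build-profile`.

## Trim comparison

Identical strings are counted without aligning. Otherwise the two trimmed
products are globally aligned under affine gaps (match +2, mismatch −1,
gap open −0.5, gap extend −0.1; the first gap base costs the open penalty
only, later bases the extend penalty — the convention of the aligner the
published comparison used). Offsets are the signed overhangs at the
alignment ends (start offset = leading gaps in B's row minus A's; stop
offset = trailing gaps in A's row minus B's), so comparing B-to-A negates
both. The summary reports the fraction of reads within k bases at both
ends for k = 0, 1, 2, 5. Ties among co-optimal alignments are broken by
taking the first alignment in Biopython's deterministic enumeration; only
the gap placement, never the score, depends on this. When both trimmings
are on the same original coordinate system (simulator truth, outcome
tables), `compare_trim_tables` computes offsets exactly without aligning.

## Numerical and implementation choices

- Viterbi and prefilter kernels are numba-compiled; everything is
  single-threaded (`--threads` is accepted for familiarity and is a no-op).
- Gumbel survival uses `−expm1(−exp(−x))` for accuracy at both tails;
  strong hits underflow to P = 0, which is the intended "certain" case.
- Zero-probability transitions become −inf in log space; the kernels never
  select them.
- Determinism: all randomness (simulator, calibration) flows from explicit
  seeds through `numpy.random.default_rng`; identical seeds give
  byte-identical FASTQ outputs end to end, asserted in the tests.
- Problem sizes in the test and acceptance runs (2,000 reads for the
  clustering-equivalence check, 1,000 for boundary recovery, 500 uniques
  for clustering soundness, 1,000 background reads for prefilter
  conservativeness) were chosen as the smallest sets at which the measured
  fractions are stable to re-seeding.

## Known limitations

- The bundled profiles are synthetic; out of the box the tool trims its
  simulator's reads, not real fungal data (supply real flank alignments for
  that).
- One E-value calibration length per profile; no length correction.
- Greedy first-fit clustering is order-dependent by construction; results
  are reproducible but not invariant to abundance ties beyond the
  documented lexicographic tie-break.
- Paired output mode is out of scope: when pairs are consumed, the output
  is single merged trimmed records, matching the downstream
  sequence-variant use case.
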