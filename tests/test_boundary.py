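import math

import numpy as np
import pytest

from itsclip import boundary as bd

from conftest import random_dna


def _toy_profile(m=3, seed=5):
    """A small random (valid) profile for oracle comparisons."""
    rng = np.random.default_rng(seed)
    em = rng.dirichlet(np.ones(4), size=m)
    ins = rng.dirichlet(np.ones(4))
    if m > 1:
        mmd = rng.dirichlet(np.ones(3) * 5, size=m - 1)
        imi = rng.dirichlet(np.ones(2) * 5, size=m - 1)
        dmd = rng.dirichlet(np.ones(2) * 5, size=m - 1)
        transitions = {
            "mm": mmd[:, 0], "mi": mmd[:, 1], "md": mmd[:, 2],
            "im": imi[:, 0], "ii": imi[:, 1],
            "dm": dmd[:, 0], "dd": dmd[:, 1],
        }
    else:
        empty = np.zeros(0)
        transitions = {k: empty for k in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    return bd.ProfileHMM(
        name="SSU_tail", match_emissions=em, insert_emissions=ins, transitions=transitions
    )


def enumerate_viterbi(profile, read):
    """Exhaustive max over every legal local state path (M<=4, reads<=6)."""
    ms, ins, tr = profile._log_odds_tables()
    seq = bd.encode_sequence(read)
    L, M = len(seq), profile.length
    entry = -math.log2(M)
    best = -math.inf

    def extend(score, i, j, state):
        # state: current state just consumed/visited at node j, read pos i
        nonlocal best
        if state == "M":
            best = max(best, score)  # exit allowed after any match
        # transitions out of node j
        if state == "M":
            if j < M - 1:
                if i < L:
                    extend(score + tr[0, j] + ms[j + 1, seq[i]], i + 1, j + 1, "M")
                    extend(score + tr[1, j] + ins[seq[i]], i + 1, j, "I")
                extend(score + tr[2, j], i, j + 1, "D")
        elif state == "I":
            if i < L and j < M - 1:
                extend(score + tr[3, j] + ms[j + 1, seq[i]], i + 1, j + 1, "M")
                extend(score + tr[4, j] + ins[seq[i]], i + 1, j, "I")
        elif state == "D":
            if j < M - 1:
                if i < L:
                    extend(score + tr[5, j] + ms[j + 1, seq[i]], i + 1, j + 1, "M")
                extend(score + tr[6, j], i, j + 1, "D")

    for start in range(L):
        for j in range(M):
            extend(entry + ms[j, seq[start]], start + 1, j, "M")
    return best


class TestBuildProfile:
    def test_single_column_all_a_pseudocount_zero(self):
        profile = bd.build_profile(["A", "A"], pseudocount=0.0)
        assert profile.length == 1
        assert profile.match_emissions[0].tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_add_one_pseudocount_arithmetic(self):
        profile = bd.build_profile(["AC", "AC"], pseudocount=1.0)
        # 2 'A' observations + pseudocount 1 per base: A = 3/6, others 1/6
        assert profile.match_emissions[0] == pytest.approx([3 / 6, 1 / 6, 1 / 6, 1 / 6])

    def test_majority_gap_columns_become_insert_states(self):
        alignment = ["AC-G", "AC-G", "ACTG", "AC-G"]
        profile = bd.build_profile(alignment)
        assert profile.length == 3  # the mostly-gap column is an insert state

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            bd.build_profile([])

    def test_probability_invariants(self, flank_alignments):
        for name, aln in flank_alignments.items():
            profile = bd.build_profile(aln, name=name)
            assert np.allclose(profile.match_emissions.sum(axis=1), 1.0)
            for group in (("mm", "mi", "md"), ("im", "ii"), ("dm", "dd")):
                total = sum(profile.transitions[k] for k in group)
                assert np.allclose(total, 1.0)

    def test_serialization_round_trip(self, calibrated_profiles, tmp_path):
        for profile in calibrated_profiles:
            path = tmp_path / f"{profile.name.replace('.', '_')}.profile"
            profile.save(path)
            loaded = bd.ProfileHMM.load(path)
            assert loaded.name == profile.name
            assert np.allclose(loaded.match_emissions, profile.match_emissions)
            assert loaded.calibration == pytest.approx(profile.calibration)
            assert loaded.prefilter_calibration == pytest.approx(
                profile.prefilter_calibration
            )


class TestViterbiOracle:
    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_matches_exhaustive_path_enumeration(self, m, rng):
        profile = _toy_profile(m=m, seed=m)
        for _ in range(30):
            read = random_dna(rng, int(rng.integers(1, 7)))
            expected = enumerate_viterbi(profile, read)
            got = bd.viterbi_score(profile, read)
            assert got == pytest.approx(expected, abs=1e-9), (m, read)

    def test_consensus_self_hit_spans_profile(self, calibrated_profiles):
        for profile in calibrated_profiles:
            consensus = "".join(
                "ACGT"[i] for i in profile.match_emissions.argmax(axis=1)
            )
            hit = bd.viterbi_local(profile, consensus)
            assert hit is not None
            assert hit.bit_score > 0
            assert (hit.profile_start, hit.profile_end) == (0, profile.length)
            assert (hit.seq_start, hit.seq_end) == (0, profile.length)

    def test_background_read_rejected_at_default_f3(self, calibrated_profiles, rng):
        for profile in calibrated_profiles:
            for _ in range(10):
                read = random_dna(rng, 400)
                assert bd.viterbi_local(profile, read) is None

    def test_lowering_f3_never_adds_hits(self, calibrated_profiles, rng):
        reads = [random_dna(rng, 300) for _ in range(50)]
        profile = calibrated_profiles[0]
        loose = bd.HeuristicThresholds(f3=1e-2)
        strict = bd.HeuristicThresholds(f3=1e-8)
        for read in reads:
            if bd.viterbi_local(profile, read, thresholds=strict) is not None:
                assert bd.viterbi_local(profile, read, thresholds=loose) is not None


class TestCalibration:
    def test_top_background_score_has_unit_expected_count(self, calibrated_profiles):
        """E = n * P(S >= max of n calibration draws) should be ~1."""
        for profile in calibrated_profiles:
            n = 400
            rng = np.random.default_rng(77)
            seqs = bd.random_background_sequences(profile, n, 400, rng)
            scores = [bd.viterbi_score(profile, s) for s in seqs]
            expected_count = n * bd.gumbel_pvalue(max(scores), profile.calibration)
            assert 0.02 < expected_count < 12

    def test_pvalue_monotone_decreasing_in_score(self, calibrated_profiles):
        profile = calibrated_profiles[0]
        ps = [bd.gumbel_pvalue(s, profile.calibration) for s in (0.0, 5.0, 20.0, 60.0)]
        assert ps == sorted(ps, reverse=True)


class TestPrefilter:
    def test_consensus_passes(self, calibrated_profiles):
        for profile in calibrated_profiles:
            consensus = "".join(
                "ACGT"[i] for i in profile.match_emissions.argmax(axis=1)
            )
            assert bd.prefilter(profile, consensus)

    def test_f1_of_one_always_passes(self, calibrated_profiles, rng):
        thresholds = bd.HeuristicThresholds(f1=1.0)
        profile = calibrated_profiles[0]
        for _ in range(20):
            assert bd.prefilter(profile, random_dna(rng, 200), thresholds)

    def test_conservative_against_full_viterbi(self, calibrated_profiles, rng):
        """prefilter(x) False must imply viterbi_local(x) is None (f3=1e-6)."""
        reads = [random_dna(rng, 300) for _ in range(300)]
        for profile in calibrated_profiles:
            for read in reads:
                if not bd.prefilter(profile, read):
                    assert bd.viterbi_local(profile, read) is None

    def test_f2_warns_and_is_ignored(self):
        with pytest.warns(UserWarning, match="f2"):
            bd.HeuristicThresholds(f2=1e-3)


class TestCallBoundaries:
    def _hit(self, profile, start, end, score=50.0, plen=0, pstart=0, pend=None):
        return bd.HmmHit(
            profile=profile, seq_id="s", seq_start=start, seq_end=end,
            profile_start=pstart, profile_end=pend if pend is not None else end - start,
            bit_score=score, e_value=0.0, profile_length=plen,
        )

    def test_its1_between_ssu_and_58s(self):
        hits = [self._hit("SSU_tail", 0, 42), self._hit("R5.8S", 260, 400)]
        call = bd.call_boundaries(hits, "ITS1", 500)
        assert (call.start, call.stop) == (42, 260)
        assert call.left_flank_found and call.right_flank_found

    def test_no_hits_excludes_read(self):
        assert bd.call_boundaries([], "ITS1", 500) is None

    def test_single_flank_falls_back_to_read_edge(self):
        call = bd.call_boundaries([self._hit("SSU_tail", 0, 42)], "ITS1", 500)
        assert (call.start, call.stop) == (42, 500)
        assert call.left_flank_found and not call.right_flank_found
        call = bd.call_boundaries([self._hit("R5.8S", 260, 400)], "ITS1", 500)
        assert (call.start, call.stop) == (0, 260)
        assert not call.left_flank_found and call.right_flank_found

    def test_collapsed_interval_excluded(self):
        hits = [self._hit("SSU_tail", 0, 300), self._hit("R5.8S", 100, 200)]
        assert bd.call_boundaries(hits, "ITS1", 400) is None

    def test_envelope_edges_extrapolated_to_full_profile(self):
        # SSU envelope stops 2 model columns short; trim point extends by 2
        left = self._hit("SSU_tail", 0, 40, plen=50, pstart=0, pend=48)
        right = self._hit("R5.8S", 262, 400, plen=155, pstart=2, pend=140)
        call = bd.call_boundaries([left, right], "ITS1", 500)
        assert (call.start, call.stop) == (42, 260)

    def test_best_hit_per_profile_ties_leftmost(self):
        a = self._hit("SSU_tail", 10, 52, score=30.0)
        b = self._hit("SSU_tail", 5, 47, score=30.0)
        call = bd.call_boundaries([a, b], "ITS1", 500)
        assert call.start == 47  # leftmost of the tied hits wins

    def test_regions_use_their_flanks(self):
        hits = [
            self._hit("SSU_tail", 0, 50),
            self._hit("R5.8S", 200, 355),
            self._hit("LSU_head", 500, 550),
        ]
        assert bd.call_boundaries(hits, "ITS1", 550).stop == 200
        its2 = bd.call_boundaries(hits, "ITS2", 550)
        assert (its2.start, its2.stop) == (355, 500)
        allr = bd.call_boundaries(hits, "ALL", 550)
        assert (allr.start, allr.stop) == (50, 500)


class TestSimulatedBoundaryRecovery:
    def test_error_free_reads_recover_exact_boundaries(
        self, clean_simulation, calibrated_profiles
    ):
        truth = {t.read_id: t for t in clean_simulation.truth}
        for read in clean_simulation.reads[::5]:
            hits = bd.scan_read(calibrated_profiles, read.sequence, read.id)
            t = truth[read.id]
            its1 = bd.call_boundaries(hits, "ITS1", len(read.sequence))
            assert (its1.start, its1.stop) == (t.its1_start, t.its1_stop)
            its2 = bd.call_boundaries(hits, "ITS2", len(read.sequence))
            assert (its2.start, its2.stop) == (t.its2_start, t.its2_stop)

    def test_noisy_reads_within_two_bases(self, small_simulation, calibrated_profiles):
        truth = {t.read_id: t for t in small_simulation.truth}
        called = 0
        for read in small_simulation.reads[::10]:
            hits = bd.scan_read(calibrated_profiles, read.sequence, read.id)
            call = bd.call_boundaries(hits, "ITS1", len(read.sequence))
            if call is None:
                continue
            called += 1
            t = truth[read.id]
            assert abs(call.start - t.its1_start) <= 2
            assert abs(call.stop - t.its1_stop) <= 2
        assert called > 0


class TestDomtblout:
    def _hits(self):
        return [
            bd.HmmHit(
                profile="SSU_tail", seq_id="rep1", seq_start=42, seq_end=260,
                profile_start=0, profile_end=50, bit_score=55.25, e_value=1.5e-20,
                profile_length=50,
            ),
            bd.HmmHit(
                profile="R5.8S", seq_id="rep2", seq_start=0, seq_end=155,
                profile_start=3, profile_end=155, bit_score=140.0, e_value=0.0,
                profile_length=155,
            ),
        ]

    def test_coordinate_shift_one_based_inclusive(self, tmp_path):
        path = tmp_path / "hits.domtbl"
        bd.write_domtblout(self._hits(), path)
        parsed = bd.parse_domtblout(path)
        assert parsed[0].seq_start == 42 and parsed[0].seq_end == 260
        # the env-from field on disk is 1-based inclusive
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        assert line.split()[19] == "43" and line.split()[20] == "260"

    def test_comment_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.domtbl"
        path.write_text("# nothing here\n#\n")
        assert bd.parse_domtblout(path) == []

    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "rt.domtbl"
        hits = self._hits()
        bd.write_domtblout(hits, path)
        assert bd.parse_domtblout(path) == hits

    def test_malformed_line_fatal_with_line_number(self, tmp_path):
        path = tmp_path / "bad.domtbl"
        path.write_text("only three fields here\n")
        with pytest.raises(ValueError, match="line 1"):
            bd.parse_domtblout(path)

    def test_profile_name_mapping(self, tmp_path):
        path = tmp_path / "map.domtbl"
        hits = self._hits()
        bd.write_domtblout(hits, path)
        parsed = bd.parse_domtblout(path, profile_names={"SSU_tail": "SSU_tail_v2"})
        assert parsed[0].profile == "SSU_tail_v2"
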