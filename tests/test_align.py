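import numpy as np
import pytest

from _oracles import realign_score, sw_oracle_score
from repforge.align import (
    ScoringScheme,
    SegmentAlignment,
    _fill,
    _fill_py,
    _encode,
    assign_segments,
    call_isotype,
    migrate_boundary,
    smith_waterman,
)
from repforge.germline import GermlineDatabase, GermlineSegment
from repforge.simulate import SimulationConfig, simulate_repertoire


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestSmithWaterman:
    def test_identity(self):
        aln = smith_waterman("ACGT", "ACGT")
        assert aln.score == 8
        assert aln.operations == (("M", 4),)
        assert aln.mismatch_positions == ()

    def test_all_mismatch_yields_empty_alignment(self):
        aln = smith_waterman("AAAA", "TTTT")
        assert aln.score == 0 and aln.operations == ()

    def test_substitution_beats_shorter_exact_match(self):
        # full-length alignment with one substitution (7*2 - 2 = 12) beats
        # the exact 4-mer (8)
        aln = smith_waterman("ACGTACGT", "ACGAACGT")
        assert aln.score == 12
        assert aln.mismatch_positions == (3,)

    def test_n_never_matches(self):
        assert smith_waterman("NNNN", "NNNN").score == 0
        aln = smith_waterman("ACNGT", "ACAGT")
        # N counts as mismatch: 4*2 - 2 = 6
        assert aln.score == 6

    def test_gap_scoring_affine(self):
        # deleting 2 bases from the query: 8 matches, one gap of length 2
        aln = smith_waterman("AAAACCCC", "AAAAGGAACCCC")
        assert realign_score(aln, "AAAACCCC", "AAAAGGAACCCC") == aln.score

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_recursive_oracle_on_short_strings(self, trial):
        rng = np.random.default_rng(1000 + trial)
        a = _random_seq(rng, int(rng.integers(1, 11)))
        b = _random_seq(rng, int(rng.integers(1, 11)))
        aln = smith_waterman(a, b)
        assert aln.score == sw_oracle_score(a, b)
        if aln.operations:
            assert realign_score(aln, a, b) == aln.score

    def test_score_symmetry_under_symmetric_scoring(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = _random_seq(rng, int(rng.integers(1, 12)))
            b = _random_seq(rng, int(rng.integers(1, 12)))
            assert smith_waterman(a, b).score == smith_waterman(b, a).score

    def test_pure_python_fill_agrees_with_active_kernel(self):
        rng = np.random.default_rng(3)
        a, b = _encode(_random_seq(rng, 40)), _encode(_random_seq(rng, 35))
        for fa, fb in zip(_fill(a, b, 2, -2, -3, -1), _fill_py(a, b, 2, -2, -3, -1)):
            assert np.array_equal(fa, fb)


class TestMigrateBoundary:
    def test_ungapped_offset_arithmetic(self):
        aln = SegmentAlignment("x", 200, (0, 100), (10, 110), (("M", 100),), ())
        assert migrate_boundary(aln, 40) == 30

    def test_deletion_before_position_shifts_by_deletion_length(self):
        ops = (("M", 20), ("D", 2), ("M", 78))
        aln = SegmentAlignment("x", 0, (0, 98), (10, 110), ops, ())
        assert migrate_boundary(aln, 40) == 28  # 2 less than the ungapped 30

    def test_position_inside_deletion_maps_just_3prime(self):
        ops = (("M", 20), ("D", 2), ("M", 78))
        aln = SegmentAlignment("x", 0, (0, 98), (10, 110), ops, ())
        assert migrate_boundary(aln, 31) == 20

    def test_out_of_range_is_absent(self):
        aln = SegmentAlignment("x", 0, (0, 100), (10, 110), (("M", 100),), ())
        assert migrate_boundary(aln, 5) is None
        assert migrate_boundary(aln, 110) is None


def _simulated_read(igh_db, seed=0, **kw):
    cfg = SimulationConfig(seed=seed, n_clones=1, **kw)
    [truth] = simulate_repertoire(cfg, igh_db)
    return truth


class TestAssignSegments:
    def test_clean_simulated_read_gets_exact_calls(self, igh_db):
        t = _simulated_read(igh_db, seed=123, isotype_mixture={"IgG1": 1.0})
        calls = assign_segments(t.amplicon, igh_db, "IGH")
        assert calls is not None
        assert calls.v.segment_id == t.v_id
        assert calls.j.segment_id == t.j_id
        assert calls.isotype == "IgG1"
        assert call_isotype(calls) == "IgG1"

    def test_read_coordinate_ordering_of_calls(self, igh_db):
        t = _simulated_read(igh_db, seed=5)
        calls = assign_segments(t.amplicon, igh_db, "IGH")
        starts = [calls.v.query_interval[0], calls.j.query_interval[0]]
        if calls.d:
            starts.insert(1, calls.d.query_interval[0])
        if calls.c:
            starts.append(calls.c.query_interval[0])
        assert starts == sorted(starts)

    def test_bare_constant_read_is_unassignable(self, igh_db):
        c_seq = igh_db.get("IGHC-IgM").sequence
        assert assign_segments(c_seq, igh_db, "IGH") is None

    def test_duplicated_v_alleles_tie_break_lexicographically(self, igh_db):
        v = igh_db.get("IGHV1-tst")
        j = igh_db.get("IGHJ1-tst")
        c = igh_db.get("IGHC-IgM")
        segs = [
            GermlineSegment("IGHV1-a", "IGH", "V", v.sequence, v.cdr2_start, v.cdr3_anchor),
            GermlineSegment("IGHV1-b", "IGH", "V", v.sequence, v.cdr2_start, v.cdr3_anchor),
            j,
            c,
        ]
        db = GermlineDatabase.from_segments(segs)
        read = v.sequence + "ACAC" + j.sequence + c.sequence
        calls = assign_segments(read, db, "IGH")
        assert calls.v.segment_id == "IGHV1-a"

    def test_shared_constant_prefix_ties_flag_ambiguity(self, igh_db):
        # a read covering only the 20 nt the IgG2b/IgG2c constants share
        v = igh_db.get("IGHV1-tst")
        j = igh_db.get("IGHJ1-tst")
        shared = igh_db.get("IGHC-IgG2b").sequence[:20]
        assert shared == igh_db.get("IGHC-IgG2c").sequence[:20]
        read = v.sequence + "AC" + j.sequence + shared
        calls = assign_segments(read, igh_db, "IGH")
        assert calls.isotype == "IgG2b"  # lexicographically first of the tie
        assert calls.c_ambiguous

    def test_trb_isotype_label(self, trb_db):
        cfg = SimulationConfig(seed=9, n_clones=1, locus="TRB")
        [t] = simulate_repertoire(cfg, trb_db)
        calls = assign_segments(t.amplicon, trb_db, "TRB")
        assert calls.isotype == "TRBC"


class TestAssignmentAccuracy:
    def test_error_free_assignment_is_perfect(self, igh_db):
        cfg = SimulationConfig(seed=21, n_clones=60)
        truth = simulate_repertoire(cfg, igh_db)
        for t in truth:
            calls = assign_segments(t.amplicon, igh_db, "IGH")
            assert (calls.v.segment_id, calls.j.segment_id, calls.isotype) == (
                t.v_id,
                t.j_id,
                t.isotype,
            )

    def test_v_accuracy_under_shm(self, igh_db):
        cfg = SimulationConfig(seed=22, n_clones=120, shm_rate_per_base=0.02)
        truth = simulate_repertoire(cfg, igh_db)
        v_ok = j_ok = c_ok = 0
        for t in truth:
            calls = assign_segments(t.amplicon, igh_db, "IGH")
            v_ok += calls.v.segment_id == t.v_id
            j_ok += calls.j.segment_id == t.j_id
            c_ok += calls.isotype == t.isotype
        n = len(truth)
        assert v_ok / n >= 0.95
        assert j_ok / n >= 0.99 and c_ok / n >= 0.99


def test_scoring_scheme_rejects_bad_signs():
    with pytest.raises(ValueError):
        ScoringScheme(match=0)
    with pytest.raises(ValueError):
        ScoringScheme(mismatch=1)
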