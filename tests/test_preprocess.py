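import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repforge.preprocess import (
    MergedSequence,
    MergeFailure,
    SequencingRead,
    collapse_duplicates,
    demultiplex,
    merge_pair,
    quality_trim,
    reverse_complement,
)


def _read(seq, quals=None, rid="r1", mate="R1"):
    if quals is None:
        quals = (35,) * len(seq)
    return SequencingRead(rid, seq, tuple(quals), mate)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestDemultiplex:
    def _pairs(self, prefixes, payload="ACGTACGTACGT"):
        return [
            (_read(payload, rid=f"p{i}"), _read(p + payload, rid=f"p{i}", mate="R2"))
            for i, p in enumerate(prefixes)
        ]

    def test_exact_prefix_assigned_and_stripped(self):
        res = demultiplex(self._pairs(["ACGTAC"]), {"ACGTAC": "s1"}, max_mismatch=0)
        assert res.counts == {"input": 1, "assigned": 1, "unassigned": 0, "ambiguous": 0}
        _, r2 = res.by_sample["s1"][0]
        assert r2.sequence == "ACGTACGTACGT"

    def test_one_mismatch_rejected_at_zero_tolerance(self):
        res = demultiplex(self._pairs(["ACGTAA"]), {"ACGTAC": "s1"}, max_mismatch=0)
        assert res.counts["unassigned"] == 1 and not res.by_sample["s1"]

    def test_nearest_unique_barcode_wins_within_tolerance(self):
        # "AAAATG": distance 2 to AAAAAA, 1 to AAAATT -> uniquely assigned
        table = {"AAAAAA": "s1", "AAAATT": "s2"}
        res = demultiplex(self._pairs(["AAAATG"]), table, max_mismatch=1)
        assert len(res.by_sample["s2"]) == 1 and res.counts["ambiguous"] == 0

    def test_equidistant_prefix_is_ambiguous(self):
        # "AAAAAT": distance 1 to both barcodes -> unassigned, counted ambiguous
        table = {"AAAAAA": "s1", "AAAATT": "s2"}
        res = demultiplex(self._pairs(["AAAAAT"]), table, max_mismatch=1)
        assert res.counts["ambiguous"] == 1 and res.counts["unassigned"] == 1

    @given(st.lists(st.sampled_from(["AACCGG", "AACCGT", "TTGGCC", "NNNNNN"]), max_size=20))
    @settings(deadline=None)
    def test_conservation_for_any_input(self, prefixes):
        table = {"AACCGG": "s1", "TTGGCC": "s2"}
        res = demultiplex(self._pairs(prefixes), table, max_mismatch=1)
        assigned = sum(len(v) for v in res.by_sample.values())
        assert assigned + len(res.unassigned) == len(prefixes)
        assert res.counts["assigned"] + res.counts["unassigned"] == res.counts["input"]


class TestQualityTrim:
    @pytest.mark.parametrize(
        "quals, kept",
        [
            ((30, 30, 30, 30), 4),  # no failing window
            ((30, 30, 30, 10, 30), 2),  # first failing window starts at index 2
            ((10, 30, 30), 0),  # failing window at index 0
            ((30, 30, 10), 1),  # last valid window start is len - window
            ((30,), 1),  # shorter than the window: untouched
        ],
    )
    def test_stated_rule(self, quals, kept):
        out = quality_trim(_read("A" * len(quals), quals), window=2, qmin=20)
        assert len(out) == kept

    @given(st.lists(st.integers(0, 41), min_size=0, max_size=60))
    @settings(deadline=None)
    def test_idempotent(self, quals):
        r = _read("A" * len(quals), quals)
        once = quality_trim(r)
        twice = quality_trim(once)
        assert once.sequence == twice.sequence and once.qualities == twice.qualities


class TestMergePair:
    def test_exact_reconstruction_of_400bp_amplicon(self):
        rng = np.random.default_rng(0)
        amp = _random_seq(rng, 400)
        r1 = _read(amp[:250])
        r2 = _read(reverse_complement(amp[150:]), mate="R2")
        m = merge_pair(r1, r2, min_overlap=10)
        assert isinstance(m, MergedSequence)
        assert m.sequence == amp and m.overlap_length == 100

    def test_single_substitution_in_overlap_discards(self):
        rng = np.random.default_rng(1)
        amp = _random_seq(rng, 400)
        r1 = _read(amp[:250])
        tail = list(amp[150:])
        tail[50] = "A" if tail[50] != "A" else "C"  # inside the 100 nt overlap
        r2 = _read(reverse_complement("".join(tail)), mate="R2")
        m = merge_pair(r1, r2, min_overlap=10)
        assert m == MergeFailure("mismatch")

    def test_short_chance_overlap_is_reported_as_short(self):
        r1 = _read("C" * 50 + "ACGT")
        r2 = _read(reverse_complement("ACGT" + "G" * 50), mate="R2")
        m = merge_pair(r1, r2, min_overlap=10)
        assert m == MergeFailure("short_overlap")

    def test_n_in_overlap_forces_discard(self):
        amp = "ACGT" * 20
        r1 = _read(amp[:50])
        tail = amp[20:].replace("A", "N", 1)
        r2 = _read(reverse_complement(tail), mate="R2")
        assert isinstance(merge_pair(r1, r2, min_overlap=10), MergeFailure)

    def test_error_free_population_reconstructs_and_mutated_discards(self):
        rng = np.random.default_rng(42)
        ok, bad = 0, 0
        for _ in range(50):
            amp = _random_seq(rng, 380)
            r1 = _read(amp[:250])
            r2 = _read(reverse_complement(amp[-250:]), mate="R2")
            if (
                isinstance(m := merge_pair(r1, r2), MergedSequence)
                and m.sequence == amp
            ):
                ok += 1
            pos = int(rng.integers(140, 240))  # inside overlap [130, 250)
            mut = list(amp)
            mut[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[pos]]
            r2m = _read(reverse_complement("".join(mut)[-250:]), mate="R2")
            if merge_pair(r1, r2m) == MergeFailure("mismatch"):
                bad += 1
        assert ok == 50 and bad == 50


class TestCollapseDuplicates:
    def _merged(self, seq, rid):
        return MergedSequence(rid, seq, 100, rid)

    def test_identical_strings_collapse_with_count(self):
        out = collapse_duplicates([self._merged("AAAA", f"r{i}") for i in range(7)])
        assert len(out) == 1 and out[0].copy_count == 7
        assert out[0].representative_id == "r0"

    def test_conservation_and_grouping(self):
        items = [self._merged("A" * 8, f"a{i}") for i in range(5)]
        items += [self._merged("C" * 8, f"b{i}") for i in range(4)]
        out = collapse_duplicates(items)
        assert [u.copy_count for u in out] == [5, 4]
        assert sum(u.copy_count for u in out) == 9

    def test_empty_input(self):
        assert collapse_duplicates([]) == []

    @given(st.lists(st.sampled_from(["AAAA", "CCCC", "GGGG"]), max_size=30))
    @settings(deadline=None)
    def test_order_independent_and_conserving(self, seqs):
        items = [self._merged(s, f"r{i:03d}") for i, s in enumerate(seqs)]
        fwd = collapse_duplicates(items)
        rev = collapse_duplicates(items[::-1])
        assert fwd == rev
        assert sum(u.copy_count for u in fwd) == len(seqs)
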