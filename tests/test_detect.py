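"""Detection tests: dot-plot oracle equivalence, array inference, delimitation."""
import numpy as np
import pytest

from its2repeats.detect import (
    delimit_units,
    extract_units,
    find_repeat_array,
    infer_array,
    inverted_content,
    self_dotplot,
)
from its2repeats.records import SpacerRecord, reverse_complement
from its2repeats.simulate import barbirostris_like_config, generate_dataset

from conftest import random_seq


def bruteforce_exact_matches(seq, min_len):
    """All-offset exact self-match oracle: maximal runs per diagonal."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(seq)
    out = set()
    for d in range(1, n):
        eq = raw[: n - d] == raw[d:]
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_len:
                out.add((d, int(s), int(e - s)))
    return out


class TestSelfDotplot:
    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            self_dotplot("")

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            self_dotplot("ACGT" * 50, word_size=3)
        with pytest.raises(ValueError):
            self_dotplot("ACGT" * 50, word_size=11, min_match_length=10)

    def test_random_sequence_has_no_long_matches(self, rng):
        seq = random_seq(rng, 500)
        assert bruteforce_exact_matches(seq, 30) == set()
        assert self_dotplot(seq, min_identity=1.0) == []

    def test_exact_triple_repeat_offsets(self, rng):
        x = random_seq(rng, 100)
        seq = x + x + x
        matches = self_dotplot(seq, min_identity=1.0)
        got = {(m.offset, m.start, m.length) for m in matches}
        assert got == bruteforce_exact_matches(seq, 30)
        assert {m.offset for m in matches} == {100, 200}
        by_offset = {m.offset: m for m in matches}
        assert by_offset[100].length == 200  # run extends across the array
        assert by_offset[200].length == 100

    def test_thirty_bp_floor_excludes_short_duplicates(self, rng):
        dup = random_seq(rng, 25)
        seq = random_seq(rng, 200) + dup + random_seq(rng, 200) + dup + random_seq(rng, 50)
        assert self_dotplot(seq, min_identity=1.0) == []
        # the same duplicate is found once the floor drops below its length
        assert any(
            m.length >= 25 for m in self_dotplot(seq, word_size=11, min_match_length=25,
                                                 min_identity=1.0)
        )

    def test_raising_floor_never_adds_matches(self, rng):
        x = random_seq(rng, 120)
        seq = random_seq(rng, 80) + x + x + random_seq(rng, 60) + x[:45]
        counts = [
            len(self_dotplot(seq, min_match_length=floor))
            for floor in (30, 40, 60, 90, 130)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_reported_identity_verifies_by_direct_comparison(self, fig1_dataset):
        _, records, _ = fig1_dataset
        seq = records[0].sequence
        for m in self_dotplot(seq):
            a = seq[m.start : m.start + m.length]
            b = seq[m.start + m.offset : m.start + m.offset + m.length]
            ident = sum(x == y for x, y in zip(a, b)) / m.length
            assert ident == pytest.approx(m.identity)
            assert ident >= 0.7 and m.length >= 30


class TestInferArray:
    def test_exact_tandem_triple(self, rng):
        x = random_seq(rng, 100)
        seq = random_seq(rng, 50) + x * 3 + random_seq(rng, 50)
        cand = infer_array(self_dotplot(seq, min_identity=1.0), seq)
        assert cand is not None
        assert cand.period == 100
        assert cand.start == pytest.approx(50, abs=3)
        assert cand.end - cand.start == pytest.approx(300, abs=5)

    def test_dispersed_duplicates_yield_no_array(self, rng):
        x = random_seq(rng, 80)
        seq = random_seq(rng, 30) + x + random_seq(rng, 400) + x + random_seq(rng, 30)
        assert infer_array(self_dotplot(seq, min_identity=1.0), seq) is None

    def test_no_matches_yield_no_array(self, rng):
        assert infer_array([], random_seq(rng, 100)) is None

    def test_a1_like_period_near_unit_length(self):
        """Period estimates on ten-unit arrays track the planted unit length."""
        found = 0
        for seed in range(10):
            records, truth = generate_dataset(barbirostris_like_config(seed=seed))
            rec = records[0]
            t = truth.records["A1"]
            unit_len = np.mean([u.end - u.start for u in t.units])
            cand = infer_array(self_dotplot(rec.sequence), rec.sequence)
            if cand is not None:
                found += 1
                assert abs(cand.period - unit_len) <= 5
        assert found >= 5


def make_exact_array(rng, n_units=3, interior=90):
    unit = "GGGTG" + random_seq(rng, interior) + "CACCC"
    pre, post = random_seq(rng, 60), random_seq(rng, 60)
    seq = pre + unit * n_units + post
    return seq, unit, (60, 60 + len(unit) * n_units)


class TestDelimitUnits:
    def test_exact_array_cut_at_motifs(self, rng):
        seq, unit, span = make_exact_array(rng)
        array = delimit_units(seq, span, 100)
        assert len(array.units) == 3
        assert all(len(u) == 100 for u in array.units)
        assert all(u.boundary == "motif" for u in array.units)

    def test_mutated_motif_falls_back_to_periodic_cut(self, rng):
        seq, unit, span = make_exact_array(rng)
        # destroy the 5' motif of the middle unit
        s = list(seq)
        s[160:165] = "TTTTT"
        seq = "".join(s)
        array = delimit_units(seq, span, 100)
        assert len(array.units) == 3
        assert array.units[1].boundary == "periodic"

    def test_span_shorter_than_period_rejected(self, rng):
        seq, _, _ = make_exact_array(rng)
        with pytest.raises(ValueError):
            delimit_units(seq, (60, 120), 100)

    def test_a3_like_truncated_units_recovered(self, fig1_dataset, fig1_arrays):
        _, _, truth = fig1_dataset
        array = fig1_arrays["A3"]
        t = truth.records["A3"]
        assert len(array.units) == 3
        for unit, tu in zip(array.units, t.units):
            assert abs(len(unit) - (tu.end - tu.start)) <= 3


class TestExtractUnits:
    def test_naming_follows_species_and_order(self, fig1_arrays):
        names = [u.name for u in fig1_arrays["A1"].units]
        assert names == [f"A1-{i}" for i in range(1, 11)]

    def test_single_unit_array(self, rng):
        seq, unit, _ = make_exact_array(rng, n_units=2)
        record = SpacerRecord(id="zz", sequence=seq, species_code="zz")
        array = find_repeat_array(record)
        assert array.units[0].name == "zz-1"

    def test_concatenated_units_reproduce_span(self, fig1_dataset, fig1_arrays):
        _, records, _ = fig1_dataset
        for rec in records:
            array = fig1_arrays[rec.id]
            joined = "".join(u.sequence for u in array.units)
            assert joined == rec.sequence[array.start : array.end]


class TestFindRepeatArray:
    def test_recovers_planted_arrays(self, fig1_dataset, fig1_arrays):
        _, records, truth = fig1_dataset
        for rec in records:
            array = fig1_arrays[rec.id]
            t = truth.records[rec.id]
            assert len(array.units) == len(t.units)
            for u, tu in zip(array.units, t.units):
                assert abs(u.start - tu.start) <= 5 and abs(u.end - tu.end) <= 5

    def test_repeat_free_record_yields_none(self, rng):
        record = SpacerRecord(id="bare", sequence=random_seq(rng, 800))
        assert find_repeat_array(record) is None


class TestInvertedContent:
    def test_perfect_palindrome_single_stem(self):
        report = inverted_content("AAAATTTT", min_stem=4)
        assert len(report.stems) == 1
        s = report.stems[0]
        assert (s.start1, s.end1, s.start2, s.end2) == (0, 4, 4, 8)
        assert report.score == 1.0

    def test_homopolymer_has_no_stems(self):
        assert inverted_content("A" * 40, min_stem=4).stems == []

    def test_planted_hairpin_found(self, rng):
        arm = random_seq(rng, 20)
        seq = arm + random_seq(rng, 15) + reverse_complement(arm)
        report = inverted_content(seq, min_stem=10)
        assert any(s.length >= 20 for s in report.stems)

    def test_min_stem_validated(self):
        with pytest.raises(ValueError):
            inverted_content("ACGTACGT", min_stem=2)

    def test_stems_verify_as_reverse_complements(self, fig1_units):
        unit = fig1_units[0]
        report = inverted_content(unit.sequence, min_stem=5)
        for s in report.stems:
            arm1 = unit.sequence[s.start1 : s.end1]
            arm2 = unit.sequence[s.start2 : s.end2]
            assert arm1 == reverse_complement(arm2)
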