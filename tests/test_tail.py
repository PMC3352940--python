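"""Tail-character parsing, encoding, mapping, and classification."""

import math

import pytest

import morphpars as mp
from morphpars.matrix import INAPPLICABLE, MISSING
from morphpars.tail import (
    Bound,
    TailError,
    TailRecord,
    parse_tail_table,
    parse_value,
    restrict_tree,
)


def _by_taxon(records):
    return {r.taxon: r for r in records}


class TestParsing:
    def test_empty_table(self):
        assert parse_tail_table("") == []

    def test_value_tokens(self):
        assert parse_value("-") is INAPPLICABLE
        assert parse_value("?") is None
        assert parse_value("11") == Bound(11, 11)
        assert parse_value(">10") == Bound(11, math.inf)
        assert parse_value("24-26") == Bound(24, 26)
        assert parse_value("28-20") == Bound(20, 28)  # normalized
        assert parse_value("36 (+4)") == Bound(40, 40)
        assert parse_value("22 (+3 to 8)") == Bound(25, 30)
        assert parse_value("22 (+5?)") == Bound(22, 27)
        assert parse_value("approx. 30") == Bound(30, 30, approx=True)
        assert parse_value(">8*") == Bound(9, math.inf)

    def test_malformed_token_reports_row(self):
        text = "taxon\tgroup\tNC\tTP\tE\tPZ\tC\t2x\tTrPt\nBad\tX\tfoo\t1\t1\t-\t-\tNo\tNo\n"
        with pytest.raises(TailError, match="Bad"):
            parse_tail_table(text)

    def test_study_rows_transcribed(self, tail_records):
        recs = _by_taxon(tail_records)
        dein = recs["Deinonychus antirrhopus"]
        assert dein.nc == Bound(40, 40)
        assert dein.tp == Bound(10, 10)
        assert dein.e == Bound(9, 9)
        assert dein.pz == Bound(11, math.inf)
        assert dein.c == Bound(8, 8)
        assert dein.twofold is False and dein.trpt is True
        micro = recs["Microraptor zhaoianus"]
        assert micro.nc == Bound(24, 26)
        assert (micro.tp, micro.e, micro.pz, micro.c) == (
            Bound(6, 6), Bound(6, 6), Bound(6, 6), Bound(3, 3),
        )
        assert micro.twofold is True

    def test_contact_beyond_contributor_rejected(self):
        with pytest.raises(TailError, match="caudal"):
            TailRecord("x", "g", pz=Bound(5, 5), c=Bound(7, 7))


class TestEncoding:
    def test_unenlagiine_scored_acaudothecate(self, tail_records):
        m = mp.encode_tail_characters(tail_records)
        row = m.row("Buitreraptor gonzalezorum")
        assert row[0] == frozenset({0})

    def test_hemicaudotheca_injected_from_side_table(self, tail_records):
        m = mp.encode_tail_characters(
            tail_records, extra_states=mp.load_hemicaudotheca_taxa()
        )
        assert m.row("Utahraptor ostrommaysorum")[0] == frozenset({2})
        assert m.row("Achillobator giganticus")[1:] == [MISSING] * 6

    def test_all_unknown_record_gives_missing_row(self):
        rec = TailRecord("mystery", "none")
        m = mp.encode_tail_characters([rec])
        assert all(c is MISSING for c in m.row("mystery"))

    def test_interval_straddle_becomes_ambiguity_set(self, tail_records):
        m = mp.encode_tail_characters(tail_records)
        # caudal count ">25" intersects the 25-30 and >30 bins only
        j = 3  # nc_class
        assert m.row("Huaxiagnathus orientalis")[j] == frozenset({1, 2})

    def test_dropped_taxa_are_logged_not_silent(self, tail_records, reference_tree):
        keep = set(reference_tree.labels.values())
        m = mp.encode_tail_characters(tail_records, keep_taxa=keep)
        assert m.meta["dropped_taxa"] == ["UMNH VP 20209"]
        assert set(m.taxa) <= keep


@pytest.fixture(scope="module")
def changes(tail_records, reference_tree):
    m = mp.encode_tail_characters(
        tail_records,
        extra_states=mp.load_hemicaudotheca_taxa(),
        keep_taxa=set(reference_tree.labels.values()),
    )
    return mp.map_tail_changes(reference_tree, m), m, reference_tree


class TestMapping:
    def test_caudotheca_gain_then_hemicaudotheca_within(self, changes):
        chs, _, _ = changes
        sheath = [c for c in chs if c.character == "caudotheca"]
        assert len(sheath) == 2
        gain = next(c for c in sheath if (c.from_state, c.to_state) == (0, 1))
        hemi = next(c for c in sheath if (c.from_state, c.to_state) == (1, 2))
        # the hemicaudotheca arises INSIDE the caudothecate clade
        assert hemi.clade < gain.clade
        assert hemi.clade == frozenset(
            {"Utahraptor ostrommaysorum", "Achillobator giganticus"}
        )

    def test_elongation_gain_in_paraves_reversal_in_eudromaeosauria(self, changes):
        chs, _, tree = changes
        elong = [c for c in chs if c.character == "elongation_2x"]
        assert len(elong) == 2
        gain = next(c for c in elong if c.to_state == 1)
        loss = next(c for c in elong if c.to_state == 0)
        assert "Archaeopteryx sp." in gain.clade and "Anchiornis huxleyi" in gain.clade
        assert "Microraptor zhaoianus" in gain.clade
        eudro = {
            "Bambiraptor feinbergorum", "Deinonychus antirrhopus",
            "Tsaagan sp.", "Velociraptor mongoliensis",
            "Utahraptor ostrommaysorum", "Achillobator giganticus",
        }
        assert loss.clade < eudro

    def test_sheath_position_characters_separate_the_two_clades(self, changes):
        chs, _, _ = changes
        for name in ("pz_class", "c_class"):
            moved = [c for c in chs if c.character == name]
            assert len(moved) == 1
            assert "Microraptor zhaoianus" not in moved[0].clade
            assert "Deinonychus antirrhopus" in moved[0].clade

    def test_change_counts_equal_parsimony_lengths(self, changes):
        chs, m, tree = changes
        shared = sorted(set(tree.labels.values()) & set(m.taxa))
        sub_tree = restrict_tree(tree, shared)
        names = [d.description for d in m.definitions]
        for j, name in enumerate(names):
            col = {t: m.column(j)[t] for t in shared}
            expect = mp.character_length(sub_tree, col)
            got = sum(1 for c in chs if c.character == name)
            assert got == expect

    def test_constant_character_maps_no_changes(self, reference_tree):
        recs = [
            TailRecord(t, "g", twofold=False)
            for t in sorted(reference_tree.labels.values())[:6]
        ]
        m = mp.encode_tail_characters(recs)
        chs = mp.map_tail_changes(reference_tree, m)
        assert chs == []


class TestClassification:
    def test_study_examples(self, tail_records):
        recs = _by_taxon(tail_records)
        assert mp.classify_tail_condition(recs["Microraptor zhaoianus"]) == (
            "microraptorian-pattern"
        )
        assert mp.classify_tail_condition(recs["Velociraptor mongoliensis"]) == (
            "eudromaeosaurian-pattern"
        )
        assert mp.classify_tail_condition(recs["UMNH VP 20209"]) == (
            "eudromaeosaurian-pattern"
        )
        assert mp.classify_tail_condition(recs["Gorgosaurus libratus"]) == (
            "acaudothecate"
        )
        assert mp.classify_tail_condition(recs["Microraptor gui"]) == "indeterminate"

    def test_agrees_with_clade_for_fully_known_dromaeosaurids(self, tail_records):
        want = {
            "Microraptoria": "microraptorian-pattern",
            "Eudromaeosauria": "eudromaeosaurian-pattern",
        }
        for r in tail_records:
            if r.group not in want or r.taxon == "UMNH VP 20209":
                continue
            fields = (r.tp, r.pz, r.c)
            if not all(isinstance(f, Bound) and f.hi < math.inf for f in fields):
                continue  # not fully known
            assert mp.classify_tail_condition(r) == want[r.group], r.taxon


class TestCaudothecaPosition:
    def test_study_worked_example(self):
        assert mp.infer_caudotheca_position(4, 3) == (8, 7)

    def test_nothing_missing(self):
        assert mp.infer_caudotheca_position(0, 1) == (2, 1)

    def test_strictly_increasing_in_both_arguments(self):
        for m in range(7):
            for k in range(1, 6):
                first, extent = mp.infer_caudotheca_position(m, k)
                assert first == extent + 1
                assert mp.infer_caudotheca_position(m + 1, k)[1] > extent
                assert mp.infer_caudotheca_position(m, k + 1)[1] > extent

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            mp.infer_caudotheca_position(-1, 1)
        with pytest.raises(ValueError):
            mp.infer_caudotheca_position(0, 0)
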