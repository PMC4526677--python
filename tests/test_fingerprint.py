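"""The tri-state fingerprint value type: parsing, field access, merge
algebra, packing, and concatenation."""

import pytest
from hypothesis import given, strategies as st

import frog
from frog.fingerprint import (
    all_unknown,
    concatenate,
    fingerprint_from_string,
    get_field,
    merge,
    pack,
    set_field,
    split,
    unpack,
)

LEVEL_WIDTHS = {
    "Chromosome": 13, "DNA": 15, "RNA": 23, "Protein": 22,
    "Variation": 18, "Interaction": 11,
}


def random_fp(draw, level_name, width):
    symbols = draw(
        st.text(alphabet="01*", min_size=width, max_size=width)
    )
    return frog.TriStateFingerprint(level_name, symbols)


@st.composite
def level_fingerprints(draw, level_name=None):
    if level_name is None:
        level_name = draw(st.sampled_from(sorted(LEVEL_WIDTHS)))
    return random_fp(draw, level_name, LEVEL_WIDTHS[level_name])


@pytest.mark.parametrize("name,width", LEVEL_WIDTHS.items())
def test_level_widths_match_published_layout(schema, name, width):
    assert schema.level_width(name) == width
    assert len(all_unknown(name, schema)) == width


@pytest.mark.parametrize(
    "text,level",
    [("01011**********", "DNA"), ("010111******010000", "Variation")],
)
def test_worked_example_strings_parse_and_round_trip(schema, text, level):
    fp = fingerprint_from_string(text, level, schema)
    assert fp.to_string() == text


def test_wrong_width_reports_expected_vs_actual(schema):
    with pytest.raises(frog.FingerprintError, match="15 symbols, got 14"):
        fingerprint_from_string("0" * 14, "DNA", schema)


def test_illegal_character_reports_position(schema):
    with pytest.raises(frog.FingerprintError, match="position 4"):
        fingerprint_from_string("0101X**********", "DNA", schema)


def test_set_then_get_recovers_every_property_in_the_schema(schema):
    for level in schema.levels:
        base = all_unknown(level.name, schema)
        for attr in level.attributes:
            for pc in attr.codes:
                fp = set_field(base, attr, pc.label)
                assert get_field(fp, attr) == pc.label
                # untouched spans stay unknown
                assert fp.symbols.count("*") == len(fp) - attr.bit_width


def test_set_field_is_idempotent(schema):
    attr = frog.lookup_attribute(schema, "DNA", "Transition")
    fp = all_unknown("DNA", schema)
    once = set_field(fp, attr, "T to C")
    assert set_field(once, attr, "T to C") == once
    assert once.field_symbols(attr) == "11"


def test_get_field_unknown_on_partial_span_and_undecodable_on_unlisted_code(schema):
    kind = frog.lookup_attribute(schema, "RNA", "Variation Kind")  # 3 bits, 5 codes
    fp = frog.TriStateFingerprint("RNA", "1*1" + "*" * 20)
    assert get_field(fp, kind) == frog.UNKNOWN
    fp = frog.TriStateFingerprint("RNA", "111" + "*" * 20)  # only 5 of 8 codes used
    assert get_field(fp, kind) == frog.UNDECODABLE


def test_level_mismatch_is_an_error(schema):
    attr = frog.lookup_attribute(schema, "DNA", "Transition")
    with pytest.raises(frog.FingerprintError, match="level"):
        set_field(all_unknown("RNA", schema), attr, "T to C")


class TestMerge:
    def test_rule_application_on_toy_strings(self):
        a = frog.TriStateFingerprint("Interaction", "01*" + "*" * 8)
        b = frog.TriStateFingerprint("Interaction", "0*1" + "*" * 8)
        assert merge(a, b).symbols == "011" + "*" * 8

    def test_conflict_reports_first_position(self):
        a = frog.TriStateFingerprint("Interaction", "01*" + "*" * 8)
        b = frog.TriStateFingerprint("Interaction", "00*" + "*" * 8)
        with pytest.raises(frog.MergeConflictError, match="position 1"):
            merge(a, b)

    @given(level_fingerprints())
    def test_all_unknown_is_identity(self, schema, fp):
        ident = frog.TriStateFingerprint(fp.level_name, "*" * len(fp))
        assert merge(fp, ident) == fp
        assert merge(ident, fp) == fp

    @given(level_fingerprints(level_name="DNA"), st.data())
    def test_commutative_and_associative_on_conflict_free_triples(self, schema, fp, data):
        # derive compatible partners by masking symbols of fp
        def mask(name):
            keep = data.draw(
                st.lists(st.booleans(), min_size=len(fp), max_size=len(fp)), label=name
            )
            return frog.TriStateFingerprint(
                fp.level_name,
                "".join(s if k else "*" for s, k in zip(fp.symbols, keep)),
            )

        a, b, c = mask("a"), mask("b"), mask("c")
        assert merge(a, b) == merge(b, a)
        assert merge(merge(a, b), c) == merge(a, merge(b, c))


class TestPacking:
    def test_packed_size_is_quarter_symbol_count_rounded_up(self, schema):
        fp = fingerprint_from_string("01011**********", "DNA", schema)
        assert len(pack(fp)) == 4  # ceil(15 * 2 / 8)

    @given(level_fingerprints())
    def test_round_trip_identity(self, schema, fp):
        assert unpack(pack(fp), fp.level_name, schema) == fp

    def test_reserved_symbol_value_rejected(self, schema):
        with pytest.raises(frog.FingerprintError, match="reserved"):
            unpack(b"\xff\x00\x00", "Interaction", schema)

    def test_inconsistent_byte_length_rejected(self, schema):
        with pytest.raises(frog.FingerprintError, match="bytes"):
            unpack(b"\x00", "DNA", schema)


class TestConcatenate:
    def test_six_all_unknown_levels_give_102_stars(self, schema):
        fps = {name: all_unknown(name, schema) for name in frog.LEVEL_ORDER}
        full = concatenate(fps, schema)
        assert full.symbols == "*" * 102 and full.level_name == "ALL"

    @given(st.data())
    def test_concatenate_then_split_is_identity(self, schema, data):
        fps = {
            name: random_fp(data.draw, name, LEVEL_WIDTHS[name])
            for name in frog.LEVEL_ORDER
        }
        assert split(concatenate(fps, schema), schema) == fps

    def test_missing_level_is_an_error(self, schema):
        fps = {name: all_unknown(name, schema) for name in frog.LEVEL_ORDER[:-1]}
        with pytest.raises(frog.FingerprintError, match="Interaction"):
            concatenate(fps, schema)
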