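"""Annotation encoding: the substitution code tables, HGVS parsing, the
published worked example, and the decode∘encode round trip."""

import pytest

import frog
from frog.encoder import GenomicChange, ProteinChange
from frog.synth import GeneratorConfig, generate_annotations

# the complete published code tables: 4 transitions, 8 transversions
TRANSITIONS = {("A", "G"): "00", ("G", "A"): "01", ("C", "T"): "10", ("T", "C"): "11"}
TRANSVERSIONS = {
    ("A", "C"): "000", ("A", "T"): "001", ("G", "C"): "010", ("G", "T"): "100",
    ("C", "A"): "011", ("C", "G"): "101", ("T", "A"): "110", ("T", "G"): "111",
}


class TestClassifySubstitution:
    @pytest.mark.parametrize("pair,code", TRANSITIONS.items())
    def test_transitions_get_two_bit_codes(self, pair, code):
        sub = frog.classify_substitution(*pair)
        assert (sub.category, sub.code) == ("transition", code)

    @pytest.mark.parametrize("pair,code", TRANSVERSIONS.items())
    def test_transversions_get_three_bit_codes(self, pair, code):
        sub = frog.classify_substitution(*pair)
        assert (sub.category, sub.code) == ("transversion", code)

    def test_total_on_exactly_twelve_ordered_pairs(self):
        pairs = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
        assert len(pairs) == 12
        cats = [frog.classify_substitution(r, a).category for r, a in pairs]
        assert cats.count("transition") == 4 and cats.count("transversion") == 8

    def test_identical_bases_rejected(self):
        with pytest.raises(frog.AnnotationError, match="not a substitution"):
            frog.classify_substitution("A", "A")

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(frog.AnnotationError, match="ambiguity"):
            frog.classify_substitution("N", "A")


class TestHgvsParsing:
    def test_mitochondrial_substitution(self):
        change = frog.parse_hgvs_substitution("m.10084T>C")
        assert change == GenomicChange("m", 10084, "T", "C")

    def test_protein_substitution(self):
        change = frog.parse_hgvs_substitution("p.I9T")
        assert change == ProteinChange(9, "I", "T")

    @pytest.mark.parametrize("text", ["10084TC", "x.1A>G", "p.I9", "m.T>C"])
    def test_malformed_strings_rejected(self, text):
        with pytest.raises(frog.HgvsParseError, match="malformed"):
            frog.parse_hgvs_substitution(text)

    @pytest.mark.parametrize("text", ["m.100delA", "c.4_6del", "p.I9fs", "g.5dup"])
    def test_unsupported_features_reported_explicitly(self, text):
        with pytest.raises(frog.HgvsParseError, match="unsupported"):
            frog.parse_hgvs_substitution(text)


class TestWorkedExample:
    def test_dna_fingerprint_matches_printed_string(self, schema, table2_annotation):
        fp = frog.encode_level(table2_annotation, "DNA", schema)
        assert fp.to_string() == "01011**********"

    def test_variation_fingerprint_matches_printed_string(self, schema, table2_annotation):
        fp = frog.encode_level(table2_annotation, "Variation", schema)
        assert fp.to_string() == "010111******010000"

    def test_chromosome_rna_interaction_stay_all_unknown(self, schema, table2_annotation):
        fps = frog.encode_all(table2_annotation, schema)
        for name in ("Chromosome", "RNA", "Interaction"):
            assert fps[name].is_all_unknown()

    def test_protein_fingerprint_matches_reconstructed_layout(self, schema, table2_annotation):
        # 21 printed symbols against a 22-bit level: the accessibility bit at
        # position 3 is reconstructed as '*', not verbatim from the source
        fp = frog.encode_level(table2_annotation, "Protein", schema)
        assert fp.to_string() == "00*1101" + "*" * 15

    def test_decoding_dna_fingerprint_names_the_transition(self, schema):
        fp = frog.fingerprint_from_string("01011**********", "DNA", schema)
        decoded = {pa.attribute: pa for pa in frog.decode_level(fp, schema)}
        assert decoded["Variation Kind"].property_label == "Transition"
        assert decoded["Transition"].property_label == "T to C"
        unknowns = [pa for pa in decoded.values() if pa.status == frog.UNKNOWN]
        assert len(unknowns) == 5

    def test_synonymy_contradiction_is_preserved_but_lintable(
        self, schema, table2_annotation
    ):
        # the worked example itself marks an I->T change as Synonymous
        warnings = frog.lint_annotation(table2_annotation, schema)
        assert len(warnings) == 1 and "Synonymous" in warnings[0]


class TestEncodeDecode:
    def test_empty_annotation_encodes_all_unknown_everywhere(self, schema):
        fps = frog.encode_all(frog.VariantAnnotation(variant_id="v"), schema)
        assert all(fp.is_all_unknown() for fp in fps.values())

    def test_unknown_property_label_rejected(self, schema):
        ann = frog.VariantAnnotation(
            variant_id="v", properties={("Variation", "Variation Origin"): "Maternall"}
        )
        with pytest.raises(frog.AnnotationError, match="Maternall"):
            frog.encode_level(ann, "Variation", schema)

    def test_supplied_label_contradicting_sequence_change_rejected(self, schema):
        ann = frog.VariantAnnotation(
            variant_id="v",
            genomic_change=GenomicChange("m", 10, "T", "C"),
            properties={("DNA", "Transition"): "A to G"},
        )
        with pytest.raises(frog.AnnotationError, match="contradict"):
            frog.encode_level(ann, "DNA", schema)

    def test_round_trip_recovers_known_fields_exactly(self, schema):
        """decode(encode(a)) == known fields of a, UNKNOWN elsewhere, over a
        seeded synthetic population with mixed missingness."""
        config = GeneratorConfig(seed=2024, n_records=1000, missingness=0.4)
        for ann in generate_annotations(config, schema):
            fps = frog.encode_all(ann, schema)
            for level_name, fp in fps.items():
                known = ann.known_properties(level_name)
                # sequence-derived fields join the expectation
                if level_name == "DNA" and ann.genomic_change is not None:
                    sub = frog.classify_substitution(
                        ann.genomic_change.ref_base, ann.genomic_change.alt_base, schema
                    )
                    known.setdefault("Variation Kind", sub.category.capitalize())
                    known.setdefault(sub.category.capitalize(), sub.label)
                if level_name == "Protein" and ann.protein_change is not None:
                    known.setdefault("Variation Kind", "Substitution")
                for pa in frog.decode_level(fp, schema):
                    if pa.attribute in known:
                        assert pa.property_label == known[pa.attribute]
                    else:
                        assert pa.status == frog.UNKNOWN

    def test_information_monotonicity_adding_a_field_only_fills_stars(self, schema):
        ann = frog.VariantAnnotation(
            variant_id="v", properties={("Variation", "Variation Origin"): "Maternal"}
        )
        before = frog.encode_level(ann, "Variation", schema)
        ann.properties[("Variation", "Pathogenicity")] = "Disease Causing"
        after = frog.encode_level(ann, "Variation", schema)
        for b, a in zip(before.symbols, after.symbols):
            assert b == a or b == "*"

    def test_fully_specified_annotation_has_no_stars(self, schema):
        config = GeneratorConfig(seed=7, n_records=20, missingness=0.0)
        for ann in generate_annotations(config, schema):
            fps = frog.encode_all(ann, schema)
            assert all("*" not in fp.symbols for fp in fps.values())
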