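import pytest
from hypothesis import settings

import frog

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    return frog.default_schema()


@pytest.fixture(scope="session")
def table2_annotation(schema):
    """The published worked example: MitoLSDB variant 531, m.10084T>C / p.I9T.

    Property labels mirror the example's assigned terms: maternal origin,
    single-nucleotide change, marked Synonymous (reproduced verbatim even
    though the protein change alters the residue), tissue and experiment data
    available, conservation 'variant', MeSH terms available, no model
    organism reported, and SIFT/PolyPhen calls tolerated/benign.
    """
    return frog.VariantAnnotation(
        variant_id="531",
        genomic_change=frog.parse_hgvs_substitution("m.10084T>C"),
        protein_change=frog.parse_hgvs_substitution("p.I9T"),
        properties={
            ("Variation", "Variation Origin"): "Maternal",
            ("Variation", "Classification"): "Single Base Or Amino Acid",
            ("Variation", "Association"): "Synonymous",
            ("Variation", "Tissue Details"): "Available",
            ("Variation", "Experiment Details"): "Available",
            ("Variation", "Invariant Region"): "Variant Region",
            ("Variation", "MeSH Terms"): "Available",
            ("Variation", "Model Organism Mouse"): "Not Reported",
            ("Variation", "Model Organism Rat"): "Not Reported",
            ("Variation", "Model Organism Zebrafish"): "Not Reported",
            ("Variation", "Model Organism Fly"): "Not Reported",
            ("Protein", "Predicted Pathogenicity"): "PolyPhen Benign, SIFT Tolerated",
        },
    )


def brute_force_search(collection, query, schema):
    """Independent oracle: per-record, per-constraint span comparison done
    directly on the strings, without compile_filter/match/numpy."""
    hits = []
    for vid, fps in collection.records:
        ok = True
        for level_name, attr_name, prop in query.constraints:
            attr = schema.level(level_name).attribute(attr_name)
            code = attr.code_for(prop)
            fp = fps.get(level_name)
            span = (
                fp.symbols[attr.bit_offset : attr.bit_offset + attr.bit_width]
                if fp is not None
                else "*" * attr.bit_width
            )
            for q, r in zip(code, span):
                if r == q:
                    continue
                if r == "*" and query.match_mode == "permissive":
                    continue
                ok = False
                break
            if not ok:
                break
        if ok:
            hits.append(vid)
    return hits
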