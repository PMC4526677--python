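"""Encode structured variant annotations to per-level fingerprints and back.

A :class:`VariantAnnotation` is a sparse record: a genomic substitution
(HGVS-style, e.g. ``m.10084T>C``), an optional protein substitution
(``p.I9T``), and a map of (level, attribute) -> property label for everything
else the schema knows about (origin, synonymy, HapMap population,
pathogenicity class, ...).  Absent fields encode as '*' across the
attribute's span.

Substitutions are classified on the reported strand: purine<->purine or
pyrimidine<->pyrimidine changes are transitions (2-bit codes), all other
changes transversions (3-bit codes).  A genomic substitution auto-populates
the DNA level's Variation Kind plus the matching Transition or Transversion
attribute; a protein substitution auto-populates the Protein level's
Variation Kind.  Supplied property labels are reproduced verbatim — the
encoder never second-guesses them against the sequence change (an optional
lint reports such contradictions instead).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import AnnotationError, HgvsParseError, MergeConflictError
from .fingerprint import (
    UNDECODABLE,
    UNKNOWN,
    TriStateFingerprint,
    all_unknown,
    get_field,
    merge,
    set_field,
)
from .schema import LEVEL_ORDER, Schema

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class GenomicChange:
    """A single-nucleotide substitution on a g/m/c molecule, 1-based."""

    molecule: str  # 'g' genomic, 'm' mitochondrial, 'c' coding
    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self):
        if self.molecule not in {"g", "m", "c"}:
            raise AnnotationError(f"molecule must be g, m or c, got {self.molecule!r}")
        for base in (self.ref_base, self.alt_base):
            if base not in PURINES | PYRIMIDINES:
                raise AnnotationError(f"base must be one of A,C,G,T, got {base!r}")
        if self.ref_base == self.alt_base:
            raise AnnotationError("reference and alternate base are identical")
        if self.position < 1:
            raise AnnotationError("positions are 1-based; got {self.position}")

    def hgvs(self) -> str:
        return f"{self.molecule}.{self.position}{self.ref_base}>{self.alt_base}"


@dataclass(frozen=True)
class ProteinChange:
    """A single amino-acid substitution, 1-based, one-letter codes."""

    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self):
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AMINO_ACIDS:
                raise AnnotationError(f"not a one-letter amino acid: {aa!r}")
        if self.position < 1:
            raise AnnotationError("positions are 1-based")

    def hgvs(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class VariantAnnotation:
    """A partially populated variant record; the encoder's input."""

    variant_id: str
    genomic_change: GenomicChange | None = None
    protein_change: ProteinChange | None = None
    properties: dict[tuple[str, str], str] = field(default_factory=dict)

    def known_properties(self, level_name: str) -> dict[str, str]:
        return {a: p for (lv, a), p in self.properties.items() if lv == level_name}

    def validate(self, schema: Schema) -> None:
        """Check every (level, attribute, property) triple against the schema."""
        for (level_name, attr_name), label in self.properties.items():
            attr = schema.level(level_name).attribute(attr_name)
            if label not in attr.labels():
                raise AnnotationError(
                    f"{self.variant_id}: {level_name}.{attr_name} has no property "
                    f"{label!r} (known: {', '.join(attr.labels()[:6])}...)"
                )


@dataclass(frozen=True)
class SubstitutionClass:
    category: str  # "transition" | "transversion"
    label: str  # e.g. "T to C"
    code: str  # 2-bit (transition) or 3-bit (transversion) code


@dataclass(frozen=True)
class PropertyAssignment:
    """One decoded attribute: a label, UNKNOWN, or UNDECODABLE."""

    level: str
    attribute: str
    property_label: str
    status: str  # "known" | UNKNOWN | UNDECODABLE


def classify_substitution(
    ref_base: str, alt_base: str, schema: Schema | None = None
) -> SubstitutionClass:
    """Classify a nucleotide substitution and return its published code.

    Transitions (A<->G, C<->T) carry 2-bit codes, the eight transversions
    3-bit codes, both read from the DNA level's code tables.
    """
    from .schema import default_schema

    schema = schema or default_schema()
    for base in (ref_base, alt_base):
        if base not in PURINES | PYRIMIDINES:
            raise AnnotationError(
                f"base must be one of A,C,G,T (ambiguity codes rejected): {base!r}"
            )
    if ref_base == alt_base:
        raise AnnotationError(f"not a substitution: {ref_base} to {alt_base}")
    label = f"{ref_base} to {alt_base}"
    is_transition = (ref_base in PURINES) == (alt_base in PURINES)
    attr_name = "Transition" if is_transition else "Transversion"
    attr = schema.level("DNA").attribute(attr_name)
    return SubstitutionClass(attr_name.lower(), label, attr.code_for(label))


_NT_RE = re.compile(r"^([gmc])\.(\d+)([A-Za-z*]+)>([A-Za-z*]+)$")
_AA_RE = re.compile(r"^p\.([A-Za-z*])(\d+)([A-Za-z*])$")
_UNSUPPORTED_RE = re.compile(r"(del|ins|dup|inv|con|ext|fs|_|\[)")


def parse_hgvs_substitution(text: str) -> GenomicChange | ProteinChange:
    """Parse the minimal substitution dialects ``<g|m|c>.<pos><REF>><ALT>``
    and ``p.<RefAA><pos><AltAA>`` (one-letter amino acids).

    Indels, ranges and other HGVS features raise an explicit "unsupported"
    error rather than failing silently.
    """
    text = text.strip()
    if _UNSUPPORTED_RE.search(text):
        raise HgvsParseError(
            f"unsupported HGVS feature in {text!r}: only simple substitutions "
            "(g./m./c. single-nucleotide, p. single-residue) are handled"
        )
    m = _NT_RE.match(text)
    if m:
        mol, pos, ref, alt = m.groups()
        if len(ref) != 1 or len(alt) != 1:
            raise HgvsParseError(f"unsupported multi-base substitution: {text!r}")
        try:
            return GenomicChange(mol, int(pos), ref.upper(), alt.upper())
        except AnnotationError as exc:
            raise HgvsParseError(f"{text!r}: {exc}") from exc
    m = _AA_RE.match(text)
    if m:
        ref, pos, alt = m.groups()
        try:
            return ProteinChange(int(pos), ref.upper(), alt.upper())
        except AnnotationError as exc:
            raise HgvsParseError(f"{text!r}: {exc}") from exc
    raise HgvsParseError(
        f"malformed variant description {text!r}: neither the nucleotide dialect "
        "'<g|m|c>.<pos><REF>><ALT>' nor the protein dialect 'p.<Ref><pos><Alt>' matched"
    )


def _derived_fingerprint(
    annotation: VariantAnnotation, level_name: str, schema: Schema
) -> TriStateFingerprint:
    """Fields implied by the sequence changes rather than supplied labels."""
    fp = all_unknown(level_name, schema)
    if level_name == "DNA" and annotation.genomic_change is not None:
        gc = annotation.genomic_change
        sub = classify_substitution(gc.ref_base, gc.alt_base, schema)
        level = schema.level("DNA")
        fp = set_field(fp, level.attribute("Variation Kind"), sub.category.capitalize())
        attr = level.attribute("Transition" if sub.category == "transition" else "Transversion")
        fp = set_field(fp, attr, sub.label)
    if level_name == "Protein" and annotation.protein_change is not None:
        fp = set_field(fp, schema.level("Protein").attribute("Variation Kind"), "Substitution")
    return fp


def encode_level(
    annotation: VariantAnnotation, level_name: str, schema: Schema
) -> TriStateFingerprint:
    """Encode one level: every known attribute contributes its code at its
    bit offset, everything else stays '*'.

    Explicitly supplied labels and sequence-derived fields are merged; a
    contradiction between them (e.g. a supplied Transition label disagreeing
    with the genomic change) surfaces as an :class:`AnnotationError`.
    """
    annotation.validate(schema)
    level = schema.level(level_name)
    fp = all_unknown(level_name, schema)
    for attr_name, label in annotation.known_properties(level_name).items():
        fp = set_field(fp, level.attribute(attr_name), label)
    try:
        return merge(fp, _derived_fingerprint(annotation, level_name, schema))
    except MergeConflictError as exc:
        raise AnnotationError(
            f"{annotation.variant_id}: supplied {level_name} properties contradict "
            f"the sequence change ({exc})"
        ) from exc


def encode_all(
    annotation: VariantAnnotation, schema: Schema
) -> dict[str, TriStateFingerprint]:
    """Encode all six levels."""
    return {name: encode_level(annotation, name, schema) for name in LEVEL_ORDER}


def decode_level(fp: TriStateFingerprint, schema: Schema) -> list[PropertyAssignment]:
    """Decode a level fingerprint into one assignment per attribute."""
    level = schema.level(fp.level_name)
    out = []
    for attr in level.attributes:
        result = get_field(fp, attr)
        if result in (UNKNOWN, UNDECODABLE):
            out.append(PropertyAssignment(level.name, attr.name, "", result))
        else:
            out.append(PropertyAssignment(level.name, attr.name, result, "known"))
    return out


def lint_annotation(annotation: VariantAnnotation, schema: Schema) -> list[str]:
    """Report internal contradictions the encoder deliberately preserves,
    e.g. a Synonymous flag alongside an amino-acid-changing substitution."""
    warnings = []
    pc = annotation.protein_change
    syn = annotation.properties.get(("Variation", "Association"))
    if pc is not None and pc.ref_aa != pc.alt_aa and syn == "Synonymous":
        warnings.append(
            f"{annotation.variant_id}: marked Synonymous but {pc.hgvs()} changes the residue"
        )
    if pc is not None and pc.ref_aa == pc.alt_aa and syn == "Non Synonymous":
        warnings.append(
            f"{annotation.variant_id}: marked Non Synonymous but {pc.hgvs()} is silent"
        )
    return warnings
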