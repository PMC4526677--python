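"""Schema registry: the authoritative map from (level, attribute, property)
to bit positions and binary codes.

The schema is a six-level hierarchy — Chromosome, DNA, RNA, Protein,
Variation, Interaction — where each level is an ordered list of *attributes*
(contiguous bit spans) and each attribute an ordered table of *properties*
(controlled-vocabulary terms, one binary code each).  The default definition
ships with the package as a YAML document and totals 102 bits, 48 attributes
and 278 properties.

Codes carry a provenance flag: ``paper_fixed`` for codes stated verbatim in
the published code tables (transition/transversion tables, HapMap population
codes, pathogenicity classes, the worked-example bits), and
``implementation_assigned`` for codes completed by this implementation to
cover the full property inventories.
"""

from __future__ import annotations

import difflib
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import yaml

from .errors import SchemaError, UnknownAttributeError, UnknownLevelError

LEVEL_ORDER = ("Chromosome", "DNA", "RNA", "Protein", "Variation", "Interaction")

PAPER_FIXED = "paper_fixed"
IMPLEMENTATION_ASSIGNED = "implementation_assigned"


@dataclass(frozen=True)
class PropertyCode:
    """One controlled-vocabulary term and its binary code."""

    label: str
    code: str
    provenance: str = IMPLEMENTATION_ASSIGNED


@dataclass(frozen=True)
class Attribute:
    """A named group of mutually exclusive properties occupying a
    contiguous span of ``bit_width`` bits starting at ``bit_offset``
    within its level's fingerprint."""

    name: str
    level: str
    bit_width: int
    bit_offset: int
    codes: tuple[PropertyCode, ...]
    allows_unknown: bool = True

    @property
    def span(self) -> tuple[int, int]:
        """Half-open [start, stop) symbol range within the level fingerprint."""
        return (self.bit_offset, self.bit_offset + self.bit_width)

    def code_for(self, label: str) -> str:
        for pc in self.codes:
            if pc.label == label:
                return pc.code
        raise UnknownAttributeError(self.level, f"{self.name}={label}", self.labels())

    def label_for(self, code: str) -> str | None:
        for pc in self.codes:
            if pc.code == code:
                return pc.label
        return None

    def labels(self) -> list[str]:
        return [pc.label for pc in self.codes]


@dataclass(frozen=True)
class Level:
    name: str
    attributes: tuple[Attribute, ...]
    declared_bit_total: int
    declared_attribute_total: int
    declared_property_total: int

    @property
    def bit_total(self) -> int:
        return sum(a.bit_width for a in self.attributes)

    @property
    def property_total(self) -> int:
        return sum(len(a.codes) for a in self.attributes)

    def attribute(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        suggestions = difflib.get_close_matches(name, [a.name for a in self.attributes], n=3)
        raise UnknownAttributeError(self.name, name, suggestions)


@dataclass(frozen=True)
class Violation:
    """One schema-invariant violation, with a machine-readable path like
    ``DNA/Transition/codes``."""

    path: str
    message: str


@dataclass(frozen=True)
class Schema:
    levels: tuple[Level, ...]
    version: str = "1.0"
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_by_name", {lv.name: lv for lv in self.levels})

    def level(self, name: str) -> Level:
        try:
            return self._by_name[name]
        except KeyError:
            suggestions = difflib.get_close_matches(name, list(self._by_name), n=3)
            raise UnknownLevelError(name, suggestions) from None

    def level_width(self, level_name: str) -> int:
        """Fingerprint width for a level name, or 102 for the "ALL"
        concatenation of all six levels."""
        if level_name == "ALL":
            return sum(lv.bit_total for lv in self.levels)
        return self.level(level_name).bit_total

    @property
    def total_bits(self) -> int:
        return sum(lv.bit_total for lv in self.levels)

    @property
    def total_attributes(self) -> int:
        return sum(len(lv.attributes) for lv in self.levels)

    @property
    def total_properties(self) -> int:
        return sum(lv.property_total for lv in self.levels)

    def iter_attributes(self) -> Iterable[Attribute]:
        for lv in self.levels:
            yield from lv.attributes


# ---------------------------------------------------------------------------
# Loading


def _assign_codes(raw_props: list, width: int, path: str) -> list[PropertyCode]:
    """Resolve a property list to coded entries.

    Entries may be plain strings (assigned the smallest unused code, in
    listing order) or mappings with explicit ``code`` and optional ``fixed``.
    """
    explicit: dict[int, tuple[str, str, bool]] = {}
    order: list[tuple[str, str | None, bool]] = []
    for entry in raw_props:
        if isinstance(entry, str):
            order.append((entry, None, False))
        elif isinstance(entry, dict):
            try:
                label = entry["label"]
            except KeyError:
                raise SchemaError(f"{path}: property mapping without a label") from None
            order.append((str(label), entry.get("code"), bool(entry.get("fixed", False))))
        else:
            raise SchemaError(f"{path}: property entry must be a string or mapping")

    taken: set[str] = set()
    for label, code, _fixed in order:
        if code is not None:
            code = str(code)
            if len(code) != width or set(code) - {"0", "1"}:
                raise SchemaError(
                    f"{path}/{label}: code {code!r} is not a {width}-bit binary string"
                )
            if code in taken:
                raise SchemaError(f"{path}/{label}: duplicate code {code!r}")
            taken.add(code)

    # sequential fill of unassigned labels with the smallest unused value
    next_val = 0
    out: list[PropertyCode] = []
    for label, code, fixed in order:
        if code is None:
            while format(next_val, f"0{width}b") in taken:
                next_val += 1
            if next_val >= 2**width:
                raise SchemaError(f"{path}: more properties than {width} bits can encode")
            code = format(next_val, f"0{width}b")
            taken.add(code)
        out.append(
            PropertyCode(label, code, PAPER_FIXED if fixed else IMPLEMENTATION_ASSIGNED)
        )
    labels = [pc.label for pc in out]
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise SchemaError(f"{path}: duplicate property label {dup!r}")
    return out


def load_schema(
    source: Union[str, Path, io.TextIOBase, None] = None, validate: bool = True
) -> Schema:
    """Load a schema from a YAML definition.

    ``source`` may be a path, an open text stream, a YAML string, or ``None``
    for the packaged default.  The returned schema has been validated; a
    definition violating any structural invariant raises :class:`SchemaError`
    naming the offending level/attribute.  With ``validate=False`` the
    structural check is skipped so callers can collect the full
    :func:`validate_schema` report themselves.
    """
    if source is None:
        text = resources.files("frog.data").joinpath("schema.yaml").read_text()
    elif isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    else:
        text = source

    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"schema definition is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "levels" not in doc:
        raise SchemaError("schema definition must be a mapping with a 'levels' list")

    levels = []
    for raw_level in doc["levels"]:
        lname = raw_level.get("name")
        if lname not in LEVEL_ORDER:
            raise SchemaError(f"unknown level name {lname!r}; expected one of {LEVEL_ORDER}")
        attrs = []
        offset = 0
        seen_names: set[str] = set()
        for raw_attr in raw_level.get("attributes", []):
            aname = raw_attr.get("name")
            if aname is None:
                raise SchemaError(f"{lname}: attribute without a name")
            if aname in seen_names:
                raise SchemaError(f"{lname}/{aname}: duplicate attribute name")
            seen_names.add(aname)
            width = raw_attr.get("width")
            if not isinstance(width, int) or width < 1:
                raise SchemaError(f"{lname}/{aname}: width must be a positive integer")
            codes = _assign_codes(raw_attr.get("properties", []), width, f"{lname}/{aname}")
            attrs.append(
                Attribute(
                    name=aname,
                    level=lname,
                    bit_width=width,
                    bit_offset=offset,
                    codes=tuple(codes),
                    allows_unknown=bool(raw_attr.get("allows_unknown", True)),
                )
            )
            offset += width
        levels.append(
            Level(
                name=lname,
                attributes=tuple(attrs),
                declared_bit_total=int(raw_level.get("declared_bits", offset)),
                declared_attribute_total=int(raw_level.get("declared_attributes", len(attrs))),
                declared_property_total=int(
                    raw_level.get("declared_properties", sum(len(a.codes) for a in attrs))
                ),
            )
        )

    schema = Schema(levels=tuple(levels), version=str(doc.get("version", "1.0")))
    if not validate:
        return schema
    report = validate_schema(schema)
    if report:
        first = report[0]
        raise SchemaError(
            f"invalid schema ({len(report)} violation(s)); first: {first.path}: {first.message}"
        )
    return schema


def validate_schema(schema: Schema) -> list[Violation]:
    """Check every structural invariant; violations are returned as data,
    an empty list meaning the schema is valid."""
    out: list[Violation] = []
    names = tuple(lv.name for lv in schema.levels)
    if names != LEVEL_ORDER:
        out.append(
            Violation("levels", f"expected the six levels {LEVEL_ORDER} in order, got {names}")
        )
    for lv in schema.levels:
        offset = 0
        for attr in lv.attributes:
            path = f"{lv.name}/{attr.name}"
            if attr.bit_offset != offset:
                out.append(
                    Violation(path, f"offset {attr.bit_offset} leaves a gap (expected {offset})")
                )
            offset = attr.bit_offset + attr.bit_width
            if len(attr.codes) > 2**attr.bit_width:
                out.append(
                    Violation(
                        f"{path}/codes",
                        f"{len(attr.codes)} properties exceed 2^{attr.bit_width} codes",
                    )
                )
            seen_codes: set[str] = set()
            seen_labels: set[str] = set()
            for pc in attr.codes:
                if len(pc.code) != attr.bit_width or set(pc.code) - {"0", "1"}:
                    out.append(
                        Violation(
                            f"{path}/{pc.label}",
                            f"code {pc.code!r} is not a {attr.bit_width}-bit binary string",
                        )
                    )
                if pc.code in seen_codes:
                    out.append(Violation(f"{path}/{pc.label}", f"duplicate code {pc.code!r}"))
                if pc.label in seen_labels:
                    out.append(Violation(f"{path}/{pc.label}", "duplicate label"))
                seen_codes.add(pc.code)
                seen_labels.add(pc.label)
        if lv.bit_total != lv.declared_bit_total:
            out.append(
                Violation(
                    f"{lv.name}/declared_bit_total",
                    f"attributes sum to {lv.bit_total} bits but level declares "
                    f"{lv.declared_bit_total}",
                )
            )
        if len(lv.attributes) != lv.declared_attribute_total:
            out.append(
                Violation(
                    f"{lv.name}/declared_attribute_total",
                    f"{len(lv.attributes)} attributes but level declares "
                    f"{lv.declared_attribute_total}",
                )
            )
        if lv.property_total != lv.declared_property_total:
            out.append(
                Violation(
                    f"{lv.name}/declared_property_total",
                    f"{lv.property_total} properties but level declares "
                    f"{lv.declared_property_total}",
                )
            )
    return out


def schema_stats(schema: Schema) -> dict[str, tuple[int, int, int]]:
    """Per-level and total (bits, attributes, properties) counts."""
    stats = {
        lv.name: (lv.bit_total, len(lv.attributes), lv.property_total) for lv in schema.levels
    }
    stats["TOTAL"] = (schema.total_bits, schema.total_attributes, schema.total_properties)
    return stats


def lookup_attribute(schema: Schema, level_name: str, attribute_name: str) -> Attribute:
    """Find an attribute by level and name; unknown names raise with
    near-miss suggestions."""
    return schema.level(level_name).attribute(attribute_name)


def serialize_schema(schema: Schema) -> str:
    """Render a schema back to its YAML definition dialect.

    ``load_schema(serialize_schema(s))`` reproduces ``s`` exactly (codes are
    written explicitly, so sequential assignment plays no role on re-load).
    """
    doc = {
        "version": schema.version,
        "levels": [
            {
                "name": lv.name,
                "declared_bits": lv.declared_bit_total,
                "declared_attributes": lv.declared_attribute_total,
                "declared_properties": lv.declared_property_total,
                "attributes": [
                    {
                        "name": a.name,
                        "width": a.bit_width,
                        "properties": [
                            {
                                "label": pc.label,
                                "code": pc.code,
                                "fixed": pc.provenance == PAPER_FIXED,
                            }
                            for pc in a.codes
                        ],
                    }
                    for a in lv.attributes
                ],
            }
            for lv in schema.levels
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


_DEFAULT: Schema | None = None


def default_schema() -> Schema:
    """The packaged default schema (loaded once, cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_schema(None)
    return _DEFAULT
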