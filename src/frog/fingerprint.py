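"""Tri-state fingerprints.

A fingerprint is a fixed-width string over the alphabet ``{'0', '1', '*'}``
describing one variant at one schema level (13/15/23/22/18/11 symbols for the
six levels, or the 102-symbol concatenation of all of them).  ``'*'`` marks a
property that is not applicable to the variant or not available in the source
data; no distinction is made between the two.

The canonical interchange form is the character string.  A compact packed
form (2 bits per symbol: '0'->00, '1'->01, '*'->10; value 11 is reserved;
zero-padded to a byte boundary) is provided for storage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FingerprintError, MergeConflictError
from .schema import LEVEL_ORDER, Attribute, Schema

ALPHABET = frozenset("01*")
UNKNOWN = "UNKNOWN"
UNDECODABLE = "UNDECODABLE"

_SYM_TO_BITS = {"0": 0b00, "1": 0b01, "*": 0b10}
_BITS_TO_SYM = {v: k for k, v in _SYM_TO_BITS.items()}


@dataclass(frozen=True)
class TriStateFingerprint:
    """An immutable tri-state symbol string tied to a level name."""

    level_name: str
    symbols: str

    def __post_init__(self):
        bad = set(self.symbols) - ALPHABET
        if bad:
            pos = next(i for i, s in enumerate(self.symbols) if s in bad)
            raise FingerprintError(
                f"illegal character {self.symbols[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.symbols)

    def to_string(self) -> str:
        return self.symbols

    def is_all_unknown(self) -> bool:
        return set(self.symbols) <= {"*"}

    def field_symbols(self, attribute: Attribute) -> str:
        self._check_attribute(attribute)
        start, stop = attribute.span
        return self.symbols[start:stop]

    def _check_attribute(self, attribute: Attribute) -> None:
        if attribute.level != self.level_name:
            raise FingerprintError(
                f"attribute {attribute.name!r} belongs to level {attribute.level!r}, "
                f"not {self.level_name!r}"
            )
        if attribute.bit_offset + attribute.bit_width > len(self.symbols):
            raise FingerprintError(
                f"attribute {attribute.name!r} span exceeds fingerprint width"
            )


def all_unknown(level_name: str, schema: Schema) -> TriStateFingerprint:
    """The identity fingerprint: every symbol '*'."""
    return TriStateFingerprint(level_name, "*" * schema.level_width(level_name))


def fingerprint_from_string(text: str, level_name: str, schema: Schema) -> TriStateFingerprint:
    """Parse a fingerprint string, checking width against the schema and the
    alphabet symbol by symbol."""
    expected = schema.level_width(level_name)
    if len(text) != expected:
        raise FingerprintError(
            f"{level_name} fingerprint must be {expected} symbols, got {len(text)}"
        )
    for i, ch in enumerate(text):
        if ch not in ALPHABET:
            raise FingerprintError(f"illegal character {ch!r} at position {i}")
    return TriStateFingerprint(level_name, text)


def set_field(
    fp: TriStateFingerprint, attribute: Attribute, property_label: str
) -> TriStateFingerprint:
    """Return a fingerprint with the attribute's span set to the property's
    code; all other symbols are unchanged.  Idempotent for a fixed label."""
    fp._check_attribute(attribute)
    code = attribute.code_for(property_label)
    start, stop = attribute.span
    return TriStateFingerprint(fp.level_name, fp.symbols[:start] + code + fp.symbols[stop:])


def get_field(fp: TriStateFingerprint, attribute: Attribute) -> str:
    """Decode one attribute span.

    Returns the matching property label, :data:`UNKNOWN` if any symbol in the
    span is '*' (a partially determined span never partially matches), or
    :data:`UNDECODABLE` if the span is fully determined but matches no code.
    """
    span = fp.field_symbols(attribute)
    if "*" in span:
        return UNKNOWN
    label = attribute.label_for(span)
    return label if label is not None else UNDECODABLE


def merge(a: TriStateFingerprint, b: TriStateFingerprint) -> TriStateFingerprint:
    """Combine two partial fingerprints symbol-wise.

    '*' yields to a determined symbol; equal symbols pass through; '0' vs '1'
    raises :class:`MergeConflictError` at the first conflicting position.
    Commutative and idempotent; the all-'*' fingerprint is the identity.
    """
    if a.level_name != b.level_name or len(a) != len(b):
        raise FingerprintError(
            f"cannot merge {a.level_name} ({len(a)}) with {b.level_name} ({len(b)})"
        )
    out = []
    for i, (x, y) in enumerate(zip(a.symbols, b.symbols)):
        if x == y or y == "*":
            out.append(x)
        elif x == "*":
            out.append(y)
        else:
            raise MergeConflictError(i, x, y)
    return TriStateFingerprint(a.level_name, "".join(out))


def pack(fp: TriStateFingerprint) -> bytes:
    """Pack into 2 bits per symbol, most significant pair first, zero-padded
    to a byte boundary."""
    out = bytearray()
    acc = 0
    nbits = 0
    for sym in fp.symbols:
        acc = (acc << 2) | _SYM_TO_BITS[sym]
        nbits += 2
        if nbits == 8:
            out.append(acc)
            acc, nbits = 0, 0
    if nbits:
        out.append(acc << (8 - nbits))
    return bytes(out)


def unpack(data: bytes, level_name: str, schema: Schema) -> TriStateFingerprint:
    """Inverse of :func:`pack`; rejects a byte length inconsistent with the
    level width and the reserved symbol value 11."""
    n = schema.level_width(level_name)
    expected_len = (2 * n + 7) // 8
    if len(data) != expected_len:
        raise FingerprintError(
            f"packed {level_name} fingerprint must be {expected_len} bytes, got {len(data)}"
        )
    symbols = []
    for i in range(n):
        byte = data[i // 4]
        pair = (byte >> (6 - 2 * (i % 4))) & 0b11
        if pair not in _BITS_TO_SYM:
            raise FingerprintError(f"reserved symbol value 11 at position {i}")
        symbols.append(_BITS_TO_SYM[pair])
    return TriStateFingerprint(level_name, "".join(symbols))


def concatenate(
    per_level: dict[str, TriStateFingerprint], schema: Schema
) -> TriStateFingerprint:
    """Join one fingerprint per level, in schema order, into the full-width
    ("ALL") fingerprint."""
    parts = []
    for name in LEVEL_ORDER:
        if name not in per_level:
            raise FingerprintError(f"missing level {name!r}")
        fp = per_level[name]
        expected = schema.level_width(name)
        if fp.level_name != name or len(fp) != expected:
            raise FingerprintError(
                f"level {name!r}: expected a {expected}-symbol {name} fingerprint"
            )
        parts.append(fp.symbols)
    return TriStateFingerprint("ALL", "".join(parts))


def split(fp: TriStateFingerprint, schema: Schema) -> dict[str, TriStateFingerprint]:
    """Slice an "ALL" fingerprint back into its six per-level fingerprints;
    inverse of :func:`concatenate`."""
    if fp.level_name != "ALL" or len(fp) != schema.level_width("ALL"):
        raise FingerprintError("expected a full-width 'ALL' fingerprint")
    out = {}
    pos = 0
    for name in LEVEL_ORDER:
        w = schema.level_width(name)
        out[name] = TriStateFingerprint(name, fp.symbols[pos : pos + w])
        pos += w
    return out
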