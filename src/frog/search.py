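"""Wildcard-aware search over fingerprint collections.

A query filter is a conjunction of (level, attribute, property) constraints,
compiled to one masked query fingerprint per constrained level: the
constrained spans carry the property codes, everything else is '*'.

Matching is symbol-wise.  A query '*' matches anything.  A determined query
symbol against the same record symbol matches; against a record '*' the
result depends on the mode: **strict** (default) treats an unrecorded field
as a non-match — a search for T->C transitions should not return variants
whose transition field was never recorded — while **permissive** lets '*'
satisfy any query symbol, trading precision for recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FingerprintError, FrogError
from .fingerprint import TriStateFingerprint, all_unknown, set_field
from .schema import Schema

STRICT = "strict"
PERMISSIVE = "permissive"

_SYM_CODE = {"0": 0, "1": 1, "*": 2}


@dataclass(frozen=True)
class QueryFilter:
    """Conjunctive constraints; at most one per (level, attribute)."""

    constraints: tuple[tuple[str, str, str], ...]  # (level, attribute, property)
    match_mode: str = STRICT

    def __post_init__(self):
        if self.match_mode not in (STRICT, PERMISSIVE):
            raise FrogError(f"match mode must be strict or permissive: {self.match_mode!r}")
        seen = set()
        for level, attr, _prop in self.constraints:
            if (level, attr) in seen:
                raise FrogError(f"duplicate constraint on {level}.{attr}")
            seen.add((level, attr))

    @classmethod
    def from_strings(cls, specs: list[str], match_mode: str = STRICT) -> "QueryFilter":
        """Parse ``level.attribute=property`` strings (CLI form)."""
        constraints = []
        for spec in specs:
            try:
                key, prop = spec.split("=", 1)
                level, attr = key.split(".", 1)
            except ValueError:
                raise FrogError(
                    f"filter {spec!r} must look like level.attribute=property"
                ) from None
            constraints.append((level.strip(), attr.strip(), prop.strip()))
        return cls(tuple(constraints), match_mode)


@dataclass
class FingerprintCollection:
    """An in-memory store of per-level fingerprints, one row per variant."""

    schema: Schema
    records: list[tuple[str, dict[str, TriStateFingerprint]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def add(self, variant_id: str, fingerprints: dict[str, TriStateFingerprint]) -> None:
        for name, fp in fingerprints.items():
            if len(fp) != self.schema.level_width(name) or fp.level_name != name:
                raise FingerprintError(
                    f"{variant_id}: invalid {name} fingerprint of width {len(fp)}"
                )
        self.records.append((variant_id, dict(fingerprints)))

    def variant_ids(self) -> list[str]:
        return [vid for vid, _ in self.records]

    def _level_matrix(self, level_name: str) -> np.ndarray:
        """(n_records, width) uint8 matrix, 0/1/2 for '0'/'1'/'*'; records
        missing the level are treated as all-'*'."""
        width = self.schema.level_width(level_name)
        mat = np.full((len(self.records), width), _SYM_CODE["*"], dtype=np.uint8)
        for i, (_vid, fps) in enumerate(self.records):
            fp = fps.get(level_name)
            if fp is not None:
                mat[i] = np.frombuffer(fp.symbols.encode("ascii"), dtype=np.uint8)
        if len(self.records):
            # remap ASCII '0','1','*' -> 0,1,2
            lut = np.full(256, 2, dtype=np.uint8)
            lut[ord("0")] = 0
            lut[ord("1")] = 1
            mat = lut[mat] if mat.max() > 2 else mat
        return mat


def compile_filter(
    query: QueryFilter, schema: Schema
) -> dict[str, TriStateFingerprint]:
    """Compile constraints to one masked query fingerprint per constrained
    level.  An empty filter compiles to an empty map (matches everything)."""
    per_level: dict[str, TriStateFingerprint] = {}
    for level_name, attr_name, prop in query.constraints:
        attr = schema.level(level_name).attribute(attr_name)
        if prop not in attr.labels():
            raise FrogError(
                f"{level_name}.{attr_name} has no property {prop!r} "
                f"(known: {', '.join(attr.labels()[:6])}...)"
            )
        fp = per_level.get(level_name) or all_unknown(level_name, schema)
        per_level[level_name] = set_field(fp, attr, prop)
    return per_level


def match(
    query: TriStateFingerprint, record: TriStateFingerprint, mode: str = STRICT
) -> bool:
    """Does one record fingerprint satisfy one query fingerprint?"""
    if query.level_name != record.level_name or len(query) != len(record):
        raise FingerprintError(
            f"level/width mismatch: query {query.level_name}({len(query)}) vs "
            f"record {record.level_name}({len(record)})"
        )
    for q, r in zip(query.symbols, record.symbols):
        if q == "*" or q == r:
            continue
        if r == "*" and mode == PERMISSIVE:
            continue
        return False
    return True


def search(collection: FingerprintCollection, query: QueryFilter) -> list[str]:
    """All variant ids (in stable input order) whose fingerprints satisfy
    every constrained level.  Vectorized over the collection; behaviorally
    identical to a record-by-record scan with :func:`match`."""
    compiled = compile_filter(query, collection.schema)
    if not compiled or not collection.records:
        return collection.variant_ids()
    keep = np.ones(len(collection.records), dtype=bool)
    for level_name, qfp in compiled.items():
        q = np.array([_SYM_CODE[s] for s in qfp.symbols], dtype=np.uint8)
        mat = collection._level_matrix(level_name)
        ok = (q == 2) | (mat == q)
        if query.match_mode == PERMISSIVE:
            ok |= mat == 2
        keep &= ok.all(axis=1)
    return [vid for vid, flag in zip(collection.variant_ids(), keep) if flag]
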