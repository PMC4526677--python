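"""Readers and writers: annotation TSV, fingerprint TSV, minimal VCF.

Annotation TSV dialect: a header row with ``variant_id`` plus any of
``genomic_change``, ``protein_change`` (HGVS-style substitution strings) and
``Level.Attribute`` columns whose cells hold property labels; empty cells
mean unknown.  Unknown columns and unknown labels are rejected with a
row/column location (unknown columns are ignored in lax mode).

Fingerprint TSV dialect: ``variant_id``, ``level``, ``fingerprint`` — one
row per (variant, level), the fingerprint in its character string form.

VCF ingestion is deliberately minimal: sites only, biallelic SNV alleles
(multi-allelic records are split on ALT); everything else is counted and
skipped with a reason.  INFO/FORMAT are ignored.  "MT", "chrM", "M" and
"chrMT" contigs normalize to the mitochondrial molecule code ``m``.
"""

from __future__ import annotations

import difflib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

from cyvcf2 import VCF

from .encoder import GenomicChange, ProteinChange, VariantAnnotation, parse_hgvs_substitution
from .errors import FormatError, HgvsParseError
from .fingerprint import TriStateFingerprint, fingerprint_from_string
from .schema import LEVEL_ORDER, Schema
from .search import FingerprintCollection

_MITO_NAMES = {"MT", "CHRM", "M", "CHRMT"}
_RESERVED_COLUMNS = ("variant_id", "genomic_change", "protein_change")


def _open_lines(source: Union[str, Path, TextIO]) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    return Path(source).read_text().splitlines()


def _resolve_columns(header: list[str], schema: Schema, lax: bool) -> dict[int, tuple[str, str]]:
    """Map column index -> (level, attribute) for property columns."""
    if "variant_id" not in header:
        raise FormatError("annotation TSV must have a 'variant_id' column", line=1)
    mapping: dict[int, tuple[str, str]] = {}
    known = [
        f"{lv.name}.{a.name}" for lv in schema.levels for a in lv.attributes
    ]
    for idx, col in enumerate(header):
        if col in _RESERVED_COLUMNS:
            continue
        if col in known:
            level, attr = col.split(".", 1)
            mapping[idx] = (level, attr)
        elif not lax:
            hint = difflib.get_close_matches(col, known, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise FormatError(f"unknown column{suggestion}", line=1, column=col)
    return mapping


def read_annotations(
    source: Union[str, Path, TextIO], schema: Schema, lax: bool = False
) -> list[VariantAnnotation]:
    """Read an annotation TSV; one :class:`VariantAnnotation` per data row."""
    lines = _open_lines(source)
    if not lines:
        raise FormatError("empty file: a header row is required", line=1)
    header = lines[0].rstrip("\n").split("\t")
    columns = _resolve_columns(header, schema, lax)
    id_idx = header.index("variant_id")
    gc_idx = header.index("genomic_change") if "genomic_change" in header else None
    pc_idx = header.index("protein_change") if "protein_change" in header else None

    annotations = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"expected {len(header)} fields, got {len(cells)}", line=lineno
            )

        def cell(idx):
            return cells[idx].strip() if idx is not None and cells[idx].strip() else None

        genomic = protein = None
        for idx, target in ((gc_idx, "genomic"), (pc_idx, "protein")):
            text = cell(idx)
            if text is None:
                continue
            try:
                change = parse_hgvs_substitution(text)
            except HgvsParseError as exc:
                raise FormatError(str(exc), line=lineno, column=header[idx]) from exc
            if target == "genomic":
                if not isinstance(change, GenomicChange):
                    raise FormatError(
                        f"{text!r} is not a nucleotide substitution",
                        line=lineno,
                        column=header[idx],
                    )
                genomic = change
            else:
                if not isinstance(change, ProteinChange):
                    raise FormatError(
                        f"{text!r} is not a protein substitution",
                        line=lineno,
                        column=header[idx],
                    )
                protein = change

        props: dict[tuple[str, str], str] = {}
        for idx, (level, attr_name) in columns.items():
            label = cell(idx)
            if label is None:
                continue
            attr = schema.level(level).attribute(attr_name)
            if label not in attr.labels():
                hint = difflib.get_close_matches(label, attr.labels(), n=1)
                suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
                raise FormatError(
                    f"unknown property {label!r}{suggestion}",
                    line=lineno,
                    column=header[idx],
                )
            props[(level, attr_name)] = label
        annotations.append(
            VariantAnnotation(
                variant_id=cells[id_idx].strip(),
                genomic_change=genomic,
                protein_change=protein,
                properties=props,
            )
        )
    return annotations


def write_annotations(
    annotations: Iterable[VariantAnnotation], sink: TextIO, schema: Schema
) -> None:
    """Write the annotation TSV dialect (all schema columns, empty = unknown)."""
    columns = [f"{lv.name}.{a.name}" for lv in schema.levels for a in lv.attributes]
    sink.write("\t".join(["variant_id", "genomic_change", "protein_change"] + columns) + "\n")
    for ann in annotations:
        row = [
            ann.variant_id,
            ann.genomic_change.hgvs() if ann.genomic_change else "",
            ann.protein_change.hgvs() if ann.protein_change else "",
        ]
        for col in columns:
            level, attr = col.split(".", 1)
            row.append(ann.properties.get((level, attr), ""))
        sink.write("\t".join(row) + "\n")


@dataclass
class VcfIngest:
    """SNV annotations recovered from a VCF plus skip bookkeeping."""

    annotations: list[VariantAnnotation] = field(default_factory=list)
    skipped: Counter = field(default_factory=Counter)


def read_vcf_snvs(path: Union[str, Path]) -> VcfIngest:
    """Ingest biallelic SNV alleles from a VCF (v4.x, sites only).

    Each qualifying ALT allele becomes one annotation with only
    ``genomic_change`` populated (1-based position preserved); indels, MNVs
    and symbolic alleles are skipped and counted by reason.
    """
    result = VcfIngest()
    try:
        reader = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc
    for variant in reader:
        chrom = variant.CHROM
        molecule = "m" if chrom.upper() in _MITO_NAMES else "g"
        ref = variant.REF
        alts = variant.ALT
        if not alts:
            result.skipped["missing_alt"] += 1
            continue
        for k, alt in enumerate(alts):
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                result.skipped["not_snv"] += 1
                continue
            if ref == alt:
                result.skipped["ref_equals_alt"] += 1
                continue
            suffix = f"_{k + 1}" if len(alts) > 1 else ""
            vid = f"{chrom}:{variant.POS}:{ref}>{alt}{suffix}"
            result.annotations.append(
                VariantAnnotation(
                    variant_id=vid,
                    genomic_change=GenomicChange(molecule, variant.POS, ref, alt),
                )
            )
    return result


def write_fingerprints(
    records: Iterable[tuple[str, dict[str, TriStateFingerprint]]], sink: TextIO
) -> None:
    """Write the fingerprint TSV dialect, levels in schema order."""
    sink.write("variant_id\tlevel\tfingerprint\n")
    for variant_id, fps in records:
        for name in LEVEL_ORDER:
            if name in fps:
                sink.write(f"{variant_id}\t{name}\t{fps[name].to_string()}\n")
        for name in fps:
            if name not in LEVEL_ORDER:  # e.g. "ALL"
                sink.write(f"{variant_id}\t{name}\t{fps[name].to_string()}\n")


def read_fingerprints(
    source: Union[str, Path, TextIO], schema: Schema
) -> FingerprintCollection:
    """Read a fingerprint TSV into a collection; width/alphabet violations
    are rejected with their line number."""
    lines = _open_lines(source)
    if not lines or lines[0].split("\t") != ["variant_id", "level", "fingerprint"]:
        raise FormatError(
            "fingerprint TSV must start with header 'variant_id\\tlevel\\tfingerprint'",
            line=1,
        )
    collection = FingerprintCollection(schema=schema)
    per_variant: dict[str, dict[str, TriStateFingerprint]] = {}
    order: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 3:
            raise FormatError(f"expected 3 fields, got {len(cells)}", line=lineno)
        vid, level_name, text = cells
        try:
            fp = fingerprint_from_string(text, level_name, schema)
        except Exception as exc:
            raise FormatError(str(exc), line=lineno) from exc
        if vid not in per_variant:
            per_variant[vid] = {}
            order.append(vid)
        per_variant[vid][level_name] = fp
    for vid in order:
        collection.add(vid, per_variant[vid])
    return collection
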