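"""Seeded generator of schema-consistent variant annotations.

This is the package's stand-in for a real curated variation corpus: it draws
a property for every schema attribute (independently unknown with a
configurable missingness probability), then derives the sequence-level
fields so they agree with the drawn categorical ones — a record whose DNA
Variation Kind is Transition gets a genomic substitution whose bases realize
the drawn transition, and a record whose Protein Variation Kind is
Substitution gets a matching amino-acid change.  Draws use only the stdlib
Mersenne generator over integers/uniforms, so a fixed seed reproduces the
identical record list on any platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .encoder import AMINO_ACIDS, GenomicChange, ProteinChange, VariantAnnotation, encode_all
from .errors import FrogError
from .schema import Schema
from .search import FingerprintCollection

_MT_GENOME_LENGTH = 16569  # human mitochondrial genome, the classic corpus scale

Weights = dict[tuple[str, str], dict[str, float]]


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_records: int = 100
    missingness: float = 0.3
    property_weights: Weights = field(default_factory=dict)
    block_missingness: float = 0.0  # probability an entire level is unknown

    def __post_init__(self):
        if not 0.0 <= self.missingness <= 1.0:
            raise FrogError(f"missingness must be in [0, 1]: {self.missingness}")
        if not 0.0 <= self.block_missingness <= 1.0:
            raise FrogError(f"block_missingness must be in [0, 1]: {self.block_missingness}")
        if self.n_records < 0:
            raise FrogError(f"n_records must be >= 0: {self.n_records}")


def mtdna_like_weights() -> Weights:
    """Categorical weights mimicking a mitochondrial-variation corpus:
    substitutions dominate and transitions outnumber transversions heavily."""
    return {
        ("DNA", "Variation Kind"): {
            "Transition": 70,
            "Transversion": 10,
            "Substitution": 10,
            "Indel": 4,
            "Deletion": 3,
            "Insertion": 3,
        },
        ("Variation", "Classification"): {"Single Base Or Amino Acid": 90, "Stretch": 10},
        ("Variation", "Variation Origin"): {"Maternal": 85, "Paternal": 5, "Non Genetic": 5, "Both": 5},
    }


def _draw_label(rng: random.Random, labels: list[str], weights: dict[str, float] | None) -> str:
    if not weights:
        return labels[rng.randrange(len(labels))]
    w = [weights.get(label, 0.0) for label in labels]
    if sum(w) <= 0:
        raise FrogError(f"weights give zero total mass over {labels[:4]}...")
    return rng.choices(labels, weights=w, k=1)[0]


def _bases_from_label(label: str) -> tuple[str, str]:
    ref, _, alt = label.partition(" to ")
    return ref, alt


def generate_annotations(config: GeneratorConfig, schema: Schema) -> list[VariantAnnotation]:
    """Generate ``config.n_records`` reproducible annotations."""
    rng = random.Random(config.seed)
    aa_list = sorted(AMINO_ACIDS)
    out = []
    for i in range(config.n_records):
        props: dict[tuple[str, str], str] = {}
        for level in schema.levels:
            if config.block_missingness and rng.random() < config.block_missingness:
                continue
            for attr in level.attributes:
                if config.missingness and rng.random() < config.missingness:
                    continue
                key = (level.name, attr.name)
                props[key] = _draw_label(
                    rng, attr.labels(), config.property_weights.get(key)
                )

        genomic = None
        kind = props.get(("DNA", "Variation Kind"))
        if kind in ("Transition", "Transversion"):
            sub_label = props.get(("DNA", kind))
            if sub_label is not None:
                ref, alt = _bases_from_label(sub_label)
                genomic = GenomicChange("m", rng.randint(1, _MT_GENOME_LENGTH), ref, alt)

        protein = None
        if props.get(("Protein", "Variation Kind")) == "Substitution":
            ref_aa = aa_list[rng.randrange(len(aa_list))]
            alt_aa = aa_list[rng.randrange(len(aa_list))]
            # a silent p.X->X record is legal only when marked Synonymous
            if ref_aa == alt_aa and props.get(("Variation", "Association")) != "Synonymous":
                alt_aa = aa_list[(aa_list.index(ref_aa) + 1) % len(aa_list)]
            protein = ProteinChange(rng.randint(1, 500), ref_aa, alt_aa)

        out.append(
            VariantAnnotation(
                variant_id=f"SYN{i + 1:06d}",
                genomic_change=genomic,
                protein_change=protein,
                properties=props,
            )
        )
    return out


def generate_collection(
    config: GeneratorConfig, schema: Schema
) -> tuple[FingerprintCollection, list[VariantAnnotation]]:
    """Generate annotations and encode them into a searchable collection."""
    annotations = generate_annotations(config, schema)
    collection = FingerprintCollection(schema=schema)
    for ann in annotations:
        collection.add(ann.variant_id, encode_all(ann, schema))
    return collection, annotations
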