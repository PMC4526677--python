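# frog-fingerprints

FROG ("FingeRprinting Ontology of Genomic variations") encodes what is known
about a genetic variant — where it sits, what it changes at the DNA, RNA and
protein levels, its origin, population distribution and pathogenicity — as a
fixed-width binary fingerprint, so that heterogeneous variant annotations
become machine-comparable strings that can be stored compactly and searched
with bitwise filters.

This package is a library + CLI implementation of that idea for people who
curate or mine variant-annotation collections:

- a **schema registry**: six levels (Chromosome, DNA, RNA, Protein,
  Variation, Interaction) partitioned into 48 attributes holding 278
  controlled-vocabulary properties, mapped onto **102 bits** in total
  (13/15/23/22/18/11 per level). Each property has a binary code; codes
  stated verbatim in the published code tables are flagged `paper_fixed`,
  the rest `implementation_assigned`;
- **tri-state fingerprints** over `{0, 1, *}` — `*` marks a property not
  applicable or not recorded — with field get/set, merge, 2-bit packing and
  concatenation into the full 102-symbol form;
- an **encoder/decoder** between structured annotations and fingerprints,
  including classification of nucleotide substitutions (transitions `00=A→G,
  01=G→A, 10=C→T, 11=T→C`; the eight transversions in 3 bits) and a minimal
  HGVS substitution parser (`m.10084T>C`, `p.I9T`);
- a **wildcard-aware search engine**: conjunctive attribute filters compile
  to masked query fingerprints; *strict* mode (default) does not let an
  unrecorded `*` satisfy a set query bit, *permissive* mode does;
- TSV/VCF **IO** and a seeded **synthetic-annotation generator** that stands
  in for a real curated corpus.

## Worked example

The canonical example is a mitochondrial variant, `m.10084T>C` (a T→C
transition changing ND3 isoleucine 9 to threonine, `p.I9T`), annotated as
maternal, single-nucleotide, with tissue and experiment data available,
MeSH terms attached and no model-organism reports. Encode it:

```sh
frog encode --in demo.tsv
```

```text
variant_id	level	fingerprint
531	Chromosome	*************
531	DNA	01011**********
531	RNA	***********************
531	Protein	00*1101***************
531	Variation	010111******010000
531	Interaction	***********
```

Reading the DNA fingerprint: the first 3 bits `010` say the variation kind
is a transition, bits 4–5 `11` identify it as T→C, and the ten `*` say
nothing else was recorded at the DNA level. In the Variation fingerprint,
`01` = maternal origin, then single-nucleotide (`0`), synonymous flag (`1`),
tissue (`1`) and experiment (`1`) data available; the six `*` cover the
unrecorded HapMap population, pathogenicity class, minor-allele-frequency
and copy-number fields; then `0` (variant region), `1` (MeSH available) and
`0000` (no model organism reported). The schema layout behind this:

```sh
$ frog schema show
level           bits  attributes  properties
Chromosome        13           5          38
DNA               15           7          36
RNA               23           9          58
Protein           22           8          78
Variation         18          15          36
Interaction       11           4          32
TOTAL            102          48         278
```

Search a fingerprint collection for all T→C transitions:

```sh
frog search --db fingerprints.tsv --filter "DNA.Transition=T to C" --count-only
```

Other subcommands: `frog schema validate <file>`, `frog decode`,
`frog generate` (seeded synthetic corpora), `frog encode --vcf sites.vcf`.
See `frog --help`.

## Library use

```python
import frog

schema = frog.default_schema()
ann = frog.VariantAnnotation(
    variant_id="531",
    genomic_change=frog.parse_hgvs_substitution("m.10084T>C"),
    properties={("Variation", "Variation Origin"): "Maternal"},
)
fps = frog.encode_all(ann, schema)
print(fps["DNA"].to_string())        # 01011**********
hits = frog.search(collection, frog.QueryFilter((("DNA", "Transition", "T to C"),)))
```

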