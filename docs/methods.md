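# Methods

## The encoding model

A variant annotation is modeled as a sparse assignment of controlled-
vocabulary *properties* to *attributes*, grouped into six *levels* —
Chromosome, DNA, RNA, Protein, Variation, Interaction. Each attribute owns a
contiguous span of bits inside its level's fingerprint; each of its
properties is one binary code of exactly that width. A variant's fingerprint
at a level is therefore a fixed-width string over `{0, 1, *}`: determined
spans carry property codes, `*` fills every attribute for which no
information exists. The six levels concatenate to a 102-symbol string
(13 + 15 + 23 + 22 + 18 + 11). Bit 1 in prose descriptions is the leftmost
character of the string form (offset 0).

The single wildcard `*` deliberately conflates "not applicable" and "not
available": the source format makes no distinction, and introducing a fourth
symbol would break string compatibility with existing fingerprints.
A partially wild attribute span always decodes as UNKNOWN — partial matches
against a code table would be unsound. A fully determined span matching no
code decodes as UNDECODABLE rather than raising, so damaged data can be
inventoried.

## Schema completion and provenance

The published inventory fixes the per-level totals — Chromosome 13 bits /
5 attributes / 38 properties, DNA 15/7/36, RNA 23/9/58, Protein 22/8/78,
Variation 18/15/36, Interaction 11/4/32; 102/48/278 overall — and a subset
of the codes: the transition table (2 bits), the eight transversions
(3 bits), the DNA variation-kind code for transitions (`010`), the Protein
substitution code (`00`) and the joint PolyPhen/SIFT code `1101` for
benign + tolerated, and at the Variation level the origin code `01` =
maternal, the single-vs-stretch, synonymy, tissue and experiment flag
polarities, the HapMap population codes (YRI `00`, JPT `11`, CHB `01`,
CEU `10`), the four pathogenicity classes, the invariant-region polarity and
the MeSH flag. Every other code — and every property label needed to reach
the printed counts where the prose only sketches the inventories — is
completed by this implementation. The shipped YAML definition records the
distinction per code (`paper_fixed` vs `implementation_assigned`), so fixed
codes are testable separately and a future revision can tighten the
assigned ones without touching the fixed ones.

Two layout choices deserve note:

- **Variation level, 15 attributes in 18 bits.** The published bit
  narrative walks through origin (2), single-vs-stretch (1), synonymy (1),
  tissue (1), experiment (1), HapMap geography (2), pathogenicity (2),
  MAF (1), CNV (1), invariant region (1), MeSH (1) and a 4-bit
  model-organism block — 12 spans, yet the level declares 15 attributes and
  36 properties. The only tiling consistent with all three constraints is to
  treat the model-organism block as four independent 1-bit reported/not
  flags (mouse, rat, zebrafish, fly): 15 attributes, and property counts
  4+2+2+2+2+4+4+2+2+2+2+2·4 = 36 exactly.
- **Protein level, the missing symbol.** The worked example prints a
  21-symbol Protein fingerprint against a declared 22-bit level, with its
  caption addressing bits 1–2 (variation kind) and 4–7 (predicted
  pathogenicity); a symbol at position 3 was evidently lost to a footnote
  marker in typesetting. The layout here places a 1-bit Accessibility
  attribute (buried/exposed) at offset 2, and the example reconstructs as
  `00*1101` + 15 `*`. This reconstruction is checked in the test suite but
  deliberately excluded from the byte-exact worked-example checks, which
  cover only the DNA and Variation rows printed in full.

The joint PolyPhen×SIFT attribute uses 4 bits as 2+2 (PolyPhen call, SIFT
call), with the orderings chosen so that benign+tolerated lands on the fixed
`1101`.

## Encoding semantics

A genomic substitution auto-populates the DNA level: variation kind plus the
matching transition or transversion code, classified on the reported
(forward) strand — purine↔purine or pyrimidine↔pyrimidine is a transition,
the rest transversions; ambiguity codes are rejected. A protein substitution
auto-populates the Protein variation kind. All other supplied labels are
reproduced verbatim: the encoder never derives synonymy from the amino-acid
change, because curated records can and do disagree with the sequence (the
worked example itself flags an isoleucine→threonine change as synonymous).
`lint_annotation` reports such contradictions without blocking encoding;
an explicit label that contradicts the sequence-derived *code* (e.g. a
supplied `A to G` next to `m.10084T>C`) is an error, surfaced through the
fingerprint merge rule. Coordinates are 1-based everywhere (HGVS and VCF
conventions).

The HGVS parser covers exactly the two dialects the annotation format uses
— `<g|m|c>.<pos><REF>><ALT>` and `p.<RefAA><pos><AltAA>` with one-letter
amino acids — and refuses indels, duplications and ranges with an explicit
"unsupported" error instead of silently misparsing them.

## Search semantics

Filters are conjunctive (AND across constraints; OR/NOT are out of scope)
and compile to one masked query fingerprint per constrained level. Matching
is symbol-wise; the one semantic decision the string format leaves open is
what a record's `*` does against a set query bit. Default is **strict** (no
match): a query for T→C transitions should not return variants whose
transition field was never recorded. **Permissive** mode is exposed for
recall-oriented queries; permissive results always contain the strict
results. The collection scan is vectorized with numpy over a uint8
symbol matrix but is behaviorally identical to a per-record scan — the test
suite and the acceptance script both enforce equality against an independent
brute-force oracle rather than assuming it.

## Synthetic data

The generator stands in for a curated variation corpus (the original was a
mitochondrial database of ~142,500 variations; its corpus-scale query counts
depend on that external resource and are not reproduced). Per record it
draws every schema attribute independently — unknown with probability
`missingness` (default 0.3, the attribute-wise sparsity visible in the
worked example's fingerprints), otherwise a categorical draw (uniform by
default, or weighted). Sequence fields are then derived *from* the drawn
categories so records are internally consistent: a record whose DNA kind is
Transition/Transversion gets a mitochondrial-coordinate substitution
(positions 1–16569) realizing the drawn base change, and a Protein
substitution record gets a matching amino-acid change. `mtdna_like_weights`
skews kind draws toward transitions (70:10 over transversions, maternal
origin dominant), mimicking a mitochondrial mutational spectrum at desk
scale; no attempt is made to model site-specific hotspots, disease
associations, or linkage between attributes beyond these consistency rules —
so passing round-trip and search tests demonstrates correctness of the
encoding and matching machinery, not realism of any biological distribution.
Randomness uses the stdlib Mersenne generator over integer/uniform draws
only, so a fixed seed reproduces identical records on any platform.

Problem sizes used by the shipped checks: 1,000 records at missingness 0.5
for the round-trip and oracle-equivalence properties (50 random filters,
both match modes), and 10,000 transition-skewed records for the T→C search
demo, where the engine's hit list must equal the brute-force scan exactly.

## Numerical and format choices

- Packed form: 2 bits per symbol (`0`→00, `1`→01, `*`→10, 11 reserved),
  most significant pair first, zero-padded to a byte boundary; an artifact
  addition for compact storage — the character string remains canonical.
- TSV dialects: annotations as `variant_id` / `genomic_change` /
  `protein_change` / `Level.Attribute` columns (empty cell = unknown);
  fingerprints as `variant_id` / `level` / `fingerprint`. Readers reject
  rather than coerce, and every rejection carries a line (and column)
  location plus a near-miss suggestion for misspelled labels or columns.
- VCF ingestion is sites-only and SNV-only by design: the schema's richer
  fields have no standard VCF home. Multi-allelic records split on ALT;
  skipped alleles are counted by reason. `MT`, `chrM`, `M`, `chrMT`
  normalize to molecule code `m`.

## Known limitations

- Property labels completed beyond the published inventories are plausible
  domain terms, not authoritative vocabulary; they are clearly flagged by
  provenance and trivially replaceable in the YAML definition.
- No OWL/OBO export, no cross-referencing into external variation
  ontologies, no schema-migration tooling.
- The search engine is an in-memory scan; it is linear in collection size
  and holds the whole collection in RAM, which is ample at the scales this
  package targets (10⁴–10⁵ records).
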