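# Methods

## The procedure and its assumptions

`recdf` rebuilds GeneChip probe sets from three inputs: a genome FASTA,
an Ensembl-dialect GTF and the chip's PM probe table. The pipeline has
three stages — exact genome mapping, containment annotation, probe-set
assembly — and its core assumptions are:

* **Exact, contiguous matching.** A probe measures its target only when
  its 25-mer matches the genome with 100% identity at exactly one locus
  (counting both strands). Anything else — multi-locus matches (a
  cross-hybridisation risk), probes with no contiguous genomic match
  (including probes spanning splice junctions) — is excluded. No
  mismatch tolerance and no spliced/transcriptome alignment is
  attempted; junction-aware mapping is explicitly out of scope.
* **Complete containment.** A probe is assigned to a feature only when
  the feature contains both ends of its hit interval. Partial overlaps
  carry ambiguous signal and are dropped at the region and gene level;
  a transcript span may still contain such probes (intronic probes, for
  instance, are transcript-level evidence of pre-mRNA or retained
  introns).
* **One annotation per probe.** Probe intensities are summarised per
  probe set, so a probe may belong to exactly one non-control probe set
  per CDF.

Coordinates are 1-based inclusive throughout (the GTF convention); any
0-based external representation is converted at the file boundary.

## Mapping

Probes on one chip share a single length, so exact alignment reduces to
a dictionary from every genomic k-mer (k = probe length) to its loci.
Only forward-strand windows are indexed; a probe is looked up as itself
and as its reverse complement. Consequences of this model:

* a self-reverse-complementary probe matching one genomic window is
  found by both lookups and counts as **two** loci, i.e. multi-mapped —
  consistent with a two-strand alignment model; the case is
  astronomically rare for 25-mers and deterministic;
* overlapping occurrences (homopolymer-like probes) each count as one
  locus;
* genomic windows containing N are never indexed, and probes containing
  non-ACGT characters are classified unmapped rather than erroring.

MM probes never enter the mapper; they are re-attached to their PM
partners only when the CDF is assembled (default convention: the MM
probe occupies the cell directly below its PM, `(x, y+1)`; an explicit
MM column in the probe table is also supported).

## Containment queries: nested containment list

Features of each chromosome are stored in a nested containment list:
intervals sorted by (start ascending, end descending), with every
interval that is contained in a predecessor nested in that
predecessor's sublist. Within any sibling list no interval contains a
later sibling, which forces sibling starts *and* ends to be strictly
increasing — so a containment query (find all F with
`F.start ≤ q.start` and `q.end ≤ F.end`) is a binary search for the
last sibling starting at or before the query, a backward walk over the
suffix whose ends still reach the query end, and a descent **only**
into sublists whose parent contains the query. Equal-coordinate
duplicates (the same exon listed for several transcripts) are all
retained and nest deterministically under the tie-break key
(start, −end, feature class, gene id, transcript id); the same key
orders query output, making every downstream "first annotation" choice
reproducible. The structure answers containment only — generic overlap
queries are not implemented, because the annotation step never needs
them.

## Annotation policies

**Region classes.** Region mode keeps UTR5/UTR3, CDS and exon intervals.
"Individual exon" denotes the non-UTR exon signal: exons of structural
RNAs, and exon-contained probes of coding genes that are in neither a
UTR nor a CDS (e.g. probes straddling the CDS/UTR boundary inside one
exon).

**Priority.** UTR assignments always beat the exon features that
enclose them (the UTR is the more specific call). For the remaining
classes there is a genuine design choice: since CDS intervals are
nested inside exon intervals in Ensembl annotations, every
CDS-contained probe is also exon-contained, and a literal
UTR > exon > CDS priority would leave CDS probe sets empty. The default
policy therefore orders **UTR > CDS > exon**, which yields three
populated, effectively disjoint region classes; the literal
UTR > exon > CDS order remains available via
`AnnotationConfig(priority="utr_exon_cds")` and is exercised by the
tests. Both UTR flavours share the `_UTR_` name suffix; the 5′/3′
identity is preserved in the sidecar annotation table.

**Cross-gene probes.** A probe contained in features of two genes keeps
the first gene under the deterministic candidate ordering
(`keep_first`, default) or is discarded entirely
(`cross_gene="discard"`); both policies are first-class because either
is defensible — keeping maximises probe usage, discarding minimises
cross-hybridisation ambiguity.

**Gene mode.** Gene-level keys are *derived* from the region-level
resolution (the gene id of the chosen region feature), so a probe is
annotated at gene level iff it is annotated at region level and the
probes-used counts of the two CDFs coincide; this also keeps partial
region overlaps excluded at the gene level. A literal
gene-span-containment mode is available via
`AnnotationConfig(gene_mode="span")`.

**Strand.** Containment is coordinate-only; the chosen feature's
annotated strand is recorded and used in probe-set names. An opt-in
filter (`require_strand_match`) demands the mapped strand equal the
feature strand.

## Probe-set assembly

One probe set per distinct target key; members ordered by chromosomal
start then grid position; one CDF unit with one block per probe set,
units name-sorted with controls last and numbered contiguously from 1 —
all purely for byte-deterministic output. The minimum-member filter
counts **PM probes only** (the PM probe is the grouping unit; MM probes
are passengers); `min_members=1` is the unrestricted grouping,
`min_members=3` the restricted one recommended against small-set false
positives. Control units (name pattern `^AFFX` by default) are copied
verbatim from the original CDF, with name- and cell-collision checks.
Chip dimensions come from the original CDF when given, else from
configuration; having neither is an error.

The ASCII CDF writer emits the GC3.0-style section layout (`[CDF]`,
`[Chip]`, `[UnitN]`, `[UnitN_BlockM]`, `CellHeader`/`CellK=` lines) with
fixed key order, LF endings and integer formatting, so writing the same
model twice is byte-identical and write→read→write is byte-idempotent.
Cells carry the probe/target base characters at the interrogation
position (complementary for PM, equal for MM — the standard convention
by which the two roles are distinguished). Binary (XDA) CDF encoding is
out of scope.

## The synthetic fixture generator

`recdf.fixtures` emulates exactly the situations the pipeline must
distinguish. The default fixture is 2 chromosomes × 50 kb of i.i.d.
bases at GC 0.5, 12 genes and 260 PM probes (plus 260 MM rows) — sized
so the full pipeline and its exhaustive oracles run in well under a
second while every branch stays populated.

Genes cycle through five templates on alternating strands: a
multi-transcript coding gene (a second transcript re-lists a truncated
exon subset), a coding gene hosting a nested antisense single-exon
structural-RNA gene inside its 3′ UTR (the cross-gene zone), two plain
coding genes, and a standalone two-exon structural-RNA gene. Coding
genes have fixed block lengths (150 nt 5′ UTR, CDS exons of 200/250/200
nt, 300 nt introns, 450 nt 3′ UTR) — regular by design, since the
containment logic is insensitive to length variation and fixed blocks
make every planting zone predictably wide enough for 25-mers.

Probes are planted per truth label: copied from UTR5/UTR3/CDS interiors
and structural-RNA exons (verified unique), from introns (unique,
contained in no region feature but in a transcript span), across exon
junctions (the spliced chimera verified absent from both strands),
duplicated into intergenic space (the only planting that edits the
genome, done before any verification so all checks run against the
final sequence), random non-genomic 25-mers (verified absent), inside
the nested gene's exon (candidates span two genes), and straddling the
CDS/UTR boundary within one exon (exon-only containment). Half the
probes, at random, are stored as the reverse complement of their
genomic window, exercising minus-strand mapping. Expected target keys
are computed from the *actual* containment candidates (via the
brute-force oracles, not the NCList) under a restatement of the
resolution rules, for the default policy and for both alternative
policies — the generator never trusts its own planting, and an
unsatisfiable label raises instead of relabeling.

What the fixtures do **not** emulate: repeat families and paralogy
(multi-mapping arises only where planted), GC heterogeneity and N runs,
realistic exon/intron length distributions, overlapping gene dense
regions beyond the single nested template, and probe intensity data.
Passing tests therefore demonstrate the correctness of the mapping,
containment, resolution and emission logic — not mapping-rate or
census values on any real chip/genome pair, which depend entirely on
the external assembly and annotation versions.

## Numerical and degenerate-input choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give byte-identical bundles and CDFs.
* Ties everywhere (NCList nesting, candidate order, probe-set member
  order, unit order) are broken by stated sort keys, never by dict or
  hash order.
* Degenerate inputs: empty GTF → everything discarded at annotation;
  empty probe-set list → a valid 0-unit CDF; k longer than every
  chromosome → empty index with a warning; probe with N → unmapped;
  MM probe passed to the mapper → error (caller contract).
* The probe-table column dialect is configuration (NetAffx-style
  defaults) because exports vary in header wording.

## Problem sizes used by the test and acceptance runs

Oracle-equivalence sweeps use 20 random fixtures of up to ~100 kb of
genome and up to 1,500 probes for the mapper, and 20 random sets of up
to 1,000 intervals × 1,000 containment queries for the NCList, checked
against brute force; invariant checks use 10 regenerated default-size
fixtures. These sizes keep the whole suite under half a minute while
leaving every code path exercised at realistic nesting depths.
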