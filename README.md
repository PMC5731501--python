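# recdf

Reannotate Affymetrix® GeneChip® probes against a current genome assembly
and regroup them into **region-based** (3′/5′ UTR, individual exon, CDS),
**gene-based** and **transcript-based** probe sets, emitted as ASCII Chip
Description Files (CDF).

Expression arrays carry 25-mer perfect-match (PM) probes grouped into
probe sets that were fixed at design time, against genome assemblies and
annotations that are now many releases old. Probes that no longer match
the genome, match multiple loci, or target a different gene than their
original probe set inflate false positives; and the original grouping
cannot separate signals from functional regions of a transcript — in
particular 3′ UTRs, whose length diversity under alternative
polyadenylation has phenotypic consequences. `recdf` is for anyone
reanalysing public GeneChip data (GEO/ArrayExpress CEL files) who wants
probe sets defined by current annotation, down to the region level.

## Method

Given a genome FASTA, an Ensembl-dialect GTF and the PM probe table of a
chip, the pipeline is:

1. **Exact mapping.** Each PM probe is classified by its number of exact
   genomic loci over both strands (the `bowtie -v 0 -m 1` semantics,
   implemented as a hash index of genomic k-mers): exactly one locus →
   *uniquely mapped* (kept), two or more → *multi-mapped* (dropped),
   none → *unmapped* (dropped; probes spanning splice junctions fall
   here, since only contiguous genomic matches are considered). MM
   probes are set aside and re-attached to their PM partners at CDF
   construction.
2. **Containment annotation.** For each chromosome a *nested containment
   list* (NCList) is built from the mode-relevant intervals — UTR,
   individual-exon and CDS intervals for region mode; gene or transcript
   spans otherwise. A probe is annotated only by features that contain
   **both** ends of its hit interval; partial overlaps are discarded at
   the region and gene level (they may survive at the transcript level,
   e.g. intronic or junction-flanking probes inside a transcript span).
3. **One annotation per probe.** When several features contain a probe,
   UTR assignments win over the enclosing exon; CDS-contained probes go
   to the CDS class by default (see `docs/methods.md` for the priority
   discussion); probes contained in genes' overlapping regions keep the
   first annotation under a deterministic ordering (or are discarded,
   by configuration).
4. **Grouping and emission.** Probes sharing a target key form a probe
   set, named `<ENSG>_<UTR|exon|CDS>_<+|->` in region mode and by the
   bare Ensembl gene/transcript id otherwise. Probe sets below a
   minimum PM count can be filtered (unrestricted ≥ 1 and restricted
   ≥ 3 groupings are both supported), control (AFFX) probe sets from
   the original CDF are copied verbatim, and the result is written as a
   deterministic, round-trippable ASCII CDF.

A deterministic synthetic-fixture generator (`recdf.fixtures`) produces
a genome, annotation, probe table, controls-only original CDF and a
verified ground truth covering every pipeline branch, so the whole tool
is testable without any external download.

## Worked example

Generate a synthetic bundle (2 chromosomes × 50 kb, 12 genes, 260 PM +
260 MM probes) and run the full pipeline:

```sh
recdf simulate --seed 7 --outdir fix
recdf make-cdf \
    --genome fix/genome.fa --gtf fix/annotation.gtf \
    --probe-tab fix/probes.tsv --original-cdf fix/original.cdf \
    --col-kind "Probe Kind" --mode all --outdir out
```

which prints:

```
PM probes: 260  unique: 180  multi: 20  unmapped: 60
region: 150 probes annotated, 23 probe sets (+3 controls), 6.52 probes/set
gene: 150 probes annotated, 10 probe sets (+3 controls), 15.0 probes/set
transcript: 180 probes annotated, 10 probe sets (+3 controls), 18.0 probes/set
```

Of the 260 PM probes, 180 map to exactly one genomic locus; 20 were
planted at two loci (multi-mapped) and 60 either match nothing or span
a splice junction. Of the 180 unique probes, 150 are fully contained in
a UTR/exon/CDS interval and are grouped into 23 region probe sets
(10 genes after collapsing regions — note the identical 150 probes used
at region and gene level); the transcript CDF additionally captures the
30 intronic probes contained in transcript spans. `out/` holds one
ASCII CDF per mode plus annotation, mapping-audit and probe-set summary
TSVs and a JSON run report with the counts at every stage.

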