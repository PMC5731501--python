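"""Resolve uniquely mapped probes into per-mode annotations.

A probe's genomic interval is queried against per-chromosome NCLists of
the mode-relevant features; only features that completely contain the
probe count (a probe partially overlapping a UTR, individual exon or CDS
is dropped at the region and gene level, though its transcript span may
still contain it).  When several features contain a probe, one annotation
is chosen and the rest removed, so every annotated probe carries exactly
one target key.

Region-class disambiguation: UTR assignments always win over the exon
features that enclose them.  Because CDS intervals are themselves nested
inside exon intervals, a literal UTR > exon > CDS priority would leave
every CDS-contained probe assigned to the exon class; the default policy
therefore orders UTR > CDS > exon, which yields the three effectively
disjoint region classes (UTR / CDS / individual exon, where "individual
exon" captures exon-only containment — exons of structural RNAs and
probes straddling intra-exon class boundaries).  The literal order
remains available via :class:`AnnotationConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

from .formats import Feature
from .mapper import MappingResult, ProbeHit
from .nclist import NCList, build_nclist

logger = logging.getLogger(__name__)

MODES = ("region", "gene", "transcript")

#: Region classes used in probe-set naming.
REGION_CLASSES = ("UTR", "exon", "CDS")

#: target key types: region -> (gene_id, region_class, strand);
#: gene -> gene_id; transcript -> transcript_id.
TargetKey = Union[tuple[str, str, str], str]


@dataclass(frozen=True)
class ProbeAnnotation:
    """One resolved probe -> target link for a given mode.

    ``region_detail`` preserves the 5'/3' identity of UTR assignments
    (probe-set names collapse both to "UTR"; the sidecar annotation table
    keeps the distinction).
    """

    hit: ProbeHit
    mode: str
    target_key: TargetKey
    feature: Feature
    region_detail: Optional[str] = None


@dataclass
class AnnotationConfig:
    """Policy knobs for annotation resolution.

    priority
        "utr_cds_exon" (default) or "utr_exon_cds" (the literal order).
    cross_gene
        "keep_first": when a probe is contained in features of several
        genes, keep the first gene under the deterministic candidate
        ordering; "discard": drop such probes entirely.
    gene_mode
        "derived" (default): gene-level keys are the gene ids of the
        region-level resolution, so partial-region probes are excluded at
        both levels and gene/region probes-used counts coincide;
        "span": literal containment in gene span features.
    require_strand_match
        Opt-in filter demanding the mapped strand equal the feature strand.
    """

    priority: str = "utr_cds_exon"
    cross_gene: str = "keep_first"
    gene_mode: str = "derived"
    require_strand_match: bool = False


DISCARD = None  # sentinel: probe resolves to no annotation


def extract_region_intervals(features: list[Feature], mode: str) -> list[Feature]:
    """Keep the feature classes relevant to a mode.

    region mode: UTR5/UTR3, CDS and exon features (exons serve as
    "individual exon" candidates); gene / transcript modes: the
    corresponding span features only.
    """
    if mode == "region":
        keep = {"UTR5", "UTR3", "CDS", "exon"}
    elif mode == "gene":
        keep = {"gene"}
    elif mode == "transcript":
        keep = {"transcript"}
    else:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    return [f for f in features if f.feature_class in keep]


def resolve_annotation(candidates: list[Feature], mode: str,
                       config: Optional[AnnotationConfig] = None,
                       ) -> Optional[tuple[TargetKey, Feature, Optional[str]]]:
    """Choose one annotation from the containing candidates, or DISCARD.

    ``candidates`` must already be in the deterministic NCList result
    order (start asc, end desc, class, gene id, transcript id).  Returns
    (target_key, chosen_feature, region_detail) or None.
    """
    config = config or AnnotationConfig()
    if not candidates:
        return DISCARD

    if mode == "transcript":
        first = candidates[0]
        return (first.transcript_id, first, None)
    if mode == "gene" and config.gene_mode == "span":
        first = candidates[0]
        return (first.gene_id, first, None)

    # region mode (gene mode "derived" resolves through it upstream)
    genes_in_order: list[str] = []
    for f in candidates:
        if f.gene_id not in genes_in_order:
            genes_in_order.append(f.gene_id)
    if len(genes_in_order) > 1 and config.cross_gene == "discard":
        return DISCARD
    gene = genes_in_order[0]
    mine = [f for f in candidates if f.gene_id == gene]

    utr = [f for f in mine if f.feature_class in ("UTR5", "UTR3")]
    cds = [f for f in mine if f.feature_class == "CDS"]
    exon = [f for f in mine if f.feature_class == "exon"]
    if utr:
        chosen, cls, detail = utr[0], "UTR", utr[0].feature_class
    elif config.priority == "utr_cds_exon":
        chosen, cls = (cds[0], "CDS") if cds else (exon[0], "exon")
        detail = None
    elif config.priority == "utr_exon_cds":
        chosen, cls = (exon[0], "exon") if exon else (cds[0], "CDS")
        detail = None
    else:
        raise ValueError(f"unknown priority policy {config.priority!r}")
    key = (gene, cls, chosen.strand)
    if mode == "gene":
        return (gene, chosen, detail)
    return (key, chosen, detail)


def annotate_probes(hits: dict, features: list[Feature], mode: str,
                    config: Optional[AnnotationConfig] = None,
                    ) -> list[ProbeAnnotation]:
    """Annotate uniquely mapped probes for one mode.

    ``hits`` is ``MappingResult.unique_hits`` (probe -> ProbeHit).  Builds
    one NCList per chromosome from the mode-relevant features, queries
    each probe's interval for complete containment, resolves one
    annotation per probe and omits DISCARDed probes.  Hits on chromosomes
    absent from the annotation are discarded with a log entry.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    config = config or AnnotationConfig()
    if isinstance(hits, MappingResult):
        hits = hits.unique_hits

    effective = "region" if (mode == "gene" and config.gene_mode == "derived") else mode
    relevant = extract_region_intervals(features, effective)
    by_chrom: dict[str, list[Feature]] = {}
    for f in relevant:
        by_chrom.setdefault(f.chrom, []).append(f)
    nclists: dict[str, NCList] = {c: build_nclist(fs) for c, fs in by_chrom.items()}

    annotations: list[ProbeAnnotation] = []
    ordered = sorted(hits.values(),
                     key=lambda h: (h.chrom, h.start, h.probe.x, h.probe.y))
    for hit in ordered:
        nc = nclists.get(hit.chrom)
        if nc is None:
            logger.info("probe at (%d, %d): chromosome %s absent from "
                        "annotation; discarded", hit.probe.x, hit.probe.y,
                        hit.chrom)
            continue
        candidates = nc.query_contained(hit.start, hit.end)
        if config.require_strand_match:
            candidates = [f for f in candidates if f.strand == hit.strand]
        resolved = resolve_annotation(candidates, mode, config)
        if resolved is DISCARD:
            continue
        key, feature, detail = resolved
        annotations.append(ProbeAnnotation(hit, mode, key, feature, detail))
    return annotations


def write_annotation_tsv(annotations: list[ProbeAnnotation], path) -> None:
    """Sidecar export: probe, mode, target key and containing feature."""
    with open(path, "w") as fh:
        fh.write("probeset_id\tx\ty\tmode\ttarget_key\tregion_detail\t"
                 "feature_chrom\tfeature_start\tfeature_end\tfeature_strand\n")
        for a in annotations:
            key = "_".join(a.target_key) if isinstance(a.target_key, tuple) \
                else a.target_key
            fh.write("\t".join(str(v) for v in (
                a.hit.probe.origin_probeset_id, a.hit.probe.x, a.hit.probe.y,
                a.mode, key, a.region_detail or "",
                a.feature.chrom, a.feature.start, a.feature.end,
                a.feature.strand)) + "\n")
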