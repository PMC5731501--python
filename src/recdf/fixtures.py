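"""Deterministic synthetic fixtures exercising every pipeline branch.

The generator emits a random genome, an Ensembl-dialect gene annotation,
a probe table and a controls-only "original" CDF, together with a
machine-readable ground truth (:class:`FixtureTruth`) stating, for every
planted probe, its mapping class, its genomic locus and its expected
target key in each mode.  Probes are planted for every branch the
pipeline distinguishes: uniquely mapping probes inside 5'/3' UTRs, CDS
and structural-RNA exons, intronic probes (transcript level only),
splice-junction probes (never contiguous in the genome, hence unmapped),
multi-copy probes, probes absent from the genome, probes inside two
overlapping genes, and probes straddling the CDS/UTR boundary within one
exon.

Truth is computed constructively at generation time and re-verified with
the exhaustive oracles (:func:`oracle_scan`, :func:`oracle_contained`)
before emission — the generator never trusts its own planting.  If a
label cannot be satisfied the generator errors; it never relabels
silently.

What this emulates and what it does not: gene structures are regular
(fixed-length UTR/CDS/intron blocks with jittered placement), base
composition is i.i.d., and probe grids are filled row-major — none of the
repeat structure, paralogy or GC heterogeneity of a real genome.  The
fixtures establish algorithmic correctness of mapping, containment and
grouping, not performance on genome-scale inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .formats import (CDFBlock, CDFCell, CDFModel, CDFUnit, Feature,
                      GenomeSequence, ProbeRecord, ProbeTabDialect, revcomp,
                      write_fasta, write_gtf, write_probe_tab, write_cdf_ascii)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Truth labels; every one is non-empty in the default design.
LABELS = ("unique_in_UTR5", "unique_in_UTR3", "unique_in_CDS",
          "unique_in_exon", "intronic", "junction", "multi_mapped",
          "unmapped", "cross_gene", "multi_feature")

#: Column mapping used by the emitted probe tables (MM rows are explicit).
FIXTURE_DIALECT = ProbeTabDialect(kind_col="Probe Kind")


class FixtureError(RuntimeError):
    """A requested planting cannot be satisfied."""


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def oracle_scan(genome: GenomeSequence, sequence: str,
                ) -> list[tuple[str, int, int, str]]:
    """Every exact locus of ``sequence`` over both strands.

    Equivalent to scanning each length-|sequence| window of every
    chromosome on both strands; implemented with substring search of the
    sequence and its reverse complement, which enumerates the same set.
    A self-reverse-complementary sequence yields two loci (one per
    strand) at the same coordinates.
    """
    k = len(sequence)
    rc = revcomp(sequence)
    loci: list[tuple[str, int, int, str]] = []
    for chrom, seq in genome.chroms.items():
        for query, strand in ((sequence, "+"), (rc, "-")):
            i = seq.find(query)
            while i != -1:
                loci.append((chrom, i + 1, i + k, strand))
                i = seq.find(query, i + 1)
    loci.sort()
    return loci


def oracle_contained(features: list[Feature], chrom: str, start: int,
                     end: int) -> list[Feature]:
    """Brute-force containment filter: F.start <= start and end <= F.end."""
    out = [f for f in features
           if f.chrom == chrom and f.start <= start and end <= f.end]
    out.sort(key=_order_key)
    return out


def _order_key(f: Feature):
    # candidate ordering restated for truth computation: start ascending,
    # end descending, then feature identity
    return (f.start, -f.end, f.feature_class, f.gene_id, f.transcript_id or "")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(n_chroms: int = 2, chrom_len: int = 50_000,
                    gc: float = 0.5, seed: int = 0) -> GenomeSequence:
    """Random genome with i.i.d. bases at the requested GC fraction.

    Reproducible: the same seed yields byte-identical sequences.  For
    chromosomes of at least ~10 kb the realized GC fraction lands within
    a few percent of ``gc``.
    """
    if n_chroms < 1:
        raise FixtureError(f"n_chroms must be >= 1, got {n_chroms}")
    if chrom_len < 100:
        raise FixtureError(f"chrom_len must be >= 100, got {chrom_len}")
    if not 0.0 < gc < 1.0:
        raise FixtureError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    genome = GenomeSequence()
    for i in range(n_chroms):
        seq = "".join(rng.choice(bases, size=chrom_len, p=p))
        genome.add(f"chr{i + 1}", seq)
    return genome


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

# transcription-order block lengths of a synthetic coding gene
_CODING_BLOCKS = (("UTR5", 150), ("CDS", 200), ("intron", 300), ("CDS", 250),
                  ("intron", 300), ("CDS", 200), ("UTR3", 450))
_NONCODING_BLOCKS = (("exon", 400), ("intron", 300), ("exon", 350))

_NESTED_EXON_LEN = 250
_NESTED_OFFSET = 100  # genomic offset of the nested gene inside the 3' UTR


def _span(blocks) -> int:
    return sum(n for _, n in blocks)


def _lay_out_gene(chrom: str, start: int, strand: str, gene_id: str,
                  transcript_ids: list[str], blocks) -> list[Feature]:
    """Emit gene/transcript/exon/CDS/UTR features for one gene.

    ``blocks`` are (class, length) in transcription order; for minus-strand
    genes the genomic layout is the reverse, so the 5' UTR sits genomically
    right of the CDS.  Additional transcript ids get progressively
    truncated transcripts (dropping trailing transcription-order exons)
    that re-list the shared exon coordinates, emulating multi-transcript
    genes without extra sequence.
    """
    genomic = blocks if strand == "+" else tuple(reversed(blocks))
    pos = start
    segments: list[tuple[str, int, int]] = []  # (class, start, end) genomic
    for cls, length in genomic:
        segments.append((cls, pos, pos + length - 1))
        pos += length
    end = pos - 1

    # exons: maximal runs of non-intron segments
    exons: list[tuple[int, int]] = []
    for cls, s, e in segments:
        if cls == "intron":
            continue
        if exons and exons[-1][1] == s - 1:
            exons[-1] = (exons[-1][0], e)
        else:
            exons.append((s, e))
    # transcription order of exons
    tx_exons = exons if strand == "+" else list(reversed(exons))

    t1 = transcript_ids[0]
    feats = [Feature(chrom, start, end, strand, "gene", gene_id),
             Feature(chrom, start, end, strand, "transcript", gene_id, t1)]
    for s, e in exons:
        feats.append(Feature(chrom, s, e, strand, "exon", gene_id, t1))
    for cls, s, e in segments:
        if cls in ("UTR5", "UTR3", "CDS"):
            feats.append(Feature(chrom, s, e, strand, cls, gene_id, t1))

    for j, tid in enumerate(transcript_ids[1:], start=1):
        keep = tx_exons[: max(len(tx_exons) - j, 1)]
        s = min(x[0] for x in keep)
        e = max(x[1] for x in keep)
        feats.append(Feature(chrom, s, e, strand, "transcript", gene_id, tid))
        for xs, xe in keep:
            feats.append(Feature(chrom, xs, xe, strand, "exon", gene_id, tid))
    return feats


def simulate_annotation(genome: GenomeSequence, n_genes: int = 12,
                        transcripts_per_gene: int = 2,
                        seed: int = 0) -> list[Feature]:
    """Plant gene models on the genome and return their features.

    Genes cycle through five templates: a multi-transcript coding gene, a
    coding gene hosting a nested antisense structural-RNA gene inside its
    3' UTR (the cross-gene ambiguity zone), two plain coding genes and a
    standalone two-exon structural-RNA gene.  Both strands are used.
    Genes are laid out in non-overlapping slots (except the deliberate
    nesting); an error is raised if the genome cannot host them.
    """
    if n_genes < 1:
        raise FixtureError(f"n_genes must be >= 1, got {n_genes}")
    if transcripts_per_gene < 1:
        raise FixtureError("transcripts_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = list(genome.chroms)
    margin = 600
    templates = ("coding_multi", "coding_nested", "coding", "noncoding",
                 "coding")

    # count hosts (a nested template yields 2 genes)
    hosts: list[str] = []
    made = 0
    i = 0
    while made < n_genes:
        t = templates[i % len(templates)]
        if t == "coding_nested" and made + 2 > n_genes:
            t = "coding"
        hosts.append(t)
        made += 2 if t == "coding_nested" else 1
        i += 1

    per_chrom = [len([h for j, h in enumerate(hosts) if j % len(chroms) == c])
                 for c in range(len(chroms))]
    features: list[Feature] = []
    gene_n = 0
    tx_n = 0

    def next_gene() -> str:
        nonlocal gene_n
        gene_n += 1
        return f"ENSG{gene_n:011d}"

    def next_tx() -> str:
        nonlocal tx_n
        tx_n += 1
        return f"ENST{tx_n:011d}"

    slot_idx = [0] * len(chroms)
    for j, template in enumerate(hosts):
        c = j % len(chroms)
        chrom = chroms[c]
        clen = len(genome[chrom])
        nslots = max(per_chrom[c], 1)
        slot_w = (clen - 2 * margin) // nslots
        blocks = _NONCODING_BLOCKS if template == "noncoding" else _CODING_BLOCKS
        span = _span(blocks)
        if slot_w < span + 100:
            raise FixtureError(
                f"chromosome {chrom} ({clen} bp) too short for {nslots} "
                f"gene slots of >= {span + 100} bp")
        jitter = int(rng.integers(0, slot_w - span - 50))
        start = margin + slot_idx[c] * slot_w + jitter
        slot_idx[c] += 1
        strand = "+" if (j % 2 == 0) else "-"

        gid = next_gene()
        if template == "coding_multi":
            n_tx = min(max(transcripts_per_gene, 1), 3)
            tids = [next_tx() for _ in range(n_tx)]
        else:
            tids = [next_tx()]
        feats = _lay_out_gene(chrom, start, strand, gid, tids, blocks)
        features.extend(feats)

        if template == "coding_nested":
            utr3 = next(f for f in feats if f.feature_class == "UTR3")
            ns = utr3.start + _NESTED_OFFSET
            ne = ns + _NESTED_EXON_LEN - 1
            if ne > utr3.end:
                raise FixtureError("3' UTR too short to host a nested gene")
            ngid = next_gene()
            ntid = next_tx()
            nstrand = "-" if strand == "+" else "+"
            features.append(Feature(chrom, ns, ne, nstrand, "gene", ngid))
            features.append(Feature(chrom, ns, ne, nstrand, "transcript",
                                    ngid, ntid))
            features.append(Feature(chrom, ns, ne, nstrand, "exon", ngid, ntid))
    return features


# ---------------------------------------------------------------------------
# Probes and truth
# ---------------------------------------------------------------------------

@dataclass
class ProbeDesign:
    """Counts per truth label plus chip-layout parameters."""

    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    probe_length: int = 25
    with_mm: bool = True
    cols: int = 60
    interrogation_position: int = 13


DEFAULT_COUNTS = {
    "unique_in_UTR5": 20, "unique_in_UTR3": 40, "unique_in_CDS": 40,
    "unique_in_exon": 30, "intronic": 30, "junction": 20,
    "multi_mapped": 20, "unmapped": 40, "cross_gene": 10,
    "multi_feature": 10,
}


@dataclass
class FixtureTruth:
    """Ground truth for one fixture: per-probe labels and expected keys.

    ``probes`` maps "x:y" of each PM probe to a dict with its label,
    expected mapping class, genomic hit and expected target key per mode
    (region under both priority policies and under the cross-gene discard
    policy, derived gene mode, transcript mode).  Region keys are stored
    as [gene_id, region_class, strand] triples.
    """

    chip_rows: int
    chip_cols: int
    probe_length: int
    probes: dict = field(default_factory=dict)

    def census(self, mode: str, min_members: int = 1,
               key_field: Optional[str] = None) -> dict[str, int]:
        """Expected probe-set census: probe-set name -> PM member count."""
        key_field = key_field or mode
        counts: dict[str, int] = {}
        for rec in self.probes.values():
            key = rec["keys"].get(key_field)
            if key is None:
                continue
            name = "_".join(key) if isinstance(key, list) else key
            counts[name] = counts.get(name, 0) + 1
        return {n: c for n, c in counts.items() if c >= min_members}

    def labels_present(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.probes.values():
            out[rec["label"]] = out.get(rec["label"], 0) + 1
        return out

    def to_json(self, path) -> None:
        payload = {"chip_rows": self.chip_rows, "chip_cols": self.chip_cols,
                   "probe_length": self.probe_length, "probes": self.probes}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "FixtureTruth":
        d = json.loads(Path(path).read_text())
        return cls(chip_rows=d["chip_rows"], chip_cols=d["chip_cols"],
                   probe_length=d["probe_length"], probes=d["probes"])


def _expected_region_key(cands: list[Feature], priority: str,
                         cross_gene: str) -> Optional[list]:
    """Truth-side restatement of the region resolution rule."""
    if not cands:
        return None
    genes: list[str] = []
    for f in cands:
        if f.gene_id not in genes:
            genes.append(f.gene_id)
    if len(genes) > 1 and cross_gene == "discard":
        return None
    mine = [f for f in cands if f.gene_id == genes[0]]
    utr = [f for f in mine if f.feature_class in ("UTR5", "UTR3")]
    cds = [f for f in mine if f.feature_class == "CDS"]
    exon = [f for f in mine if f.feature_class == "exon"]
    if utr:
        chosen, cls = utr[0], "UTR"
    elif priority == "utr_cds_exon":
        chosen, cls = (cds[0], "CDS") if cds else (exon[0], "exon")
    else:
        chosen, cls = (exon[0], "exon") if exon else (cds[0], "CDS")
    return [genes[0], cls, chosen.strand]


def _gene_structures(features: list[Feature]):
    """Index features by gene and classify gene templates."""
    by_gene: dict[str, dict] = {}
    for f in features:
        g = by_gene.setdefault(f.gene_id, {"features": [], "gene": None})
        g["features"].append(f)
        if f.feature_class == "gene":
            g["gene"] = f
    spans = {gid: g["gene"] for gid, g in by_gene.items()}
    for gid, g in by_gene.items():
        gf = g["gene"]
        g["coding"] = any(f.feature_class == "CDS" for f in g["features"])
        g["nested"] = any(
            o.chrom == gf.chrom and o.start <= gf.start and gf.end <= o.end
            for og, o in spans.items() if og != gid)
        g["hosts_nested"] = any(
            o.chrom == gf.chrom and gf.start <= o.start and o.end <= gf.end
            for og, o in spans.items() if og != gid)
    return by_gene


def simulate_probes(genome: GenomeSequence, features: list[Feature],
                    design: Optional[ProbeDesign] = None, seed: int = 0,
                    ) -> tuple[list[ProbeRecord], FixtureTruth]:
    """Plant the probe panel described by ``design`` and return its truth.

    Multi-copy probes require a second genomic occurrence, so intergenic
    bases are overwritten in place (inside ``genome``) before any
    verification; every subsequent check runs against the final sequence.
    Each planted probe is verified with :func:`oracle_scan` (locus count)
    and :func:`oracle_contained` (expected candidates) before emission;
    an unsatisfiable label raises :class:`FixtureError`.
    """
    design = design or ProbeDesign()
    k = design.probe_length
    rng = np.random.default_rng(seed)

    by_gene = _gene_structures(features)
    region_feats = [f for f in features
                    if f.feature_class in ("UTR5", "UTR3", "CDS", "exon")]
    tx_feats = [f for f in features if f.feature_class == "transcript"]
    gene_feats = [f for f in features if f.feature_class == "gene"]

    # ---- intergenic space (for multi-copy planting) ----------------------
    pad = 60
    intergenic: list[tuple[str, int, int]] = []
    for chrom in genome:
        clen = len(genome[chrom])
        spans = sorted((g.start, g.end) for g in gene_feats if g.chrom == chrom)
        cursor = 200
        for s, e in spans:
            if s - pad - cursor >= k + 10:
                intergenic.append((chrom, cursor, s - pad))
            cursor = e + pad
        if clen - 200 - cursor >= k + 10:
            intergenic.append((chrom, cursor, clen - 200))
    reserved: list[tuple[str, int, int]] = []

    def reserve_window(length: int) -> tuple[str, int]:
        for _ in range(200):
            ci = int(rng.integers(0, len(intergenic)))
            chrom, lo, hi = intergenic[ci]
            if hi - lo + 1 < length:
                continue
            s = int(rng.integers(lo, hi - length + 2))
            win = (chrom, s, s + length - 1)
            if any(c == chrom and not (we < s or ws > s + length - 1)
                   for c, ws, we in reserved):
                continue
            reserved.append(win)
            return chrom, s
        raise FixtureError("no intergenic space left for planting")

    # ---- phase A: mutate genome to host multi-copy probes ----------------
    n_multi = design.counts.get("multi_mapped", 0)
    multi_seqs: list[str] = []
    for _ in range(n_multi):
        c1, s1 = reserve_window(k)
        seq = genome.fetch(c1, s1, s1 + k - 1)
        c2, s2 = reserve_window(k)
        chrom_seq = genome.chroms[c2]
        genome.chroms[c2] = (chrom_seq[: s2 - 1] + seq
                             + chrom_seq[s2 - 1 + k :])
        multi_seqs.append(seq)

    # ---- planting helpers ------------------------------------------------
    planted: list[dict] = []  # {label, sequence, hit|None}
    used_seqs: set[str] = set()

    def flip(seq: str) -> tuple[str, str]:
        """Randomly present the probe as the minus-strand match."""
        if rng.integers(0, 2):
            return revcomp(seq), "-"
        return seq, "+"

    def region_classes(chrom: str, start: int, end: int) -> Optional[list]:
        cands = oracle_contained(region_feats, chrom, start, end)
        return _expected_region_key(cands, "utr_cds_exon", "keep_first"), cands

    def plant_unique(label: str, count: int, pools: list[Feature],
                     want_class: str, forbid_cross: bool = True) -> None:
        if count == 0:
            return
        if not pools:
            raise FixtureError(f"no candidate features for label {label}")
        for i in range(count):
            ok = False
            for _ in range(80):
                f = pools[int(rng.integers(0, len(pools)))]
                if f.length < k:
                    continue
                s = f.start + int(rng.integers(0, f.length - k + 1))
                e = s + k - 1
                seq = genome.fetch(f.chrom, s, e)
                if "N" in seq or seq in used_seqs:
                    continue
                loci = oracle_scan(genome, seq)
                if len(loci) != 1:
                    continue
                key, cands = region_classes(f.chrom, s, e)
                if key is None or key[1] != want_class:
                    continue
                genes = {c.gene_id for c in cands}
                if forbid_cross and len(genes) > 1:
                    continue
                probe_seq, strand = flip(seq)
                planted.append({"label": label, "sequence": probe_seq,
                                "hit": [f.chrom, s, e, strand]})
                used_seqs.add(seq)
                used_seqs.add(revcomp(seq))
                ok = True
                break
            if not ok:
                raise FixtureError(
                    f"could not plant probe {i + 1}/{count} for {label}")

    # unique probes inside each region class
    utr5 = [f for f in region_feats if f.feature_class == "UTR5"]
    utr3 = [f for f in region_feats if f.feature_class == "UTR3"]
    cds = [f for f in region_feats if f.feature_class == "CDS"]
    nc_exons = [f for f in region_feats
                if f.feature_class == "exon"
                and not by_gene[f.gene_id]["coding"]
                and not by_gene[f.gene_id]["nested"]]
    plant_unique("unique_in_UTR5", design.counts.get("unique_in_UTR5", 0),
                 utr5, "UTR")
    plant_unique("unique_in_UTR3", design.counts.get("unique_in_UTR3", 0),
                 utr3, "UTR")
    plant_unique("unique_in_CDS", design.counts.get("unique_in_CDS", 0),
                 cds, "CDS")
    plant_unique("unique_in_exon", design.counts.get("unique_in_exon", 0),
                 nc_exons, "exon")

    # intronic probes: inside a transcript span, in no region feature
    introns: list[tuple[str, int, int]] = []
    for gid, g in by_gene.items():
        if not g["coding"]:
            continue
        exons = sorted((f.start, f.end) for f in g["features"]
                       if f.feature_class == "exon")
        merged: list[list[int]] = []
        for s, e in exons:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        chrom = g["gene"].chrom
        for (_, pe), (ns, _) in zip(merged[:-1], merged[1:]):
            if (ns - 1) - (pe + 1) + 1 >= k + 4:
                introns.append((chrom, pe + 1, ns - 1))
    for i in range(design.counts.get("intronic", 0)):
        ok = False
        for _ in range(80):
            chrom, lo, hi = introns[int(rng.integers(0, len(introns)))]
            s = lo + int(rng.integers(0, hi - lo + 1 - k + 1))
            e = s + k - 1
            seq = genome.fetch(chrom, s, e)
            if seq in used_seqs:
                continue
            if len(oracle_scan(genome, seq)) != 1:
                continue
            if oracle_contained(region_feats, chrom, s, e):
                continue
            if not oracle_contained(tx_feats, chrom, s, e):
                continue
            probe_seq, strand = flip(seq)
            planted.append({"label": "intronic", "sequence": probe_seq,
                            "hit": [chrom, s, e, strand]})
            used_seqs.add(seq)
            used_seqs.add(revcomp(seq))
            ok = True
            break
        if not ok:
            raise FixtureError(f"could not plant intronic probe {i + 1}")

    # junction probes: spliced across genomically adjacent exons of a
    # transcript; the chimeric sequence must be absent from the genome
    junctions: list[tuple[str, int, int]] = []  # (chrom, left exon end, right exon start)
    for gid, g in by_gene.items():
        exon_sets: dict[str, list[tuple[int, int]]] = {}
        for f in g["features"]:
            if f.feature_class == "exon" and f.transcript_id:
                exon_sets.setdefault(f.transcript_id, []).append((f.start, f.end))
        for tid, exons in exon_sets.items():
            exons = sorted(set(exons))
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 > e1 + 1:
                    junctions.append((g["gene"].chrom, e1, s2))
    junctions = sorted(set(junctions))
    for i in range(design.counts.get("junction", 0)):
        ok = False
        for _ in range(80):
            chrom, e1, s2 = junctions[int(rng.integers(0, len(junctions)))]
            left = int(rng.integers(8, k - 8 + 1))  # bases taken left of the junction
            seq = (genome.fetch(chrom, e1 - left + 1, e1)
                   + genome.fetch(chrom, s2, s2 + (k - left) - 1))
            if seq in used_seqs or oracle_scan(genome, seq):
                continue
            probe_seq = revcomp(seq) if rng.integers(0, 2) else seq
            planted.append({"label": "junction", "sequence": probe_seq,
                            "hit": None})
            used_seqs.add(seq)
            used_seqs.add(revcomp(seq))
            ok = True
            break
        if not ok:
            raise FixtureError(f"could not plant junction probe {i + 1}")

    # multi-copy probes (sequence planted twice in phase A)
    for i, seq in enumerate(multi_seqs):
        if len(oracle_scan(genome, seq)) != 2:
            raise FixtureError(
                f"multi-copy probe {i + 1}: expected exactly 2 loci")
        planted.append({"label": "multi_mapped", "sequence": seq,
                        "hit": None})
        used_seqs.add(seq)
        used_seqs.add(revcomp(seq))

    # unmapped probes: random sequences verified absent
    bases = np.array(list("ACGT"))
    for i in range(design.counts.get("unmapped", 0)):
        ok = False
        for _ in range(80):
            seq = "".join(rng.choice(bases, size=k))
            if seq in used_seqs or oracle_scan(genome, seq):
                continue
            planted.append({"label": "unmapped", "sequence": seq,
                            "hit": None})
            used_seqs.add(seq)
            used_seqs.add(revcomp(seq))
            ok = True
            break
        if not ok:
            raise FixtureError(f"could not plant unmapped probe {i + 1}")

    # cross-gene probes: fully inside a nested gene's exon (itself inside
    # the host gene's 3' UTR) so candidates span two genes
    nested_exons = [f for f in region_feats
                    if f.feature_class == "exon" and by_gene[f.gene_id]["nested"]]
    if design.counts.get("cross_gene", 0) and not nested_exons:
        raise FixtureError("design requests cross_gene probes but the "
                           "annotation has no nested genes")
    for i in range(design.counts.get("cross_gene", 0)):
        ok = False
        for _ in range(80):
            f = nested_exons[int(rng.integers(0, len(nested_exons)))]
            s = f.start + int(rng.integers(0, f.length - k + 1))
            e = s + k - 1
            seq = genome.fetch(f.chrom, s, e)
            if seq in used_seqs or len(oracle_scan(genome, seq)) != 1:
                continue
            cands = oracle_contained(region_feats, f.chrom, s, e)
            if len({c.gene_id for c in cands}) < 2:
                continue
            probe_seq, strand = flip(seq)
            planted.append({"label": "cross_gene", "sequence": probe_seq,
                            "hit": [f.chrom, s, e, strand]})
            used_seqs.add(seq)
            used_seqs.add(revcomp(seq))
            ok = True
            break
        if not ok:
            raise FixtureError(f"could not plant cross_gene probe {i + 1}")

    # multi-feature probes: straddling the CDS/UTR boundary inside one
    # exon, so the only containing region feature is the exon itself
    boundary_zones: list[tuple[str, int, int]] = []
    for gid, g in by_gene.items():
        if not g["coding"] or g["hosts_nested"]:
            continue
        chrom = g["gene"].chrom
        exons = [(f.start, f.end) for f in g["features"]
                 if f.feature_class == "exon"]
        pieces = [f for f in g["features"]
                  if f.feature_class in ("UTR5", "UTR3", "CDS")]
        for a in pieces:
            for b in pieces:
                if a.end + 1 == b.start and a.feature_class != b.feature_class:
                    for xs, xe in exons:
                        if xs <= a.end and b.start <= xe:
                            boundary_zones.append((chrom, a.end, min(xe, b.end)))
    boundary_zones = sorted(set(boundary_zones))
    for i in range(design.counts.get("multi_feature", 0)):
        ok = False
        for _ in range(80):
            chrom, bnd, xe = boundary_zones[int(rng.integers(0, len(boundary_zones)))]
            lo = max(bnd - k + 2, 1)
            s = lo + int(rng.integers(0, bnd - lo + 1))
            e = s + k - 1
            if e <= bnd or e > xe:
                continue
            seq = genome.fetch(chrom, s, e)
            if seq in used_seqs or len(oracle_scan(genome, seq)) != 1:
                continue
            key, cands = region_classes(chrom, s, e)
            if key is None or key[1] != "exon":
                continue
            classes = {c.feature_class for c in cands}
            if classes != {"exon"}:
                continue
            probe_seq, strand = flip(seq)
            planted.append({"label": "multi_feature", "sequence": probe_seq,
                            "hit": [chrom, s, e, strand]})
            used_seqs.add(seq)
            used_seqs.add(revcomp(seq))
            ok = True
            break
        if not ok:
            raise FixtureError(f"could not plant multi_feature probe {i + 1}")

    # ---- grid assignment and truth ---------------------------------------
    cols = design.cols
    n = len(planted)
    probe_rows = 2 * ((n + cols - 1) // cols) if design.with_mm \
        else (n + cols - 1) // cols
    records: list[ProbeRecord] = []
    truth = FixtureTruth(chip_rows=probe_rows, chip_cols=cols, probe_length=k)
    ipos = design.interrogation_position
    for i, p in enumerate(planted):
        x = i % cols
        y = (2 * (i // cols)) if design.with_mm else (i // cols)
        pid = f"syn_{p['label']}_{i:04d}_at"
        pm = ProbeRecord(pid, x, y, p["sequence"], ipos, "PM")
        records.append(pm)
        if design.with_mm:
            off = ipos - 1
            mseq = (p["sequence"][:off] + _COMP[p["sequence"][off]]
                    + p["sequence"][off + 1 :])
            records.append(ProbeRecord(pid, x, y + 1, mseq, ipos, "MM"))

        hit = p["hit"]
        if hit is not None:
            chrom, s, e, strand = hit
            cands = oracle_contained(region_feats, chrom, s, e)
            keys = {
                "region": _expected_region_key(cands, "utr_cds_exon",
                                               "keep_first"),
                "region_literal": _expected_region_key(cands, "utr_exon_cds",
                                                       "keep_first"),
                "region_xdiscard": _expected_region_key(cands, "utr_cds_exon",
                                                        "discard"),
            }
            keys["gene"] = keys["region"][0] if keys["region"] else None
            tx_cands = oracle_contained(tx_feats, chrom, s, e)
            keys["transcript"] = tx_cands[0].transcript_id if tx_cands else None
            mapping = "unique"
        else:
            keys = {"region": None, "region_literal": None,
                    "region_xdiscard": None, "gene": None, "transcript": None}
            mapping = "multi" if p["label"] == "multi_mapped" else "unmapped"
        truth.probes[f"{x}:{y}"] = {
            "label": p["label"], "x": x, "y": y, "sequence": p["sequence"],
            "mapping": mapping, "hit": hit, "keys": keys,
        }
    return records, truth


def random_probe_panel(genome: GenomeSequence, n: int, seed: int = 0,
                       k: int = 25) -> list[ProbeRecord]:
    """A label-free random panel for mapper stress tests.

    Mixes genomic windows (forward and reverse complemented), duplicated
    picks and fully random sequences, so the unique/multi/unmapped
    classes are all populated with high probability; the exhaustive scan
    oracle supplies the expected classification.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome.chroms)
    bases = np.array(list("ACGT"))
    records = []
    last_seq = None
    for i in range(n):
        kind = rng.random()
        if kind < 0.55 or (kind < 0.7 and last_seq is None):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            clen = len(genome[chrom])
            s = int(rng.integers(1, clen - k + 1))
            seq = genome.fetch(chrom, s, s + k - 1)
            if rng.integers(0, 2):
                seq = revcomp(seq)
        elif kind < 0.7:
            seq = last_seq  # duplicate an earlier probe's sequence
        else:
            seq = "".join(rng.choice(bases, size=k))
        last_seq = seq
        records.append(ProbeRecord(f"rnd_{i:05d}_at", i % 200, 2 * (i // 200),
                                   seq, None, "PM"))
    return records


# ---------------------------------------------------------------------------
# Controls-only original CDF and bundle emission
# ---------------------------------------------------------------------------

def make_control_cdf(chip_rows: int, chip_cols: int, n_units: int = 3,
                     cells_per_unit: int = 10,
                     chip_name: str = "SYNCHIP") -> CDFModel:
    """A controls-only original CDF supplying chip dimensions.

    Control cells occupy dedicated rows appended below the probe grid, so
    they can never collide with custom probe cells.  Unit names follow
    the AFFX control convention.
    """
    rows = chip_rows + n_units
    model = CDFModel(name=chip_name, rows=rows, cols=max(chip_cols,
                                                         cells_per_unit))
    for u in range(n_units):
        y = chip_rows + u
        block = CDFBlock(name=f"AFFX-Ctrl-{u + 1}")
        for c in range(cells_per_unit):
            block.cells.append(CDFCell(
                x=c, y=y, qual=block.name, expos=c, pos=13,
                cbase="A", pbase="A", tbase="T", atom=c,
                index=y * model.cols + c))
        model.units.append(CDFUnit(name=block.name, blocks=[block]))
    model.validate()
    return model


@dataclass
class FixtureBundle:
    genome: GenomeSequence
    features: list[Feature]
    probes: list[ProbeRecord]
    truth: FixtureTruth
    original_cdf: CDFModel
    dialect: ProbeTabDialect = field(default_factory=lambda: FIXTURE_DIALECT)


def make_default_fixture(seed: int = 0, design: Optional[ProbeDesign] = None,
                         n_chroms: int = 2, chrom_len: int = 50_000,
                         n_genes: int = 12) -> FixtureBundle:
    """The default end-to-end fixture: 2 x 50 kb, 12 genes, ~300 probes."""
    genome = simulate_genome(n_chroms=n_chroms, chrom_len=chrom_len,
                             gc=0.5, seed=seed)
    features = simulate_annotation(genome, n_genes=n_genes,
                                   transcripts_per_gene=2, seed=seed + 1)
    probes, truth = simulate_probes(genome, features, design, seed=seed + 2)
    original = make_control_cdf(truth.chip_rows, truth.chip_cols)
    return FixtureBundle(genome, features, probes, truth, original)


def write_bundle(bundle: FixtureBundle, outdir) -> dict[str, Path]:
    """Write the full fixture bundle; returns the emitted paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "probes": outdir / "probes.tsv",
        "original_cdf": outdir / "original.cdf",
        "truth": outdir / "truth.json",
    }
    write_fasta(bundle.genome, paths["genome"])
    write_gtf(bundle.features, paths["gtf"])
    write_probe_tab(bundle.probes, paths["probes"], bundle.dialect)
    write_cdf_ascii(bundle.original_cdf, paths["original_cdf"])
    bundle.truth.to_json(paths["truth"])
    return paths
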