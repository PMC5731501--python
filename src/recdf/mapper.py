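"""Exact-match probe mapping: an in-package replacement for bowtie -v 0 -m 1.

Probes on expression arrays share one fixed length (25 nt on the chips this
package targets), so an exact-match aligner reduces to a dictionary from
genomic k-mer to its loci.  Only forward-strand windows are indexed; a
probe is looked up as itself (forward hits) and as its reverse complement
(reverse hits), which halves the index and makes the palindromic case
explicit: a self-reverse-complementary probe matching one window is found
by both lookups and therefore counts as two loci — the two-strand
alignment model — landing it in the multi-mapped class.

Each probe is classified as uniquely mapped (exactly one locus over both
strands), multi-mapped (two or more loci), or unmapped (none).  Windows
containing N are never matchable; probes containing non-ACGT characters
are unmapped, not an error.  Mismatch (MM) probes are the caller's job to
exclude — they are attached to their PM partners only at CDF construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .formats import GenomeSequence, ProbeRecord, revcomp

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class ProbeHit:
    """A single exact genomic locus of a probe, 1-based inclusive.

    ``strand`` is the strand of the genome the probe sequence matches
    verbatim: '+' when the forward genome spells the probe, '-' when its
    reverse complement does.
    """

    probe: ProbeRecord
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class MappingResult:
    """Partition of the PM probe panel into unique / multi / unmapped."""

    unique_hits: dict[ProbeRecord, ProbeHit] = field(default_factory=dict)
    multi: set[ProbeRecord] = field(default_factory=set)
    unmapped: set[ProbeRecord] = field(default_factory=set)

    @property
    def n_probes(self) -> int:
        return len(self.unique_hits) + len(self.multi) + len(self.unmapped)


@dataclass
class KmerIndex:
    """Forward-strand k-mer -> loci lookup over a genome."""

    k: int
    loci: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def lookup(self, seq: str) -> list[tuple[str, int, str]]:
        """All loci of ``seq`` over both strands as (chrom, start, strand)."""
        hits = [(c, s, "+") for c, s in self.loci.get(seq, ())]
        hits += [(c, s, "-") for c, s in self.loci.get(revcomp(seq), ())]
        return hits


def build_index(genome: GenomeSequence, k: int) -> KmerIndex:
    """Index every length-k forward window of the genome.

    Windows containing N are skipped.  If k exceeds the longest chromosome
    the index is empty and a warning is issued.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    index = KmerIndex(k=k)
    longest = max((len(s) for s in genome.chroms.values()), default=0)
    if k > longest:
        warnings.warn(
            f"k={k} exceeds the longest chromosome ({longest} bp); "
            f"index is empty", stacklevel=2)
        return index
    loci = index.loci
    for chrom, seq in genome.chroms.items():
        n = len(seq)
        # next_n[i]: position of the next N at or after i, for window skip
        next_n = seq.find("N")
        i = 0
        while i + k <= n:
            if next_n != -1 and next_n < i + k:
                if next_n < i:
                    next_n = seq.find("N", i)
                    continue
                i = next_n + 1
                next_n = seq.find("N", i)
                continue
            loci.setdefault(seq[i : i + k], []).append((chrom, i + 1))
            i += 1
    return index


def map_probes(probes: list[ProbeRecord], index: KmerIndex) -> MappingResult:
    """Classify PM probes as unique / multi / unmapped against the index.

    The result is independent of input order.  MM probes in the input are
    an error: they are never mapped, only re-attached downstream.
    """
    result = MappingResult()
    for probe in probes:
        if probe.kind != "PM":
            raise ValueError(
                f"MM probe at cell ({probe.x}, {probe.y}) passed to "
                f"map_probes; MM probes are attached at CDF construction")
        if len(probe.sequence) != index.k:
            raise ValueError(
                f"probe at ({probe.x}, {probe.y}) has length "
                f"{len(probe.sequence)}, index k={index.k}")
        if not _ACGT.issuperset(probe.sequence):
            logger.info("probe at (%d, %d) contains non-ACGT characters; "
                        "unmapped", probe.x, probe.y)
            result.unmapped.add(probe)
            continue
        hits = index.lookup(probe.sequence)
        if len(hits) == 1:
            chrom, start, strand = hits[0]
            result.unique_hits[probe] = ProbeHit(
                probe, chrom, start, start + index.k - 1, strand)
        elif hits:
            result.multi.add(probe)
        else:
            result.unmapped.add(probe)
    return result


def write_mapping_tsv(result: MappingResult, path) -> None:
    """Audit export: one row per PM probe with its class and locus."""
    rows = []
    for probe, hit in result.unique_hits.items():
        rows.append((probe.origin_probeset_id, probe.x, probe.y, "unique",
                     hit.chrom, hit.start, hit.end, hit.strand))
    for probe in result.multi:
        rows.append((probe.origin_probeset_id, probe.x, probe.y, "multi",
                     "", "", "", ""))
    for probe in result.unmapped:
        rows.append((probe.origin_probeset_id, probe.x, probe.y, "unmapped",
                     "", "", "", ""))
    rows.sort(key=lambda r: (r[2], r[1]))
    with open(path, "w") as fh:
        fh.write("probeset_id\tx\ty\tclass\tchrom\tstart\tend\tstrand\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")
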