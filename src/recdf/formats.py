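"""Readers and writers for the file formats the pipeline touches.

Four formats are handled: genome FASTA, Ensembl-dialect GTF gene models,
tab-delimited Affymetrix probe tables (NetAffx-style), and ASCII Chip
Description Files (CDF).  All genomic coordinates are 1-based inclusive
internally — the native GTF convention — and any 0-based external
representation is converted at the boundary.
"""

from __future__ import annotations

import re
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome FASTA
# ---------------------------------------------------------------------------

class GenomeSequence:
    """Uppercase per-chromosome nucleotide sequences over {A,C,G,T,N}.

    Chromosome names are unique and sequences non-empty.  Sequences are
    held as plain Python strings; at the genome sizes this package targets
    (arrays are remapped chromosome by chromosome) this is the simplest
    exact representation.
    """

    def __init__(self, chroms: Optional[dict[str, str]] = None):
        self.chroms: dict[str, str] = {}
        if chroms:
            for name, seq in chroms.items():
                self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self.chroms:
            raise FormatError(f"duplicate chromosome name: {name!r}")
        seq = seq.upper()
        if not seq:
            raise FormatError(f"empty sequence for chromosome {name!r}")
        bad = set(seq) - VALID_BASES
        if bad:
            pos = min(seq.index(b) for b in bad)
            raise FormatError(
                f"invalid character {seq[pos]!r} in chromosome {name!r} "
                f"at position {pos + 1}"
            )
        self.chroms[name] = seq

    def __getitem__(self, name: str) -> str:
        return self.chroms[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def __iter__(self):
        return iter(self.chroms)

    def __len__(self) -> int:
        return len(self.chroms)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self.chroms == other.chroms

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Substring at 1-based inclusive coordinates."""
        return self.chroms[chrom][start - 1 : end]


def read_fasta(path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    Lowercase is normalized to uppercase; header text after the first
    whitespace is dropped from the key.  Duplicate record names and
    characters outside {A,C,G,T,N} are hard errors.
    """
    genome = GenomeSequence()
    for record in SeqIO.parse(str(path), "fasta"):
        genome.add(record.id, str(record.seq))
    return genome


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

#: Feature classes carried through the pipeline.
FEATURE_CLASSES = ("gene", "transcript", "exon", "CDS", "UTR5", "UTR3")

_GTF_TYPE_MAP = {
    "gene": "gene",
    "transcript": "transcript",
    "exon": "exon",
    "CDS": "CDS",
    "five_prime_utr": "UTR5",
    "three_prime_utr": "UTR3",
}


@dataclass(frozen=True, order=True)
class Feature:
    """One annotated genomic interval, 1-based inclusive, start <= end."""

    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str
    gene_id: str
    transcript_id: Optional[str] = None

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"invalid coordinates {self.start}-{self.end} for "
                f"{self.feature_class} of {self.gene_id}"
            )

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_gtf(path) -> list[Feature]:
    """Parse an Ensembl-dialect GTF into :class:`Feature` records.

    Both UTR dialects are supported: explicit ``five_prime_utr`` /
    ``three_prime_utr`` lines (Ensembl >= 75) and bare ``UTR`` lines,
    which are classified as 5' or 3' by their position relative to the
    transcript's CDS span.  Feature types outside the retained set
    (start_codon, stop_codon, ...) are skipped — in Ensembl GTFs their
    bases already lie inside CDS features.
    """
    features: list[Feature] = []
    pending_utrs: list[tuple[int, Feature]] = []  # bare "UTR" lines
    cds_span: dict[str, list[int]] = {}  # transcript_id -> [min, max]

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            ftype = fields[2]
            if ftype not in _GTF_TYPE_MAP and ftype != "UTR":
                continue
            try:
                parsed = feature_from_line(line, dialect=None)
            except Exception as exc:  # pragma: no cover - malformed attrs
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            attrs = parsed.attributes
            if "gene_id" not in attrs:
                raise FormatError(
                    f"{path}: line {lineno}: retained feature lacks gene_id"
                )
            gene_id = attrs["gene_id"][0]
            transcript_id = attrs["transcript_id"][0] if "transcript_id" in attrs else None
            start, end = int(fields[3]), int(fields[4])
            strand = fields[6]
            if ftype != "gene" and transcript_id is None:
                raise FormatError(
                    f"{path}: line {lineno}: sub-gene feature lacks transcript_id"
                )
            if ftype == "CDS" and transcript_id is not None:
                span = cds_span.setdefault(transcript_id, [start, end])
                span[0] = min(span[0], start)
                span[1] = max(span[1], end)
            if ftype == "UTR":
                stub = Feature(fields[0], start, end, strand, "UTR5",
                               gene_id, transcript_id)
                pending_utrs.append((lineno, stub))
                continue
            features.append(
                Feature(fields[0], start, end, strand,
                        _GTF_TYPE_MAP[ftype], gene_id, transcript_id)
            )

    # Classify bare UTR lines now that all CDS spans are known.
    for lineno, stub in pending_utrs:
        span = cds_span.get(stub.transcript_id)
        if span is None:
            raise FormatError(
                f"{path}: line {lineno}: bare UTR for transcript "
                f"{stub.transcript_id} with no CDS to orient against"
            )
        upstream = stub.end < span[0]  # genomically left of the CDS
        if stub.strand == "+":
            cls = "UTR5" if upstream else "UTR3"
        else:
            cls = "UTR3" if upstream else "UTR5"
        features.append(Feature(stub.chrom, stub.start, stub.end, stub.strand,
                                cls, stub.gene_id, stub.transcript_id))
    return features


def write_gtf(features: Iterable[Feature], path, source: str = "recdf") -> None:
    """Write features as Ensembl-dialect GTF (five_prime_utr/three_prime_utr)."""
    inverse = {v: k for k, v in _GTF_TYPE_MAP.items()}
    with open(path, "w") as fh:
        fh.write("#!genome-build synthetic\n")
        for f in features:
            attrs = f'gene_id "{f.gene_id}";'
            if f.transcript_id is not None:
                attrs += f' transcript_id "{f.transcript_id}";'
            fh.write("\t".join([
                f.chrom, source, inverse[f.feature_class], str(f.start),
                str(f.end), ".", f.strand, ".", attrs,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Affymetrix probe tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeRecord:
    """One physical array cell: a 25-mer probe at grid position (x, y)."""

    origin_probeset_id: str
    x: int
    y: int
    sequence: str
    interrogation_position: Optional[int] = None
    kind: str = "PM"  # PM | MM

    @property
    def cell(self) -> tuple[int, int]:
        return (self.x, self.y)


@dataclass
class ProbeTabDialect:
    """Column mapping for a tab-delimited probe table.

    NetAffx exports vary in header wording, so the mapping is configuration
    rather than a constant.  When ``kind_col`` is None every row is taken
    as a PM probe (the NetAffx convention: MM sequences are not published
    and are derived later by the adjacent-cell rule).
    """

    probeset_col: str = "Probe Set Name"
    x_col: str = "Probe X"
    y_col: str = "Probe Y"
    seq_col: str = "Probe Sequence"
    interrogation_col: Optional[str] = "Probe Interrogation Position"
    kind_col: Optional[str] = None
    mm_value: str = "MM"


def read_probe_tab(path, dialect: Optional[ProbeTabDialect] = None,
                   probe_length: Optional[int] = None) -> list[ProbeRecord]:
    """Read a tab-delimited probe table into :class:`ProbeRecord` rows.

    ``probe_length`` fixes the expected sequence length; when None it is
    inferred from the first row.  Duplicate (x, y) cells and off-length
    sequences are errors.
    """
    dialect = dialect or ProbeTabDialect()
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (dialect.probeset_col, dialect.x_col, dialect.y_col, dialect.seq_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    records: list[ProbeRecord] = []
    seen: set[tuple[int, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), 2):  # header is line 1
        rd = dict(zip(df.columns, row))
        seq = rd[dialect.seq_col].strip().upper()
        if probe_length is None:
            probe_length = len(seq)
        if len(seq) != probe_length:
            raise FormatError(
                f"{path}: line {i}: sequence length {len(seq)} != "
                f"chip probe length {probe_length}"
            )
        x, y = int(rd[dialect.x_col]), int(rd[dialect.y_col])
        if (x, y) in seen:
            raise FormatError(f"{path}: line {i}: duplicate cell ({x}, {y})")
        seen.add((x, y))
        ipos = None
        if dialect.interrogation_col and dialect.interrogation_col in df.columns:
            raw = rd[dialect.interrogation_col]
            if raw is not None and raw == raw and str(raw).strip():
                ipos = int(float(raw))
        kind = "PM"
        if dialect.kind_col and dialect.kind_col in df.columns:
            kind = "MM" if rd[dialect.kind_col].strip() == dialect.mm_value else "PM"
        records.append(ProbeRecord(rd[dialect.probeset_col], x, y, seq, ipos, kind))
    return records


def write_probe_tab(records: Iterable[ProbeRecord], path,
                    dialect: Optional[ProbeTabDialect] = None) -> None:
    dialect = dialect or ProbeTabDialect(kind_col="Probe Kind")
    cols = [dialect.probeset_col, dialect.x_col, dialect.y_col, dialect.seq_col]
    if dialect.interrogation_col:
        cols.append(dialect.interrogation_col)
    if dialect.kind_col:
        cols.append(dialect.kind_col)
    rows = []
    for r in records:
        row = [r.origin_probeset_id, r.x, r.y, r.sequence]
        if dialect.interrogation_col:
            row.append("" if r.interrogation_position is None
                       else r.interrogation_position)
        if dialect.kind_col:
            row.append(r.kind)
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ASCII CDF
# ---------------------------------------------------------------------------

#: Order in which known keys are written; unknown keys follow in stored order.
_CHIP_KEYS = ("Name", "Rows", "Cols", "NumberOfUnits", "MaxUnit")
_UNIT_KEYS = ("Name", "Direction", "NumAtoms", "NumCells", "UnitNumber",
              "UnitType", "NumberBlocks")
_BLOCK_KEYS = ("Name", "BlockNumber", "NumAtoms", "NumCells",
               "StartPosition", "StopPosition")

CELL_HEADER = ("X", "Y", "PROBE", "FEAT", "QUAL", "EXPOS", "POS",
               "CBASE", "PBASE", "TBASE", "ATOM", "INDEX")


@dataclass
class CDFCell:
    """One array cell line inside a block.

    ``pbase`` is the probe base at the interrogation position and
    ``tbase`` the target base; by Affymetrix convention a PM cell has
    pbase complementary to tbase while an MM cell has pbase == tbase.
    """

    x: int
    y: int
    qual: str
    expos: int
    pos: int
    cbase: str
    pbase: str
    tbase: str
    atom: int
    index: int
    probe: str = "N"
    feat: str = "control"

    @property
    def is_pm(self) -> bool:
        return self.pbase != self.tbase

    def to_line(self) -> str:
        return "\t".join(str(v) for v in (
            self.x, self.y, self.probe, self.feat, self.qual, self.expos,
            self.pos, self.cbase, self.pbase, self.tbase, self.atom, self.index))

    @classmethod
    def from_line(cls, line: str) -> "CDFCell":
        p = line.split("\t")
        if len(p) != len(CELL_HEADER):
            raise FormatError(f"cell line has {len(p)} fields, "
                              f"expected {len(CELL_HEADER)}: {line!r}")
        return cls(x=int(p[0]), y=int(p[1]), probe=p[2], feat=p[3], qual=p[4],
                   expos=int(p[5]), pos=int(p[6]), cbase=p[7], pbase=p[8],
                   tbase=p[9], atom=int(p[10]), index=int(p[11]))


@dataclass
class CDFBlock:
    name: str
    cells: list[CDFCell] = field(default_factory=list)
    extra: "OrderedDict[str, str]" = field(default_factory=OrderedDict)

    def atoms(self) -> int:
        return len({c.atom for c in self.cells})


@dataclass
class CDFUnit:
    name: str
    unit_type: int = 3
    direction: int = 1
    blocks: list[CDFBlock] = field(default_factory=list)
    extra: "OrderedDict[str, str]" = field(default_factory=OrderedDict)

    def cells(self) -> list[CDFCell]:
        return [c for b in self.blocks for c in b.cells]


@dataclass
class CDFModel:
    """Structural model of an ASCII CDF: chip grid plus ordered units."""

    name: str
    rows: int
    cols: int
    units: list[CDFUnit] = field(default_factory=list)
    version: str = "GC3.0"
    chip_extra: "OrderedDict[str, str]" = field(default_factory=OrderedDict)

    def validate(self) -> None:
        names = [u.name for u in self.units]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate unit names: {dup}")
        for unit in self.units:
            seen: set[tuple[int, int]] = set()
            for block in unit.blocks:
                for c in block.cells:
                    if not (0 <= c.x < self.cols and 0 <= c.y < self.rows):
                        raise FormatError(
                            f"cell ({c.x}, {c.y}) of unit {unit.name!r} "
                            f"outside {self.cols}x{self.rows} grid")
                    if (c.x, c.y) in seen:
                        raise FormatError(
                            f"duplicate cell ({c.x}, {c.y}) in unit {unit.name!r}")
                    seen.add((c.x, c.y))


def write_cdf_ascii(model: CDFModel, path) -> None:
    """Write an ASCII CDF deterministically (fixed key order, LF endings).

    The layout follows the GC3.0 section/key structure: ``[CDF]``,
    ``[Chip]``, ``[UnitN]`` and ``[UnitN_BlockM]`` sections with a
    CellHeader followed by ``CellK=`` lines.  Writing the same model twice
    yields byte-identical files, and :func:`read_cdf_ascii` inverts the
    output exactly.
    """
    model.validate()
    out: list[str] = []
    out.append("[CDF]")
    out.append(f"Version={model.version}")
    out.append("")
    out.append("[Chip]")
    chip = OrderedDict([
        ("Name", model.name), ("Rows", model.rows), ("Cols", model.cols),
        ("NumberOfUnits", len(model.units)), ("MaxUnit", len(model.units)),
    ])
    for k, v in chip.items():
        out.append(f"{k}={v}")
    for k, v in model.chip_extra.items():
        if k not in chip:
            out.append(f"{k}={v}")
    out.append("")
    for ui, unit in enumerate(model.units, 1):
        ncells = len(unit.cells())
        natoms = sum(b.atoms() for b in unit.blocks)
        out.append(f"[Unit{ui}]")
        known = OrderedDict([
            ("Name", unit.name), ("Direction", unit.direction),
            ("NumAtoms", natoms), ("NumCells", ncells),
            ("UnitNumber", ui), ("UnitType", unit.unit_type),
            ("NumberBlocks", len(unit.blocks)),
        ])
        for k, v in known.items():
            out.append(f"{k}={v}")
        for k, v in unit.extra.items():
            if k not in known:
                out.append(f"{k}={v}")
        out.append("")
        for bi, block in enumerate(unit.blocks, 1):
            out.append(f"[Unit{ui}_Block{bi}]")
            bknown = OrderedDict([
                ("Name", block.name), ("BlockNumber", bi),
                ("NumAtoms", block.atoms()), ("NumCells", len(block.cells)),
                ("StartPosition", 0),
                ("StopPosition", max(block.atoms() - 1, 0)),
            ])
            for k, v in bknown.items():
                out.append(f"{k}={v}")
            for k, v in block.extra.items():
                if k not in bknown:
                    out.append(f"{k}={v}")
            out.append("CellHeader=" + "\t".join(CELL_HEADER))
            for ci, cell in enumerate(block.cells, 1):
                out.append(f"Cell{ci}={cell.to_line()}")
            out.append("")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(out))
        if out:
            fh.write("\n")


_SECTION_RE = re.compile(r"^\[(?P<name>[^\]]+)\]$")
_UNIT_RE = re.compile(r"^Unit(?P<unit>\d+)$")
_BLOCK_RE = re.compile(r"^Unit(?P<unit>\d+)_Block(?P<block>\d+)$")
_CELL_RE = re.compile(r"^Cell(?P<n>\d+)$")


def read_cdf_ascii(path) -> CDFModel:
    """Parse an ASCII CDF into a :class:`CDFModel`.

    Unknown keys are preserved as opaque attributes so that a
    read-then-write round trip is byte-faithful.  The unit count in the
    [Chip] header must match the number of unit sections, and every cell
    must lie inside the Rows x Cols grid.
    """
    sections: "OrderedDict[str, OrderedDict[str, str]]" = OrderedDict()
    cell_lines: dict[str, list[tuple[int, str]]] = {}
    current: Optional[str] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            m = _SECTION_RE.match(line)
            if m:
                current = m.group("name")
                if current in sections:
                    raise FormatError(f"{path}: duplicate section [{current}]")
                sections[current] = OrderedDict()
                cell_lines[current] = []
                continue
            if current is None or "=" not in line:
                raise FormatError(f"{path}: line {lineno}: unexpected content")
            key, _, value = line.partition("=")
            cm = _CELL_RE.match(key)
            if cm:
                cell_lines[current].append((int(cm.group("n")), value))
            else:
                sections[current][key] = value

    if "CDF" not in sections or "Chip" not in sections:
        raise FormatError(f"{path}: missing [CDF] or [Chip] section")
    chip = sections["Chip"]
    model = CDFModel(
        name=chip.get("Name", ""),
        rows=int(chip["Rows"]),
        cols=int(chip["Cols"]),
        version=sections["CDF"].get("Version", "GC3.0"),
    )
    declared = int(chip["NumberOfUnits"])
    for k, v in chip.items():
        if k not in _CHIP_KEYS:
            model.chip_extra[k] = v

    unit_ids = sorted(int(_UNIT_RE.match(s).group("unit"))
                      for s in sections if _UNIT_RE.match(s))
    if len(unit_ids) != declared:
        raise FormatError(
            f"{path}: [Chip] NumberOfUnits={declared} but "
            f"{len(unit_ids)} [UnitN] sections found")

    for ui in unit_ids:
        usec = sections[f"Unit{ui}"]
        unit = CDFUnit(
            name=usec.get("Name", f"Unit{ui}"),
            unit_type=int(usec.get("UnitType", 3)),
            direction=int(usec.get("Direction", 1)),
        )
        for k, v in usec.items():
            if k not in _UNIT_KEYS:
                unit.extra[k] = v
        nblocks = int(usec.get("NumberBlocks", 0))
        for bi in range(1, nblocks + 1):
            sname = f"Unit{ui}_Block{bi}"
            if sname not in sections:
                raise FormatError(f"{path}: missing section [{sname}]")
            bsec = sections[sname]
            block = CDFBlock(name=bsec.get("Name", unit.name))
            for k, v in bsec.items():
                if k not in _BLOCK_KEYS and k != "CellHeader":
                    block.extra[k] = v
            for _, value in sorted(cell_lines[sname]):
                block.cells.append(CDFCell.from_line(value))
            declared_cells = int(bsec.get("NumCells", len(block.cells)))
            if declared_cells != len(block.cells):
                raise FormatError(
                    f"{path}: [{sname}] NumCells={declared_cells} but "
                    f"{len(block.cells)} cell lines found")
            declared_atoms = int(bsec.get("NumAtoms", block.atoms()))
            if declared_atoms != block.atoms():
                raise FormatError(
                    f"{path}: [{sname}] NumAtoms={declared_atoms} but cells "
                    f"span {block.atoms()} atoms")
            unit.blocks.append(block)
        model.units.append(unit)
    model.validate()
    return model
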