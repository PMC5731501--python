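"""Assemble probe annotations into named probe sets and a CDF model.

Probes sharing an annotation form a probe set; names follow the
region-CDF grammar ``<gene_id>_<UTR|exon|CDS>_<strand>`` (gene and
transcript CDFs use the bare Ensembl id).  MM partners are re-attached by
the array convention (the cell directly below the PM), probe sets below a
minimum PM count can be filtered out (both the unrestricted >=1 and the
restricted >=3 groupings are meaningful deliverables), control probe sets
from the original CDF are carried over verbatim, and the result is a
:class:`~recdf.formats.CDFModel` ready for ASCII emission.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from .annotator import ProbeAnnotation, TargetKey
from .formats import CDFBlock, CDFCell, CDFModel, CDFUnit, ProbeRecord

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Grammar of emitted probe-set names on Ensembl-style ids.
NAME_RE = re.compile(r"^ENS[A-Z]*[GT]\d+(_(UTR|exon|CDS)_[+-])?$")


@dataclass
class ProbeSet:
    """A named group of PM probes (with optional MM partners)."""

    name: str
    mode: str
    members: list[tuple[ProbeRecord, Optional[ProbeRecord]]] = field(
        default_factory=list)
    provenance: Optional[TargetKey] = None
    annotations: list[ProbeAnnotation] = field(default_factory=list)
    is_control: bool = False
    raw_unit: Optional[CDFUnit] = None  # verbatim unit for controls

    @property
    def n_pm(self) -> int:
        return len(self.members)

    @property
    def n_mm(self) -> int:
        return sum(1 for _, mm in self.members if mm is not None)


def name_probeset(target_key: TargetKey, mode: str) -> str:
    """Probe-set name for a target key.

    Region mode: ``<gene_id>_<region>_<strand>`` with region in
    {UTR, exon, CDS}; gene/transcript modes: the id itself.
    """
    if mode == "region":
        gene_id, region, strand = target_key
        return f"{gene_id}_{region}_{strand}"
    return str(target_key)


def group_probesets(annotations: list[ProbeAnnotation], mode: str) -> list[ProbeSet]:
    """One ProbeSet per distinct target key.

    Members are ordered by (chromosomal start, x, y) and probe sets by
    name, so output is deterministic for any input order.
    """
    by_key: dict[TargetKey, list[ProbeAnnotation]] = {}
    for a in annotations:
        if a.mode != mode:
            raise ValueError(f"annotation mode {a.mode!r} != {mode!r}")
        by_key.setdefault(a.target_key, []).append(a)
    sets = []
    for key, anns in by_key.items():
        anns.sort(key=lambda a: (a.hit.chrom, a.hit.start,
                                 a.hit.probe.x, a.hit.probe.y))
        sets.append(ProbeSet(
            name=name_probeset(key, mode), mode=mode,
            members=[(a.hit.probe, None) for a in anns],
            provenance=key, annotations=anns))
    sets.sort(key=lambda s: s.name)
    return sets


def attach_mm(probesets: list[ProbeSet], all_probes: list[ProbeRecord],
              policy: str = "cell_below") -> list[ProbeSet]:
    """Attach MM partner probes to the PM members, in place.

    Policies: ``cell_below`` — the MM probe sits at (x, y+1) of its PM,
    the GeneChip layout convention; ``explicit`` — MM rows of the probe
    table are matched by (origin probe-set id, interrogation position);
    ``none`` — leave every set PM-only.  PM-only sets are always
    permitted.  Two PMs claiming one MM cell is an error.
    """
    if policy == "none":
        for ps in probesets:
            ps.members = [(pm, None) for pm, _ in ps.members]
        return probesets
    mm_records = [p for p in all_probes if p.kind == "MM"]
    if policy == "cell_below":
        lookup = {p.cell: p for p in mm_records}
        def find(pm: ProbeRecord) -> Optional[ProbeRecord]:
            return lookup.get((pm.x, pm.y + 1))
    elif policy == "explicit":
        lookup = {}
        for p in mm_records:
            lookup.setdefault((p.origin_probeset_id,
                               p.interrogation_position), []).append(p)
        def find(pm: ProbeRecord) -> Optional[ProbeRecord]:
            matches = lookup.get((pm.origin_probeset_id,
                                  pm.interrogation_position), [])
            return matches[0] if len(matches) == 1 else None
    else:
        raise ValueError(f"unknown MM policy {policy!r}")
    claimed: dict[tuple[int, int], ProbeRecord] = {}
    for ps in probesets:
        if ps.is_control:
            continue
        paired = []
        for pm, _ in ps.members:
            mm = find(pm)
            if mm is not None:
                prev = claimed.get(mm.cell)
                if prev is not None and prev != pm:
                    raise ValueError(
                        f"MM cell {mm.cell} claimed by PM cells "
                        f"{prev.cell} and {pm.cell}")
                claimed[mm.cell] = pm
            paired.append((pm, mm))
        ps.members = paired
    return probesets


def filter_min_probes(probesets: list[ProbeSet], min_members: int) -> list[ProbeSet]:
    """Drop probe sets with fewer than ``min_members`` PM probes.

    MM partners do not count: the PM probe is the grouping unit
    throughout.  Control sets are never filtered.  min_members=1 is the
    unrestricted grouping; 3 the restricted one.
    """
    if min_members < 1:
        raise ValueError(f"min_members must be >= 1, got {min_members}")
    return [ps for ps in probesets
            if ps.is_control or ps.n_pm >= min_members]


def merge_controls(probesets: list[ProbeSet], original_cdf: Optional[CDFModel],
                   control_name_patterns: tuple[str, ...] = (r"^AFFX",),
                   ) -> list[ProbeSet]:
    """Append the original CDF's control units, copied verbatim.

    Units whose names match any pattern (default prefix AFFX) are wrapped
    as control ProbeSets carrying the raw unit untouched.  Name collisions
    with custom sets and cell collisions with custom probe cells are
    chip-integrity errors.
    """
    if original_cdf is None:
        logger.warning("no original CDF supplied; no control probe sets merged")
        return probesets
    regexes = [re.compile(p) for p in control_name_patterns]
    custom_names = {ps.name for ps in probesets}
    custom_cells = {pr.cell
                    for ps in probesets for pm, mm in ps.members
                    for pr in (pm, mm) if pr is not None}
    out = list(probesets)
    for unit in original_cdf.units:
        if not any(r.search(unit.name) for r in regexes):
            continue
        if unit.name in custom_names:
            raise ValueError(
                f"control unit name {unit.name!r} collides with a custom "
                f"probe set")
        for cell in unit.cells():
            if (cell.x, cell.y) in custom_cells:
                raise ValueError(
                    f"control cell ({cell.x}, {cell.y}) of unit "
                    f"{unit.name!r} collides with a custom probe cell")
        out.append(ProbeSet(name=unit.name, mode="control",
                            is_control=True, raw_unit=unit))
    return out


def _central_base(seq: str, ipos: Optional[int]) -> tuple[int, str]:
    """(0-based offset, base) of the substitution position within the probe."""
    offset = len(seq) // 2 if ipos is None else min(max(ipos - 1, 0), len(seq) - 1)
    return offset, seq[offset]


def build_cdf_model(probesets: list[ProbeSet], chip_dims: tuple[int, int],
                    chip_name: str) -> CDFModel:
    """Assemble the final CDF model: one unit (one block) per probe set.

    ``chip_dims`` is (rows, cols).  Custom units are name-sorted with
    controls last; unit numbering is assigned contiguously from 1 after
    sorting.  Cells carry the probe/target base characters at the
    interrogation position (PM: complementary; MM: equal), the atom index
    and the cell index y*cols + x.
    """
    rows, cols = chip_dims
    custom = sorted((ps for ps in probesets if not ps.is_control),
                    key=lambda ps: ps.name)
    controls = [ps for ps in probesets if ps.is_control]
    model = CDFModel(name=chip_name, rows=rows, cols=cols)
    for ps in custom + controls:
        if ps.is_control:
            model.units.append(ps.raw_unit)
            continue
        block = CDFBlock(name=ps.name)
        for atom, (pm, mm) in enumerate(ps.members):
            offset, pbase = _central_base(pm.sequence, pm.interrogation_position)
            tbase = _COMP[pbase]
            pos = offset + 1
            block.cells.append(CDFCell(
                x=pm.x, y=pm.y, qual=ps.name, expos=atom, pos=pos,
                cbase=pbase, pbase=pbase, tbase=tbase, atom=atom,
                index=pm.y * cols + pm.x))
            if mm is not None:
                _, mbase = _central_base(mm.sequence, mm.interrogation_position)
                block.cells.append(CDFCell(
                    x=mm.x, y=mm.y, qual=ps.name, expos=atom, pos=pos,
                    cbase=pbase, pbase=mbase, tbase=mbase, atom=atom,
                    index=mm.y * cols + mm.x))
        unit = CDFUnit(name=ps.name, blocks=[block])
        model.units.append(unit)
    model.validate()
    return model


def write_probeset_summary(probesets: list[ProbeSet], path) -> None:
    """TSV summary: name, counts, target key and genomic span per set."""
    with open(path, "w") as fh:
        fh.write("name\tmode\tn_pm\tn_mm\ttarget_key\tchrom\tspan_start\t"
                 "span_end\n")
        for ps in probesets:
            if ps.is_control:
                fh.write(f"{ps.name}\tcontrol\t\t\t\t\t\t\n")
                continue
            key = "_".join(ps.provenance) if isinstance(ps.provenance, tuple) \
                else (ps.provenance or "")
            if ps.annotations:
                chrom = ps.annotations[0].hit.chrom
                start = min(a.hit.start for a in ps.annotations)
                end = max(a.hit.end for a in ps.annotations)
            else:
                chrom, start, end = "", "", ""
            fh.write(f"{ps.name}\t{ps.mode}\t{ps.n_pm}\t{ps.n_mm}\t{key}\t"
                     f"{chrom}\t{start}\t{end}\n")
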