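"""Nested containment list (NCList) for interval containment queries.

The annotation step needs one query shape only: *all stored features that
completely contain a query interval* (both ends of the probe inside the
feature).  An NCList stores intervals sorted by (start ascending, end
descending) with contained intervals nested in sublists under their
container.  Within any sibling list no interval contains a later sibling,
so starts and ends are both strictly increasing along siblings — which is
what makes binary search per level sound.

Containment here is coordinate-only; strand policy belongs to the caller.
Generic overlap queries are deliberately not implemented.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional

from .formats import Feature, FormatError

#: Deterministic ordering used for building and for emitting query results:
#: start ascending, end descending, then feature identity for tie-breaks.
def sort_key(f: Feature):
    return (f.start, -f.end, f.feature_class, f.gene_id, f.transcript_id or "")


@dataclass
class _Node:
    feature: Feature
    children: list["_Node"] = field(default_factory=list)


@dataclass
class NCList:
    """Per-chromosome nested containment list."""

    top: list[_Node] = field(default_factory=list)
    size: int = 0

    def query_contained(self, q_start: int, q_end: int,
                        stats: Optional[dict] = None) -> list[Feature]:
        """All stored features F with F.start <= q_start and q_end <= F.end.

        Descends only into sublists whose parent contains the query, so the
        work per level is a binary search plus the matching suffix.  When
        ``stats`` is given, ``stats["visited"]`` counts the intervals
        inspected (for cost assertions in tests).
        """
        if q_start > q_end:
            raise ValueError(f"query start {q_start} > end {q_end}")
        out: list[Feature] = []
        self._collect(self.top, q_start, q_end, out, stats)
        out.sort(key=sort_key)
        return out

    def _collect(self, siblings: list[_Node], qs: int, qe: int,
                 out: list[Feature], stats: Optional[dict]) -> None:
        if not siblings:
            return
        starts = [n.feature.start for n in siblings]
        hi = bisect_right(starts, qs)  # siblings[:hi] have start <= qs
        # Sibling ends increase with start, so the containers form a suffix
        # of siblings[:hi]; walk backwards until ends drop below qe.
        for i in range(hi - 1, -1, -1):
            node = siblings[i]
            if stats is not None:
                stats["visited"] = stats.get("visited", 0) + 1
            if node.feature.end < qe:
                break
            out.append(node.feature)
            self._collect(node.children, qs, qe, out, stats)


def build_nclist(features: list[Feature]) -> NCList:
    """Build an NCList from features on a single chromosome.

    Duplicate-coordinate intervals are all retained; ties nest
    deterministically under the sort key (start asc, end desc, class,
    gene id, transcript id).
    """
    chroms = {f.chrom for f in features}
    if len(chroms) > 1:
        raise ValueError(f"features span multiple chromosomes: {sorted(chroms)}")
    for f in features:
        if f.start > f.end:  # Feature.__post_init__ forbids this, but the
            raise FormatError(  # structure re-checks its own precondition
                f"start > end for {f.feature_class} of {f.gene_id}")
    nc = NCList(size=len(features))
    stack: list[_Node] = []
    for f in sorted(features, key=sort_key):
        node = _Node(f)
        while stack and stack[-1].feature.end < f.end:
            stack.pop()
        # Equal intervals: the earlier one (under the tie-break) contains
        # the later, so it stays on the stack and adopts it as a child.
        if stack:
            stack[-1].children.append(node)
        else:
            nc.top.append(node)
        stack.append(node)
    return nc


def check_invariants(nc: NCList) -> None:
    """Assert the structural invariants; raises AssertionError on violation."""
    count = 0

    def walk(siblings: list[_Node], parent: Optional[_Node]):
        nonlocal count
        prev: Optional[_Node] = None
        for node in siblings:
            count += 1
            f = node.feature
            if parent is not None:
                p = parent.feature
                assert p.start <= f.start and f.end <= p.end, (
                    f"child {f} not contained in parent {p}")
            if prev is not None:
                pf = prev.feature
                assert sort_key(pf) <= sort_key(f), "siblings out of order"
                assert not (pf.start <= f.start and f.end <= pf.end), (
                    f"sibling {pf} contains later sibling {f}")
            prev = node
            walk(node.children, node)

    walk(nc.top, None)
    assert count == nc.size, f"{count} nodes walked, {nc.size} stored"
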