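"""Probe-set grouping, naming, MM pairing, filtering, CDF assembly."""

import pytest

from recdf.annotator import ProbeAnnotation, annotate_probes
from recdf.builder import (NAME_RE, ProbeSet, attach_mm, build_cdf_model,
                           filter_min_probes, group_probesets,
                           merge_controls, name_probeset)
from recdf.formats import Feature, ProbeRecord
from recdf.mapper import ProbeHit, build_index, map_probes


def make_ann(key, x, y, start, mode="region"):
    probe = ProbeRecord(f"p{x}_{y}", x, y, "A" * 25, 13, "PM")
    hit = ProbeHit(probe, "c", start, start + 24, "+")
    strand = key[2] if isinstance(key, tuple) else "+"
    feature = Feature("c", max(start - 50, 1), start + 100, strand, "exon",
                      key[0] if isinstance(key, tuple) else str(key))
    return ProbeAnnotation(hit, mode, key, feature)


class TestGrouping:
    def test_group_sizes(self):
        anns = ([make_ann(("G1", "UTR", "-"), x, 0, 100 + x) for x in range(3)]
                + [make_ann(("G1", "CDS", "-"), x, 2, 500 + x) for x in range(2)])
        sets = group_probesets(anns, "region")
        assert sorted(ps.n_pm for ps in sets) == [2, 3]

    def test_empty_annotations(self):
        assert group_probesets([], "region") == []

    def test_members_ordered_by_position(self):
        anns = [make_ann(("G1", "UTR", "-"), x, 0, 1000 - 10 * x)
                for x in range(4)]
        (ps,) = group_probesets(anns, "region")
        starts = [a.hit.start for a in ps.annotations]
        assert starts == sorted(starts)

    def test_fixture_group_census_matches_truth(self, bundle):
        pm = [p for p in bundle.probes if p.kind == "PM"]
        result = map_probes(pm, build_index(bundle.genome, 25))
        for mode in ("region", "gene", "transcript"):
            anns = annotate_probes(result.unique_hits, bundle.features, mode)
            sets = group_probesets(anns, mode)
            census = {ps.name: ps.n_pm for ps in sets}
            assert census == bundle.truth.census(mode)


class TestNaming:
    @pytest.mark.parametrize("key,mode,expected", [
        (("ENSG00000001084", "UTR", "-"), "region", "ENSG00000001084_UTR_-"),
        (("ENSG00000001167", "CDS", "+"), "region", "ENSG00000001167_CDS_+"),
        (("ENSG00000001036", "exon", "-"), "region", "ENSG00000001036_exon_-"),
        ("ENSG00000001461", "gene", "ENSG00000001461"),
        ("ENST00000489806", "transcript", "ENST00000489806"),
    ])
    def test_naming_examples(self, key, mode, expected):
        assert name_probeset(key, mode) == expected

    def test_emitted_names_conform_to_grammar(self, bundle):
        pm = [p for p in bundle.probes if p.kind == "PM"]
        result = map_probes(pm, build_index(bundle.genome, 25))
        for mode in ("region", "gene", "transcript"):
            anns = annotate_probes(result.unique_hits, bundle.features, mode)
            for ps in group_probesets(anns, mode):
                assert NAME_RE.match(ps.name), ps.name

    def test_name_uniqueness(self, bundle):
        pm = [p for p in bundle.probes if p.kind == "PM"]
        result = map_probes(pm, build_index(bundle.genome, 25))
        anns = annotate_probes(result.unique_hits, bundle.features, "region")
        names = [ps.name for ps in group_probesets(anns, "region")]
        assert len(names) == len(set(names))


class TestAttachMM:
    def test_cell_below_convention(self):
        pm = ProbeRecord("a", 5, 7, "A" * 25, 13, "PM")
        mm = ProbeRecord("a", 5, 8, "A" * 12 + "T" + "A" * 12, 13, "MM")
        sets = [ProbeSet("S", "region", [(pm, None)])]
        attach_mm(sets, [pm, mm], "cell_below")
        assert sets[0].members == [(pm, mm)]

    def test_policy_none_leaves_pm_only(self):
        pm = ProbeRecord("a", 5, 7, "A" * 25, 13, "PM")
        mm = ProbeRecord("a", 5, 8, "T" * 25, 13, "MM")
        sets = [ProbeSet("S", "region", [(pm, mm)])]
        attach_mm(sets, [pm, mm], "none")
        assert sets[0].members == [(pm, None)]

    def test_fixture_every_pm_paired(self, bundle):
        pm = [p for p in bundle.probes if p.kind == "PM"]
        result = map_probes(pm, build_index(bundle.genome, 25))
        anns = annotate_probes(result.unique_hits, bundle.features, "region")
        sets = attach_mm(group_probesets(anns, "region"), bundle.probes)
        mm_by_cell = {p.cell: p for p in bundle.probes if p.kind == "MM"}
        for ps in sets:
            for pm_probe, mm_probe in ps.members:
                assert mm_probe == mm_by_cell[(pm_probe.x, pm_probe.y + 1)]


class TestFilter:
    def test_threshold(self):
        sets = [ProbeSet(f"S{n}", "region",
                         [(ProbeRecord(f"p{n}_{i}", i, 2 * n, "A" * 25, 13,
                                       "PM"), None) for i in range(n)])
                for n in (1, 2, 3, 5)]
        survivors = filter_min_probes(sets, 3)
        assert sorted(ps.n_pm for ps in survivors) == [3, 5]

    def test_min_one_is_identity(self):
        sets = [ProbeSet("S", "region",
                         [(ProbeRecord("p", 0, 0, "A" * 25, 13, "PM"), None)])]
        assert filter_min_probes(sets, 1) == sets

    def test_monotonicity(self, bundle):
        pm = [p for p in bundle.probes if p.kind == "PM"]
        result = map_probes(pm, build_index(bundle.genome, 25))
        anns = annotate_probes(result.unique_hits, bundle.features, "region")
        sets = group_probesets(anns, "region")
        prev = None
        for m in (1, 2, 3, 5, 8):
            cur = {ps.name: ps.n_pm for ps in filter_min_probes(sets, m)}
            if prev is not None:
                assert set(cur) <= set(prev)
                assert all(prev[n] == c for n, c in cur.items())
            prev = cur

    def test_restricted_census_matches_truth(self, bundle):
        pm = [p for p in bundle.probes if p.kind == "PM"]
        result = map_probes(pm, build_index(bundle.genome, 25))
        anns = annotate_probes(result.unique_hits, bundle.features, "region")
        sets = filter_min_probes(group_probesets(anns, "region"), 3)
        assert {ps.name: ps.n_pm for ps in sets} == \
            bundle.truth.census("region", min_members=3)


class TestControlsAndModel:
    def _sets(self, bundle):
        pm = [p for p in bundle.probes if p.kind == "PM"]
        result = map_probes(pm, build_index(bundle.genome, 25))
        anns = annotate_probes(result.unique_hits, bundle.features, "region")
        return attach_mm(group_probesets(anns, "region"), bundle.probes)

    def test_controls_copied_verbatim(self, bundle):
        sets = merge_controls(self._sets(bundle), bundle.original_cdf)
        controls = [ps for ps in sets if ps.is_control]
        assert [ps.raw_unit for ps in controls] == bundle.original_cdf.units

    def test_no_original_cdf_is_a_warning_not_error(self, bundle, caplog):
        sets = self._sets(bundle)
        out = merge_controls(sets, None)
        assert out == sets

    def test_control_name_collision_rejected(self, bundle):
        sets = self._sets(bundle)
        sets[0].name = bundle.original_cdf.units[0].name
        with pytest.raises(ValueError, match="collides"):
            merge_controls(sets, bundle.original_cdf)

    def test_model_counts_and_disjointness(self, bundle):
        sets = merge_controls(self._sets(bundle), bundle.original_cdf)
        dims = (bundle.original_cdf.rows, bundle.original_cdf.cols)
        model = build_cdf_model(sets, dims, "CHIP")
        model.validate()
        assert len(model.units) == len(sets)
        # PM cells pairwise disjoint across non-control units
        pm_cells = [c for u in model.units if not u.name.startswith("AFFX")
                    for c in u.cells() if c.is_pm]
        coords = [(c.x, c.y) for c in pm_cells]
        assert len(coords) == len(set(coords))

    def test_out_of_grid_cell_rejected(self, bundle):
        sets = self._sets(bundle)
        with pytest.raises(Exception, match="outside|grid"):
            build_cdf_model(sets, (2, 2), "CHIP")

    def test_empty_probesets_give_empty_model(self):
        model = build_cdf_model([], (4, 4), "CHIP")
        assert model.units == []
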