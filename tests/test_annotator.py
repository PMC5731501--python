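"""Annotation resolution: containment, priority rule, policies."""

import pytest

from recdf.annotator import (AnnotationConfig, annotate_probes,
                             extract_region_intervals, resolve_annotation)
from recdf.formats import Feature, GenomeSequence, ProbeRecord
from recdf.mapper import ProbeHit, build_index, map_probes


def F(start, end, cls, gene="G1", tx="T1", strand="-", chrom="c"):
    return Feature(chrom, start, end, strand, cls, gene, tx)


class TestExtractRegionIntervals:
    def test_region_mode_class_filter(self):
        feats = [F(1, 500, "gene"), F(1, 500, "transcript"),
                 F(1, 200, "exon"), F(1, 50, "UTR5"), F(51, 200, "CDS"),
                 F(300, 500, "exon"), F(400, 500, "UTR3")]
        got = {f.feature_class for f in extract_region_intervals(feats, "region")}
        assert got == {"exon", "UTR5", "CDS", "UTR3"}

    def test_noncoding_gene_keeps_exons_only(self):
        feats = [F(1, 700, "gene"), F(1, 700, "transcript"),
                 F(1, 200, "exon"), F(500, 700, "exon")]
        got = extract_region_intervals(feats, "region")
        assert [f.feature_class for f in got] == ["exon", "exon"]

    def test_gene_mode_keeps_spans_only(self):
        feats = [F(1, 500, "gene"), F(1, 200, "exon")]
        got = extract_region_intervals(feats, "gene")
        assert [f.feature_class for f in got] == ["gene"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            extract_region_intervals([], "probe")


class TestResolveAnnotation:
    def test_utr_wins_over_exon_of_same_gene(self):
        cands = [F(300, 600, "exon"), F(400, 600, "UTR3")]
        key, feature, detail = resolve_annotation(cands, "region")
        assert key == ("G1", "UTR", "-")
        assert detail == "UTR3"

    def test_empty_candidates_discarded(self):
        assert resolve_annotation([], "region") is None

    def test_cds_vs_exon_under_both_policies(self):
        cands = [F(1, 300, "exon"), F(51, 250, "CDS")]
        key, _, _ = resolve_annotation(
            cands, "region", AnnotationConfig(priority="utr_cds_exon"))
        assert key == ("G1", "CDS", "-")
        key, _, _ = resolve_annotation(
            cands, "region", AnnotationConfig(priority="utr_exon_cds"))
        assert key == ("G1", "exon", "-")

    def test_cross_gene_keep_first_vs_discard(self):
        cands = sorted(
            [F(100, 600, "exon", gene="GA"), F(300, 600, "UTR3", gene="GA"),
             F(350, 550, "exon", gene="GB", tx="TB", strand="+")],
            key=lambda f: (f.start, -f.end))
        key, _, _ = resolve_annotation(
            cands, "region", AnnotationConfig(cross_gene="keep_first"))
        assert key == ("GA", "UTR", "-")
        assert resolve_annotation(
            cands, "region", AnnotationConfig(cross_gene="discard")) is None

    def test_transcript_mode_takes_first_candidate(self):
        cands = [F(1, 900, "transcript", tx="T1"),
                 F(1, 500, "transcript", tx="T2")]
        key, _, _ = resolve_annotation(cands, "transcript")
        assert key == "T1"


class TestAnnotateProbes:
    def _map(self, bundle):
        pm = [p for p in bundle.probes if p.kind == "PM"]
        return map_probes(pm, build_index(bundle.genome, 25))

    def test_one_annotation_per_probe(self, bundle):
        result = self._map(bundle)
        for mode in ("region", "gene", "transcript"):
            anns = annotate_probes(result.unique_hits, bundle.features, mode)
            cells = [a.hit.probe.cell for a in anns]
            assert len(cells) == len(set(cells))

    def test_containment_soundness(self, bundle):
        # re-check containment directly, independent of the NCList
        result = self._map(bundle)
        for mode in ("region", "gene", "transcript"):
            for a in annotate_probes(result.unique_hits, bundle.features, mode):
                assert a.feature.chrom == a.hit.chrom
                assert a.feature.start <= a.hit.start
                assert a.hit.end <= a.feature.end

    def test_intronic_probes_transcript_level_only(self, bundle):
        result = self._map(bundle)
        intronic = {(t["x"], t["y"]) for t in bundle.truth.probes.values()
                    if t["label"] == "intronic"}
        assert intronic
        region = {a.hit.probe.cell for a in annotate_probes(
            result.unique_hits, bundle.features, "region")}
        gene = {a.hit.probe.cell for a in annotate_probes(
            result.unique_hits, bundle.features, "gene")}
        tx = {a.hit.probe.cell for a in annotate_probes(
            result.unique_hits, bundle.features, "transcript")}
        assert not (intronic & region) and not (intronic & gene)
        assert intronic <= tx

    def test_region_gene_consistency(self, bundle):
        # probes annotated to gene G at region level are exactly the
        # gene-level probes of G under the derived gene mode
        result = self._map(bundle)
        region = annotate_probes(result.unique_hits, bundle.features, "region")
        gene = annotate_probes(result.unique_hits, bundle.features, "gene")
        by_gene_region = {}
        for a in region:
            by_gene_region.setdefault(a.target_key[0], set()).add(
                a.hit.probe.cell)
        by_gene = {}
        for a in gene:
            by_gene.setdefault(a.target_key, set()).add(a.hit.probe.cell)
        assert by_gene_region == by_gene

    def test_transcript_mode_superset_of_region_mode(self, bundle):
        result = self._map(bundle)
        region = {a.hit.probe.cell for a in annotate_probes(
            result.unique_hits, bundle.features, "region")}
        tx = {a.hit.probe.cell for a in annotate_probes(
            result.unique_hits, bundle.features, "transcript")}
        assert region <= tx

    def test_hit_on_unannotated_chromosome_discarded(self):
        genome = GenomeSequence({"cX": "ACGTACGTACGTACGTACGTA"})
        probe = ProbeRecord("p", 0, 0, "ACGTACGTAC", None, "PM")
        index = build_index(genome, 10)
        result = map_probes([probe], index)
        feats = [F(1, 100, "exon", chrom="cY")]
        assert annotate_probes(result.unique_hits, feats, "region") == []

    def test_full_truth_recovery_all_modes(self, bundle):
        result = self._map(bundle)
        for mode, field in (("region", "region"), ("gene", "gene"),
                            ("transcript", "transcript")):
            anns = annotate_probes(result.unique_hits, bundle.features, mode)
            got = {}
            for a in anns:
                k = a.target_key
                got[f"{a.hit.probe.x}:{a.hit.probe.y}"] = (
                    list(k) if isinstance(k, tuple) else k)
            exp = {pk: t["keys"][field]
                   for pk, t in bundle.truth.probes.items()
                   if t["keys"][field] is not None}
            assert got == exp

    def test_literal_priority_matches_truth(self, bundle):
        result = self._map(bundle)
        cfg = AnnotationConfig(priority="utr_exon_cds")
        anns = annotate_probes(result.unique_hits, bundle.features, "region",
                               cfg)
        got = {f"{a.hit.probe.x}:{a.hit.probe.y}": list(a.target_key)
               for a in anns}
        exp = {pk: t["keys"]["region_literal"]
               for pk, t in bundle.truth.probes.items()
               if t["keys"]["region_literal"] is not None}
        assert got == exp

    def test_cross_gene_discard_matches_truth(self, bundle):
        result = self._map(bundle)
        cfg = AnnotationConfig(cross_gene="discard")
        anns = annotate_probes(result.unique_hits, bundle.features, "region",
                               cfg)
        got = {f"{a.hit.probe.x}:{a.hit.probe.y}": list(a.target_key)
               for a in anns}
        exp = {pk: t["keys"]["region_xdiscard"]
               for pk, t in bundle.truth.probes.items()
               if t["keys"]["region_xdiscard"] is not None}
        assert got == exp
        dropped = {pk for pk, t in bundle.truth.probes.items()
                   if t["label"] == "cross_gene"}
        assert dropped and not (dropped & set(got))
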