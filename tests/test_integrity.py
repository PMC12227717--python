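"""Lesion calling, fusion detection, rescue scanning and verdicts."""

import numpy as np
import pytest

from pseudoscan import (
    TargetLocus,
    assemble_cds,
    classify_gene,
    classify_splice_site,
    detect_exon_fusion,
    evaluate_locus,
    evolve_along_tree,
    locate_exons,
    orient_locus,
    scan_rescue_splice_site,
)
from pseudoscan import simulate as sim
from pseudoscan.integrity import MUTATED, CANONICAL, NONCANONICAL_TOLERATED, Lesion
from pseudoscan.mapping import ExonHit


class TestClassifySpliceSite:
    @pytest.mark.parametrize(
        "dinuc,side,category",
        [
            ("GT", "donor", CANONICAL),
            ("GC", "donor", NONCANONICAL_TOLERATED),
            ("AT", "donor", MUTATED),
            ("AG", "acceptor", CANONICAL),
            ("AC", "acceptor", NONCANONICAL_TOLERATED),
            ("AA", "acceptor", MUTATED),
            ("AG", "donor", MUTATED),  # sides are not interchangeable
        ],
    )
    def test_categories(self, dinuc, side, category):
        assert classify_splice_site(dinuc, side).category == category

    def test_n_is_mutated_low_confidence(self):
        call = classify_splice_site("NT", "donor")
        assert call.category == MUTATED and call.low_confidence

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            classify_splice_site("GTA", "donor")


def _verdict_for(model, loci, species):
    locus = next(l for l in loci if l.species_id == species)
    return evaluate_locus(model, locus)


class TestExonLesions:
    def test_clean_locus_has_no_lesions(self, full_model, clean_quartet):
        loci, _ = clean_quartet
        v = _verdict_for(full_model, loci, "A")
        assert v.lesions == [] and v.status == "INTACT"

    def test_one_nt_deletion_is_disrupting_frameshift(self, full_model, quartet_tree, rng):
        ev = sim.make_frameshift("A", 6, 40, 1, insert=False, rng=rng)
        loci, _ = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [ev], seed=6)
        v = _verdict_for(full_model, loci, "A")
        fs = [l for l in v.lesions if l.kind == "FRAMESHIFT_INDEL"]
        assert len(fs) == 1 and fs[0].disrupting and fs[0].exon_number == 6
        assert fs[0].reference and not fs[0].observed
        assert v.status == "PSEUDOGENE"

    def test_three_nt_deletion_is_nondisrupting_note(self, full_model, quartet_tree, rng):
        # a 3-base microdeletion preserves the reading frame: recorded, not disruptive
        ev = sim.make_inframe_indel(full_model, "A", 4, 30, 3, insert=False, rng=rng)
        loci, _ = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [ev], seed=6)
        v = _verdict_for(full_model, loci, "A")
        notes = [l for l in v.lesions if l.kind == "INFRAME_INDEL"]
        assert len(notes) == 1 and not notes[0].disrupting
        assert v.status == "INTACT"

    def test_premature_stop_detected_at_planted_codon(self, full_model, quartet_tree):
        ev = sim.make_premature_stop(full_model, "A", 8, 6)
        loci, _ = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [ev], seed=6)
        v = _verdict_for(full_model, loci, "A")
        stops = [l for l in v.lesions if l.kind == "PREMATURE_STOP"]
        assert len(stops) == 1 and stops[0].exon_number == 8
        assert stops[0].offset == ev.detail["offset"]
        assert not stops[0].secondary

    def test_stops_downstream_of_frameshift_are_secondary(
        self, full_model, quartet_tree, rng
    ):
        ev = sim.make_frameshift("A", 4, 50, 2, insert=True, rng=rng)
        loci, _ = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [ev], seed=6)
        v = _verdict_for(full_model, loci, "A")
        stops = [l for l in v.lesions if l.kind == "PREMATURE_STOP"]
        assert stops, "a frameshift should manufacture downstream STOPs"
        assert all(s.secondary for s in stops)
        assert [l.kind for l in v.primary_lesions] == ["FRAMESHIFT_INDEL"]


class TestFusion:
    def test_intact_donor_yields_no_call(self, full_model, clean_quartet):
        loci, _ = clean_quartet
        oriented = orient_locus(loci[0], full_model)
        hits = locate_exons(full_model, oriented)
        assert detect_exon_fusion(oriented, hits[9], hits[10], full_model) is None

    def test_99nt_clean_intron_incorporates_33_residues(self, full_model, quartet_tree, rng):
        ev = sim.make_exon_fusion(full_model, "A", 11, intron_length=99, rng=rng)
        loci, _ = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [ev], seed=6)
        v = _verdict_for(full_model, loci, "A")
        assert v.status == "INTACT_FUSION"
        assert len(v.fusions) == 1
        f = v.fusions[0]
        assert (f.upstream_exon, f.downstream_exon) == (11, 12)
        assert f.intron_length == 99 and f.incorporated_residues == 33
        donor = [l for l in v.lesions if l.kind == "SPLICE_DONOR_MUT"]
        assert donor and not donor[0].disrupting and "fusion" in donor[0].note

    def test_100nt_intron_is_no_fusion_and_donor_disrupts(
        self, full_model, quartet_tree, rng
    ):
        ev = sim.make_exon_fusion(full_model, "A", 11, intron_length=99, rng=rng)
        loci, truth = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [ev], seed=6)
        locus = next(l for l in loci if l.species_id == "A")
        # lengthen the retained intron to 100 nt: 100 % 3 != 0, fusion impossible
        e11_end = truth.tips["A"].exon_intervals[11][1]
        seq = locus.sequence[: e11_end + 50] + "A" + locus.sequence[e11_end + 50 :]
        # rescue scanning off: this isolates the fusion frame arithmetic
        v = evaluate_locus(full_model, TargetLocus("A", "mod", seq), rescue_window=0)
        assert v.fusions == []
        assert v.status == "PSEUDOGENE"
        donor = [l for l in v.lesions if l.kind == "SPLICE_DONOR_MUT"]
        assert donor and donor[0].disrupting

    def test_fusion_alone_never_pseudogene(self, full_model, quartet_tree, rng):
        # fusion neutrality across several draws
        for seed in (1, 2, 3):
            r = np.random.default_rng(seed)
            ev = sim.make_exon_fusion(full_model, "A", 9, intron_length=45, rng=r)
            loci, _ = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [ev], seed=6)
            v = _verdict_for(full_model, loci, "A")
            assert v.status == "INTACT_FUSION"


class TestRescueScan:
    def _locus_with_suffix(self, suffix):
        exon = "ATG" + "GCA" * 20  # 63 nt, no STOP anywhere in frame
        seq = "C" * 20 + exon + suffix + "C" * 40
        hit = ExonHit(exon_number=2, found=True, target_interval=(20, 20 + len(exon)))
        return TargetLocus("x", "rescue", seq), hit

    def test_gt_at_plus6_in_frame_is_rescue(self):
        locus, hit = self._locus_with_suffix("AACCAC" + "GT" + "CCCCCCCCCC")
        b = scan_rescue_splice_site(locus, hit, "donor", window=30, cds_offset=0)
        assert b == hit.target_interval[1] + 6

    def test_gt_only_at_plus7_is_frameshift_no_rescue(self):
        locus, hit = self._locus_with_suffix("AACCACC" + "GT" + "CCCCCCCCC")
        assert scan_rescue_splice_site(locus, hit, "donor", window=30, cds_offset=0) is None

    def test_no_canonical_dinucleotide_in_window(self):
        locus, hit = self._locus_with_suffix("C" * 40)
        assert scan_rescue_splice_site(locus, hit, "donor", window=30, cds_offset=0) is None

    def test_rescue_rejected_if_gained_region_has_stop(self):
        locus, hit = self._locus_with_suffix("TAACCC" + "GT" + "CCCCCCCCCC")
        assert scan_rescue_splice_site(locus, hit, "donor", window=30, cds_offset=0) is None


class TestAssembleCds:
    def test_zero_rate_reproduces_reference(self, full_model, clean_quartet):
        loci, _ = clean_quartet
        oriented = orient_locus(loci[0], full_model)
        hits = locate_exons(full_model, oriented)
        cds, cont, first = assemble_cds(hits, [], [], full_model, oriented)
        assert cds == full_model.cds and cont and first is None

    def test_fusion_adds_99nt_and_stays_continuous(self, full_model, quartet_tree, rng):
        ev = sim.make_exon_fusion(full_model, "A", 11, intron_length=99, rng=rng)
        loci, _ = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [ev], seed=6)
        v = _verdict_for(full_model, loci, "A")
        assert v.cds is not None and len(v.cds) == len(full_model.cds) + 99

    def test_frameshift_breaks_orf_with_position(self, full_model, quartet_tree, rng):
        ev = sim.make_frameshift("A", 4, 50, 2, insert=True, rng=rng)
        loci, _ = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [ev], seed=6)
        locus = orient_locus(next(l for l in loci if l.species_id == "A"), full_model)
        hits = locate_exons(full_model, locus)
        cds, cont, first = assemble_cds(hits, [], [], full_model, locus)
        assert not cont and first is not None
        # the first premature STOP can only appear after the planted shift
        upstream = sum(len(e.sequence) for e in full_model.exons[:2])
        assert first >= upstream


class TestVerdicts:
    def test_cetacean_style_shared_lesions(self, full_model, quartet_tree, rng):
        # donor mutations after exons 5 and 9, acceptor ahead of 11, plus a frameshift
        events = [
            sim.make_donor_mut("n1", 5),
            sim.make_donor_mut("n1", 9),
            sim.make_acceptor_mut("n1", 11),
            sim.make_frameshift("A", 3, 30, 2, insert=False, rng=rng),
        ]
        loci, _ = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, events, seed=6)
        for sp in ("A", "B"):
            v = _verdict_for(full_model, loci, sp)
            assert v.status == "PSEUDOGENE"
            kinds = {(l.kind, l.exon_number) for l in v.primary_lesions}
            assert {("SPLICE_DONOR_MUT", 5), ("SPLICE_DONOR_MUT", 9),
                    ("SPLICE_ACCEPTOR_MUT", 11)} <= kinds

    def test_splice_only_pseudogene_is_flagged(self, full_model, quartet_tree):
        loci, _ = evolve_along_tree(
            full_model, quartet_tree, 0.0, 0.0, [sim.make_acceptor_mut("A", 3)], seed=6
        )
        v = _verdict_for(full_model, loci, "A")
        assert v.status == "PSEUDOGENE" and "splice_only" in v.confidence

    def test_n_run_makes_verdict_incomplete(self, full_model, clean_quartet):
        loci, truth = clean_quartet
        locus = loci[0]
        s, e = truth.tips["A"].exon_intervals[7]
        seq = locus.sequence[: s - 5] + "N" * (e - s + 10) + locus.sequence[e + 5 :]
        v = evaluate_locus(full_model, TargetLocus("A", "gap", seq))
        assert v.status == "INCOMPLETE"
        h7 = next(h for h in v.hits if h.exon_number == 7)
        assert not h7.found and h7.unresolved

    def test_adding_disrupting_lesion_never_moves_toward_intact(
        self, full_model, clean_quartet
    ):
        loci, _ = clean_quartet
        v = _verdict_for(full_model, loci, "A")
        rank = {"PSEUDOGENE": 0, "INTACT_FUSION": 1, "INTACT": 2}
        extra = Lesion(kind="FRAMESHIFT_INDEL", exon_number=5, offset=1,
                       observed="", reference="G", disrupting=True)
        worse = classify_gene(v.hits, list(v.lesions) + [extra], v.fusions, True)
        assert rank[worse.status] <= rank[v.status]
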