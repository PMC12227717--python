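"""Simulator contracts: determinism, Dollo inheritance, rate calibration."""

import json

import numpy as np
import pytest

from pseudoscan import (
    build_reference_model,
    evolve_along_tree,
    run_scenario,
    random_scenario,
    write_fixture,
)
from pseudoscan import simulate as sim
from pseudoscan import treeutil
from tests.conftest import SMALL_MODEL_KW


class TestBuildReferenceModel:
    def test_all_gt_donors_when_forced(self):
        m = build_reference_model(**SMALL_MODEL_KW, gc_donor_fraction=0.0, seed=3)
        assert all(i[:2] == "GT" for i in m.introns)
        assert all(i[-2:] == "AG" for i in m.introns)

    def test_all_gc_donors_when_forced(self):
        m = build_reference_model(**SMALL_MODEL_KW, gc_donor_fraction=1.0, seed=3)
        assert all(i[:2] == "GC" for i in m.introns)

    def test_same_seed_byte_identical(self):
        a = build_reference_model(**SMALL_MODEL_KW, seed=9)
        b = build_reference_model(**SMALL_MODEL_KW, seed=9)
        assert a.to_json() == b.to_json()

    def test_infeasible_constraints_rejected(self):
        with pytest.raises(sim.SimulationError):
            build_reference_model(n_exons=1, seed=1)


class TestEvolveAlongTree:
    def test_zero_rate_identity(self, full_model, quartet_tree, clean_quartet):
        loci, truth = clean_quartet
        ref = loci[0].sequence
        assert all(l.sequence == ref for l in loci)
        assert all(t.n_substitutions == 0 for t in truth.tips.values())

    def test_planted_donor_mut_inherited_by_whole_clade(self, full_model, quartet_tree):
        # stem of the (A,B) clade: both tips carry the AT donor, truth lists 1 event
        ev = sim.make_donor_mut("n1", 11, "AT")
        loci, truth = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [ev], seed=4)
        for sp in ("A", "B"):
            tip = truth.tips[sp]
            assert [e.kind for e in tip.events] == ["SPLICE_DONOR_MUT"]
            locus = next(l for l in loci if l.species_id == sp)
            e_end = tip.exon_intervals[11][1]
            assert locus.sequence[e_end : e_end + 2] == "AT"
        for sp in ("C", "D"):
            assert truth.tips[sp].events == []

    def test_fusion_intron_adds_99nt_to_cds_span(self, full_model, quartet_tree, rng):
        ev = sim.make_exon_fusion(full_model, "n1", 11, intron_length=99, rng=rng)
        loci, truth = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [ev], seed=4)
        tip = truth.tips["A"]
        assert tip.fused_introns == [(11, 12, 99)]
        gap = tip.exon_intervals[12][0] - tip.exon_intervals[11][1]
        assert gap == 99

    def test_dollo_consistency_random_scenarios(self):
        # a planted event appears in a tip iff the tip descends from its branch
        for seed in range(5):
            scen = random_scenario(8, seed=300 + seed, n_events=5)
            model, loci, truth = run_scenario(scen)
            tree = treeutil.load_tree(scen.tree_newick)
            below = {
                treeutil.branch_id(nd): set(treeutil.leaves_under(nd))
                for nd in treeutil.branch_nodes(tree)
            }
            for ev in scen.planted:
                for sp, tip in truth.tips.items():
                    carried = ev in tip.events
                    assert carried == (sp in below[ev.branch])

    def test_event_on_deleted_exon_rejected(self, full_model, quartet_tree):
        events = [
            sim.make_exon_deletion("n1", 7),
            sim.make_premature_stop(full_model, "A", 7, 5),
        ]
        with pytest.raises(sim.SimulationError, match="deleted"):
            evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, events, seed=1)

    def test_negative_rate_rejected(self, full_model, quartet_tree):
        with pytest.raises(ValueError):
            evolve_along_tree(full_model, quartet_tree, -0.1, 0.0, [], seed=1)

    def test_substitution_count_poisson_mean(self):
        # empirical mean over 200 replicates within 3 SE of rate x length x sites
        model = build_reference_model(
            n_exons=4, exon_length_range=(60, 90), intron_length_range=(100, 150), seed=2
        )
        rate, blen = 0.01, 1.0
        locus_len = (
            200
            + sum(len(e.sequence) for e in model.exons)
            + sum(len(i) for i in model.introns)
        )
        masked = 4 * len(model.introns) + 6  # splice dinucleotides + start/stop codons
        expected = rate * blen * (locus_len - masked)
        counts = []
        for s in range(200):
            _, truth = evolve_along_tree(model, "(A:1,B:0.0);", rate, 0.0, [], seed=s)
            counts.append(truth.tips["A"].n_substitutions)
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - expected) <= 3 * se

    def test_two_seeds_same_planted_coordinates_different_noise(self, full_model, quartet_tree):
        ev = sim.make_premature_stop(full_model, "A", 5, 4)
        _, t1 = evolve_along_tree(full_model, quartet_tree, 0.01, 0.0, [ev], seed=1)
        _, t2 = evolve_along_tree(full_model, quartet_tree, 0.01, 0.0, [ev], seed=2)
        assert t1.tips["A"].events == t2.tips["A"].events  # identical planted detail
        assert t1.tips["A"].n_substitutions != t2.tips["A"].n_substitutions or (
            t1.tips["B"].n_substitutions != t2.tips["B"].n_substitutions
        )


class TestFixtureIO:
    def test_round_trip(self, tmp_path, full_model, quartet_tree):
        ev = sim.make_donor_mut("n1", 5, "AT")
        loci, truth = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [ev], seed=8)
        write_fixture(loci, truth, tmp_path, config={"seed": 8})
        loci2, truth2 = sim.read_fixture(tmp_path)
        assert {l.species_id: l.sequence for l in loci} == {
            l.species_id: l.sequence for l in loci2
        }
        assert truth2.to_dict() == truth.to_dict()
        n_truth_events = sum(len(t.events) for t in truth2.tips.values())
        assert n_truth_events == 2  # one event inherited by the two clade tips

    def test_scenario_reproduces_byte_identically(self, tmp_path):
        scen = random_scenario(6, seed=77, sub_rate=0.005, n_events=4)
        blob = json.dumps(scen.to_dict(), sort_keys=True)
        again = sim.Scenario.from_dict(json.loads(blob))
        m1, l1, t1 = run_scenario(scen)
        m2, l2, t2 = run_scenario(again)
        assert m1.to_json() == m2.to_json()
        assert [x.sequence for x in l1] == [x.sequence for x in l2]
        assert t1.to_dict() == t2.to_dict()


def test_random_scenario_covers_all_event_kinds():
    kinds = set()
    for s in range(12):
        scen = random_scenario(8, seed=500 + s, n_events=5)
        kinds |= {e.kind for e in scen.planted}
    assert kinds == set(sim.EVENT_KINDS)
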