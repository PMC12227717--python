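"""Lesion signatures and Dollo parsimony event counting."""

import numpy as np
import pytest

from pseudoscan import (
    evaluate_locus,
    lesion_signature,
    map_events_on_tree,
    min_loss_events,
    run_scenario,
)
from pseudoscan import simulate as sim
from pseudoscan import treeutil
from pseudoscan.dollo import annotated_newick, place_signature
from pseudoscan.integrity import Lesion
from tests.oracles import oracle_min_dollo_events


def _donor_lesion(exon, observed="AT"):
    return Lesion(kind="SPLICE_DONOR_MUT", exon_number=exon, boundary="donor",
                  observed=observed, reference="GT")


class TestSignatures:
    def test_identical_donor_lesions_share_signature(self):
        a = lesion_signature(_donor_lesion(5), "SCNN1D")
        b = lesion_signature(_donor_lesion(5), "SCNN1D")
        assert a == b

    def test_different_observed_dinucleotides_differ(self):
        a = lesion_signature(_donor_lesion(5, "AT"), "G")
        b = lesion_signature(_donor_lesion(5, "AC"), "G")
        assert a != b

    def test_indel_offsets_within_tolerance_bucket_match(self):
        l1 = Lesion(kind="FRAMESHIFT_INDEL", exon_number=4, offset=3, reference="G")
        l2 = Lesion(kind="FRAMESHIFT_INDEL", exon_number=4, offset=5, reference="G")
        assert lesion_signature(l1, "G", 3) == lesion_signature(l2, "G", 3)

    def test_offsets_in_different_buckets_differ(self):
        l1 = Lesion(kind="FRAMESHIFT_INDEL", exon_number=4, offset=2, reference="G")
        l2 = Lesion(kind="FRAMESHIFT_INDEL", exon_number=4, offset=8, reference="G")
        assert lesion_signature(l1, "G", 3) != lesion_signature(l2, "G", 3)


class TestPlacement:
    def test_sister_carriers_one_event_at_mrca(self):
        tree = treeutil.load_tree("((A,B),C);")
        p = place_signature(tree, "sig", {"A", "B"})
        assert p.n_events == 1 and p.monophyletic
        assert set(treeutil.leaves_under(treeutil.find_node(tree, p.placement_node))) == {"A", "B"}

    def test_non_monophyletic_carriers_two_events(self):
        tree = treeutil.load_tree("((A,B),C);")
        p = place_signature(tree, "sig", {"A", "C"})
        assert p.n_events == 2 and not p.monophyletic

    def test_all_cetacean_carriers_single_stem_event(self):
        # emulated whale/artiodactyl topology: one origin at the cetacean stem
        newick = "(((Tt,Pp),(Bm,Ba)),(Ha,(Bt,Oa)));"
        cet = {"Tt", "Pp", "Bm", "Ba"}
        placements = map_events_on_tree(
            {sp: ["donor5_AT"] for sp in cet} | {sp: [] for sp in ("Ha", "Bt", "Oa")},
            newick,
        )
        assert len(placements) == 1
        p = placements[0]
        assert p.n_events == 1 and p.monophyletic
        tree = treeutil.load_tree(newick)
        assert set(treeutil.leaves_under(treeutil.find_node(tree, p.placement_node))) == cet

    def test_unknown_carrier_species_raises(self):
        with pytest.raises(KeyError, match="ghost"):
            map_events_on_tree({"ghost": ["sig"]}, "((A,B),C);")


class TestMinLossEvents:
    def test_simple_clade_loss(self):
        n, stems = min_loss_events(
            {"A": "PSEUDOGENE", "B": "PSEUDOGENE", "C": "INTACT"}, "((A,B),C);"
        )
        assert n == 1 and len(stems) == 1

    def test_phocid_style_independent_losses(self):
        # no shared lesions between the elephant-seal pair and the Weddell seal:
        # on a soft topology the two losses cannot be united below one node
        n, _ = min_loss_events(
            {"M1": "PSEUDOGENE", "M2": "PSEUDOGENE", "W": "PSEUDOGENE",
             "O1": "INTACT", "O2": "INTACT"},
            "((M1,M2),W,O1,O2);",
        )
        assert n == 2

    def test_all_intact_zero_events(self):
        n, stems = min_loss_events(
            {"A": "INTACT", "B": "INTACT", "C": "INTACT"}, "((A,B),C);"
        )
        assert n == 0 and stems == []

    def test_incomplete_tips_are_pruned(self):
        # the INCOMPLETE tip between two pseudogenes must not split the event
        n, _ = min_loss_events(
            {"A": "PSEUDOGENE", "B": "INCOMPLETE", "C": "PSEUDOGENE", "D": "INTACT"},
            "(((A,B),C),D);",
        )
        assert n == 1

    def test_empty_tree_rejected(self):
        with pytest.raises(Exception):
            min_loss_events({}, ";")


class TestOracleAgreement:
    def test_matches_exhaustive_search_on_random_scenarios(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n_tips = int(rng.integers(3, 9))
            newick = sim.make_random_tree(n_tips, rng)
            tree = treeutil.load_tree(newick)
            tips = treeutil.tip_labels(tree)
            k = int(rng.integers(1, n_tips + 1))
            carriers = set(rng.choice(tips, size=k, replace=False))
            verdicts = {
                sp: ("PSEUDOGENE" if sp in carriers else "INTACT") for sp in tips
            }
            n, _ = min_loss_events(verdicts, newick)
            assert n == oracle_min_dollo_events(tree, carriers)

    def test_adding_a_carrier_never_raises_mrca_depth(self):
        tree = treeutil.load_tree("(((A,B),(C,D)),(E,F));")
        base = place_signature(tree, "s", {"A", "B"})
        wider = place_signature(tree, "s", {"A", "B", "C"})
        anc = treeutil.find_node(tree, base.placement_node)
        anc_labels = set()
        nd = anc
        while nd is not None:
            anc_labels.add(treeutil.branch_id(nd))
            nd = nd.parent_node
        assert wider.placement_node in anc_labels


class TestSimulatorClosure:
    def test_planted_event_placed_on_its_branch_at_zero_rate(self, full_model):
        newick = "(((A:1,B:1):1,C:1):1,(D:1,E:1):1);"
        ev = sim.make_donor_mut("n1", 5, "AT")  # stem of ((A,B),C)
        loci, truth = sim.evolve_along_tree(full_model, newick, 0.0, 0.0, [ev], seed=3)
        verdicts = {l.species_id: evaluate_locus(full_model, l) for l in loci}
        sigs = {
            sp: [lesion_signature(le, "G") for le in v.primary_lesions]
            for sp, v in verdicts.items()
        }
        placements = map_events_on_tree(sigs, newick)
        assert len(placements) == 1
        assert placements[0].event_branches == ("n1",)
        assert placements[0].n_events == 1


def test_annotated_newick_contains_event_marks():
    tree = "((A,B),C);"
    placements = map_events_on_tree({"A": ["sigX"], "B": ["sigX"]}, tree)
    out = annotated_newick(tree, placements)
    assert "#" in out and out.strip().endswith(";")
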