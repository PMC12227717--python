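"""NG86 counting, Fitch-based partition omega, and the per-site screen."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudoscan import (
    clade_partition_dnds,
    ng86_pairwise,
    ng86_site_counts,
    simulate_codon_alignment,
    site_selection_counts,
)
from pseudoscan import treeutil
from pseudoscan.selection import METHOD_TAG, StopCodonError, fitch_ancestral_states, pathway_counts
from tests.oracles import SENSE, oracle_pathway_counts, oracle_site_counts

codons = st.sampled_from(SENSE)


class TestSiteCounts:
    def test_phenylalanine_codon(self):
        n, s = ng86_site_counts("TTT")
        assert s == pytest.approx(1 / 3) and n == pytest.approx(8 / 3)

    def test_tryptophan_has_no_synonymous_sites(self):
        assert ng86_site_counts("TGG") == (3.0, 0.0)

    def test_normalisation_over_all_sense_codons(self):
        for c in SENSE:
            n, s = ng86_site_counts(c)
            assert n + s == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(StopCodonError):
            ng86_site_counts("TGA")

    def test_matches_independent_oracle(self):
        for c in SENSE:
            n, s = ng86_site_counts(c)
            on, os_ = oracle_site_counts(c)
            assert (n, s) == pytest.approx((on, os_))


class TestPairwise:
    def test_identical_sequences(self):
        r = ng86_pairwise("ATGGCA", "ATGGCA")
        assert r.Nd == r.Sd == 0.0 and r.omega is None
        assert r.method == METHOD_TAG

    def test_single_synonymous_difference(self):
        r = ng86_pairwise("TTT", "TTC")
        assert (r.Nd, r.Sd) == (0.0, 1.0)
        assert not r.correction_valid  # one codon: pS exceeds the JC domain

    def test_two_difference_codon_averages_both_orderings(self):
        # TTT -> GTA via GTT (n,s)=(1,1) or via TTA (n,s)=(2,0): mean (1.5, 0.5)
        r = ng86_pairwise("TTT", "GTA")
        assert (r.Nd, r.Sd) == pytest.approx((1.5, 0.5))

    def test_gap_codons_skipped_pairwise(self):
        r = ng86_pairwise("ATG---GCA", "ATGCCAGCA")
        assert r.codons_compared == 2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            ng86_pairwise("ATG", "ATGGCA")

    @given(a=st.lists(codons, min_size=2, max_size=8), b=st.lists(codons, min_size=2, max_size=8))
    @settings(max_examples=40, derandomize=True)
    def test_symmetry(self, a, b):
        n = min(len(a), len(b))
        s1, s2 = "".join(a[:n]), "".join(b[:n])
        r1, r2 = ng86_pairwise(s1, s2), ng86_pairwise(s2, s1)
        assert (r1.Nd, r1.Sd, r1.N, r1.S) == pytest.approx((r2.Nd, r2.Sd, r2.N, r2.S))

    def test_jc_limit_small_divergence(self):
        # dN -> pN and dS -> pS as divergence -> 0 (checked at p < 0.01)
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(SENSE) for _ in range(400))
        mutated = list(base)
        mutated[33] = "C" if base[33] != "C" else "G"  # one substitution
        r = ng86_pairwise(base, "".join(mutated))
        for p, d in ((r.pN, r.dN), (r.pS, r.dS)):
            if p > 0:
                assert p < 0.01 and abs(d - p) / p < 0.01

    def test_all_codon_pairs_match_pathway_oracle(self):
        # exact equivalence with the brute-force enumerator on all 61 x 61 pairs
        for c1 in SENSE:
            for c2 in SENSE:
                nd, sd, ok = pathway_counts(c1, c2)
                ond, osd, ook = oracle_pathway_counts(c1, c2)
                assert ok == ook
                assert (nd, sd) == pytest.approx((ond, osd))


class TestFitchAndPartition:
    def test_fitch_parent_state_preferred_on_ties(self):
        states = fitch_ancestral_states("((A,B),(C,D));", {"A": "A", "B": "G", "C": "G", "D": "G"})
        # root resolves to G (majority via intersection), the AB ancestor keeps G
        assert states["n0"] == "G" and states["n1"] == "G"

    def test_two_tip_tree_reduces_to_pairwise(self):
        # with at most one difference per codon the counts must match exactly
        a = "TTTGCAATGCTG"
        b = "TTCGCAATGTTG"
        part = clade_partition_dnds({"a": a, "b": b}, "(a:1,b:1);", ["a"])
        r = ng86_pairwise(a, b)
        nd = part.counts_foreground[0] + part.counts_background[0]
        sd = part.counts_foreground[1] + part.counts_background[1]
        assert (nd, sd) == pytest.approx((r.Nd, r.Sd))
        assert (part.N, part.S) == pytest.approx((r.N, r.S))

    def test_foreground_must_be_a_clade(self):
        aln, tree = simulate_codon_alignment("((a:1,b:1),(c:1,d:1));", 30, 0.02, seed=1)
        with pytest.raises(ValueError, match="clade"):
            clade_partition_dnds(aln, tree, ["a", "c"])

    def test_neutral_simulation_omega_near_one(self):
        # pooled over 10 replicates both partitions sit near omega = 1
        tree = "((a:0.5,b:0.5):0.3,(c:0.5,d:0.5):0.3);"
        nf = sf = nb = sb = 0.0
        N = S = 1.0
        for s in range(10):
            aln, t = simulate_codon_alignment(tree, 300, 0.04, seed=50 + s)
            p = clade_partition_dnds(aln, t, ["a", "b"])
            nf += p.counts_foreground[0]; sf += p.counts_foreground[1]
            nb += p.counts_background[0]; sb += p.counts_background[1]
            N, S = p.N, p.S
        for nd, sd in ((nf, sf), (nb, sb)):
            omega = (nd / N) / (sd / S)
            assert 0.75 < omega < 1.3

    def test_star_tree_partition_tracks_mean_pairwise(self):
        aln, tree = simulate_codon_alignment("(a:1,b:1,c:1,d:1);", 400, 0.03, seed=9)
        tips = sorted(aln)
        pair_omegas = []
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                r = ng86_pairwise(aln[tips[i]], aln[tips[j]])
                if r.omega not in (None, math.inf):
                    pair_omegas.append(r.omega)
        part = clade_partition_dnds(aln, tree, ["a"])
        nd = part.counts_foreground[0] + part.counts_background[0]
        sd = part.counts_foreground[1] + part.counts_background[1]
        pooled = (nd / part.N) / (sd / part.S)
        assert pooled == pytest.approx(np.mean(pair_omegas), rel=0.35)


class TestSiteScreen:
    def test_invariant_site_is_neutral_with_zero_changes(self):
        aln = {sp: "ATGGCA" for sp in "abcd"}
        out = site_selection_counts(aln, "((a,b),(c,d));", alpha=0.1)
        assert out.labels == ["neutral", "neutral"]
        assert out.syn_changes.sum() == out.nonsyn_changes.sum() == 0

    def test_planted_synonymous_burst_is_labelled_negative(self):
        # a 4-fold degenerate site with many synonymous changes and no
        # nonsynonymous ones falls below its neutral expectation
        tips = list("abcdefgh")
        third = ["T", "C", "A", "G", "T", "C", "A", "G"]
        aln = {sp: "CT" + third[i] + "ATGATG" for i, sp in enumerate(tips)}
        tree = "(" + ",".join(f"{sp}:1" for sp in tips) + ");"
        out = site_selection_counts(aln, tree, alpha=0.1)
        assert out.labels[0] == "negative"
        assert out.nonsyn_changes[0] == 0
        assert out.labels[1:] == ["neutral", "neutral"]

    def test_label_counts_partition_the_alignment(self):
        aln, tree = simulate_codon_alignment("((a:1,b:1),(c:1,d:1));", 100, 0.05, seed=3)
        out = site_selection_counts(aln, tree, alpha=0.1)
        assert out.n_positive + out.n_negative + out.n_neutral == out.n_sites
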