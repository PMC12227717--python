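"""Counting-based selection screens: NG86 pairwise dN/dS and a per-site test.

This module is an explicitly simplified, counting-level analogue of
likelihood machinery (no ML, no rate variation, no branch-site models).
Every result carries ``method="NG86-counting"`` so the numbers are never
mistaken for codeml/HyPhy output.

* :func:`ng86_site_counts` / :func:`ng86_pairwise` implement the
  Nei-Gojobori (1986) method: fractional synonymous/nonsynonymous site
  counts per codon, pathway-averaged difference counts, and the
  Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3).
* :func:`clade_partition_dnds` reconstructs nucleotide ancestral states by
  Fitch parsimony on a rooted tree, counts synonymous/nonsynonymous changes
  per branch, and pools them into foreground-clade vs background omega.
* :func:`site_selection_counts` is a SLAC-style per-site screen: observed
  changes at each codon site are tested against the site's neutral
  nonsynonymous expectation with an exact binomial test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import binomtest

from . import treeutil
from .gene_model import STOP_CODONS, translate

METHOD_TAG = "NG86-counting"

_BASES = "ACGT"
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_BIT_BASE = {1: "A", 2: "C", 4: "G", 8: "T"}


class StopCodonError(ValueError):
    pass


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) potential site counts of one sense codon.

    Per position, the synonymous fraction is computed over the non-STOP
    single-nucleotide mutants; n + s = 3 for every codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set(_BASES):
        raise ValueError(f"codon over ACGT required, got {codon!r}")
    if codon in STOP_CODONS:
        raise StopCodonError(f"STOP codon {codon} has no site counts")
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        viable = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            viable += 1
            if translate(mut) == aa:
                syn += 1
        if viable:
            s += syn / viable
    return 3.0 - s, s


@lru_cache(maxsize=None)
def pathway_counts(codon1: str, codon2: str) -> tuple[float, float, bool]:
    """Pathway-averaged (nonsynonymous, synonymous) differences between codons.

    All orderings of the differing positions are enumerated; pathways passing
    through a STOP codon are excluded and the rest weighted equally.  Returns
    (nd, sd, ok); ok is False when every pathway is blocked (the codon pair
    must then be skipped and logged by the caller).
    """
    diffs = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diffs:
        return 0.0, 0.0, True
    total_n = total_s = 0.0
    n_paths = 0
    for order in itertools.permutations(diffs):
        cur = codon1
        n = s = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate(nxt) == translate(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            total_n += n
            total_s += s
            n_paths += 1
    if n_paths == 0:
        return 0.0, 0.0, False
    return total_n / n_paths, total_s / n_paths, True


def jukes_cantor(p: float) -> float:
    """JC69 distance correction d = -(3/4) ln(1 - 4p/3); inf when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DnDsResult:
    """NG86 pairwise result; ``omega`` is None when dN = dS = 0, inf when dS = 0 < dN."""

    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    omega: Optional[float]
    codons_compared: int
    skipped_codons: int = 0
    correction_valid: bool = True
    method: str = METHOD_TAG


def ng86_pairwise(cds1: str, cds2: str) -> DnDsResult:
    """Nei-Gojobori dN/dS between two aligned in-frame coding sequences.

    Sequences must be equal length, a multiple of 3 and free of internal
    STOPs; codons containing a gap (``-``) in either sequence are skipped
    pairwise.  Multi-difference codons are averaged over all STOP-free
    substitution pathways.
    """
    if len(cds1) != len(cds2):
        raise ValueError("sequences must be equal length")
    if len(cds1) % 3:
        raise ValueError("length must be a multiple of 3")
    cds1, cds2 = cds1.upper(), cds2.upper()
    N = S = Nd = Sd = 0.0
    compared = skipped = 0
    for i in range(0, len(cds1), 3):
        c1, c2 = cds1[i : i + 3], cds2[i : i + 3]
        if "-" in c1 or "-" in c2 or "N" in c1 or "N" in c2:
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError(f"internal STOP codon at position {i}")
        nd, sd, ok = pathway_counts(c1, c2)
        if not ok:
            skipped += 1
            continue
        n1, s1 = ng86_site_counts(c1)
        n2, s2 = ng86_site_counts(c2)
        N += (n1 + n2) / 2.0
        S += (s1 + s2) / 2.0
        Nd += nd
        Sd += sd
        compared += 1
    pN = Nd / N if N else 0.0
    pS = Sd / S if S else 0.0
    valid = pS < 0.75 and pN < 0.75
    dN = jukes_cantor(pN) if pN < 0.75 else math.inf
    dS = jukes_cantor(pS) if pS < 0.75 else math.inf
    if dN == 0.0 and dS == 0.0:
        omega: Optional[float] = None
    elif dS == 0.0:
        omega = math.inf
    else:
        omega = dN / dS
    return DnDsResult(
        N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS, dN=dN, dS=dS, omega=omega,
        codons_compared=compared, skipped_codons=skipped, correction_valid=valid,
    )


# ------------------------------------------------------- Fitch reconstruction


def fitch_ancestral_states(tree, alignment: Mapping[str, str]) -> dict[str, str]:
    """Nucleotide-level Fitch parsimony states for every node of a rooted tree.

    Ties are broken by preferring the parental state, then alphabetically;
    deterministic given the rooted tree.  Gaps and Ns are treated as fully
    ambiguous.  Returns node label -> sequence (tips included verbatim where
    unambiguous).
    """
    tree = treeutil.load_tree(tree)
    tips = treeutil.tip_labels(tree)
    L = len(next(iter(alignment.values())))
    for sp in tips:
        if sp not in alignment:
            raise KeyError(f"tip {sp} missing from alignment")
        if len(alignment[sp]) != L:
            raise ValueError("alignment sequences differ in length")
    sets: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            seq = alignment[nd.taxon.label].upper()
            arr = np.array([_BASE_BITS.get(ch, 15) for ch in seq], dtype=np.int8)
            sets[nd] = arr
        else:
            kids = [sets[k] for k in nd.child_nodes()]
            inter = kids[0].copy()
            union = kids[0].copy()
            for k in kids[1:]:
                inter &= k
                union |= k
            arr = np.where(inter != 0, inter, union)
            sets[nd] = arr
    # top-down assignment
    def pick_lowest(mask: np.ndarray) -> np.ndarray:
        return (mask & (-mask)).astype(np.int8)

    states: dict = {}
    out: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        mask = sets[nd]
        if nd.parent_node is None:
            st = pick_lowest(mask)
        else:
            pst = states[nd.parent_node]
            keep = (mask & pst) != 0
            st = np.where(keep, pst, pick_lowest(mask))
        states[nd] = st
        out[treeutil.branch_id(nd)] = "".join(_BIT_BASE.get(int(b), "N") for b in st)
    return out


# --------------------------------------------------- per-branch change counts


def _edge_codon_changes(parent_seq: str, child_seq: str):
    """Yield (codon index, nd, sd) for codons differing between parent and child."""
    for ci in range(len(parent_seq) // 3):
        c1 = parent_seq[3 * ci : 3 * ci + 3]
        c2 = child_seq[3 * ci : 3 * ci + 3]
        if c1 == c2:
            continue
        if "N" in c1 or "N" in c2 or c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        nd, sd, ok = pathway_counts(c1, c2)
        if ok:
            yield ci, nd, sd


def _alignment_site_fractions(alignment: Mapping[str, str]) -> tuple[np.ndarray, np.ndarray]:
    """Mean NG86 (n, s) site counts per codon column, averaged over sequences."""
    L = len(next(iter(alignment.values()))) // 3
    n = np.zeros(L)
    s = np.zeros(L)
    cnt = np.zeros(L)
    for seq in alignment.values():
        for ci in range(L):
            codon = seq[3 * ci : 3 * ci + 3]
            if "-" in codon or "N" in codon or codon in STOP_CODONS:
                continue
            nc, sc = ng86_site_counts(codon)
            n[ci] += nc
            s[ci] += sc
            cnt[ci] += 1
    with np.errstate(invalid="ignore"):
        n = np.where(cnt > 0, n / np.maximum(cnt, 1), 0.0)
        s = np.where(cnt > 0, s / np.maximum(cnt, 1), 0.0)
    return n, s


@dataclass
class PartitionDnDs:
    omega_foreground: Optional[float]
    omega_background: Optional[float]
    counts_foreground: tuple[float, float]  # (Nd, Sd)
    counts_background: tuple[float, float]
    N: float
    S: float
    method: str = METHOD_TAG


def clade_partition_dnds(
    alignment: Mapping[str, str], tree, foreground: Iterable[str]
) -> PartitionDnDs:
    """Pooled NG86 omega for a foreground clade (stem included) vs the rest.

    ``foreground`` must be exactly the tip set of one clade of the rooted
    tree.  Per-branch synonymous/nonsynonymous changes are counted codon-wise
    on Fitch ancestral states and pooled per partition; omega is
    (Nd/N)/(Sd/S) with alignment-wide NG86 site totals.
    """
    tree = treeutil.load_tree(tree)
    fg = set(foreground)
    node = treeutil.mrca(tree, fg)
    if set(treeutil.leaves_under(node)) != fg:
        raise ValueError("foreground tips are not a clade of the tree")
    fg_edges = {treeutil.branch_id(nd) for nd in node.preorder_iter()}
    states = fitch_ancestral_states(tree, alignment)
    nd_fg = sd_fg = nd_bg = sd_bg = 0.0
    for child in treeutil.branch_nodes(tree):
        parent = child.parent_node
        pseq = states[treeutil.branch_id(parent)]
        cseq = states[treeutil.branch_id(child)]
        in_fg = treeutil.branch_id(child) in fg_edges
        for _, nd, sd in _edge_codon_changes(pseq, cseq):
            if in_fg:
                nd_fg += nd
                sd_fg += sd
            else:
                nd_bg += nd
                sd_bg += sd
    n_sites, s_sites = _alignment_site_fractions(alignment)
    N = float(n_sites.sum())
    S = float(s_sites.sum())

    def _omega(nd, sd):
        if N == 0 or S == 0:
            return None
        pn, ps = nd / N, sd / S
        if pn == 0 and ps == 0:
            return None
        if ps == 0:
            return math.inf
        return pn / ps

    return PartitionDnDs(
        omega_foreground=_omega(nd_fg, sd_fg),
        omega_background=_omega(nd_bg, sd_bg),
        counts_foreground=(nd_fg, sd_fg),
        counts_background=(nd_bg, sd_bg),
        N=N,
        S=S,
    )


# ----------------------------------------------------------- per-site screen


@dataclass
class SiteSelectionSummary:
    """Per-site change counts and selection labels at a stated alpha."""

    n_sites: int
    syn_changes: np.ndarray
    nonsyn_changes: np.ndarray
    p_values: np.ndarray
    labels: list[str]  # positive | negative | neutral, per codon site
    alpha: float
    n_positive: int
    n_negative: int
    n_neutral: int
    method: str = METHOD_TAG


def site_selection_counts(
    alignment: Mapping[str, str], tree, alpha: float = 0.1
) -> SiteSelectionSummary:
    """SLAC-style per-site screen from counted changes over all branches.

    Each codon site's nonsynonymous change count is tested (two-sided exact
    binomial) against the site's neutral expectation n/(n+s); sites with an
    excess are labelled positive, a deficit negative, at level ``alpha``.
    No multiple-testing correction is applied by default, matching the
    convention of reporting per-site p at a stated level.
    """
    tree = treeutil.load_tree(tree)
    states = fitch_ancestral_states(tree, alignment)
    L = len(next(iter(alignment.values()))) // 3
    syn = np.zeros(L)
    nonsyn = np.zeros(L)
    for child in treeutil.branch_nodes(tree):
        pseq = states[treeutil.branch_id(child.parent_node)]
        cseq = states[treeutil.branch_id(child)]
        for ci, nd, sd in _edge_codon_changes(pseq, cseq):
            nonsyn[ci] += nd
            syn[ci] += sd
    n_sites, s_sites = _alignment_site_fractions(alignment)
    pvals = np.ones(L)
    labels = []
    for ci in range(L):
        total = syn[ci] + nonsyn[ci]
        k = int(round(nonsyn[ci]))
        n = int(round(total))
        denom = n_sites[ci] + s_sites[ci]
        if n == 0 or denom == 0:
            labels.append("neutral")
            continue
        p0 = n_sites[ci] / denom
        res = binomtest(min(k, n), n, p0, alternative="two-sided")
        pvals[ci] = res.pvalue
        if res.pvalue <= alpha:
            labels.append("positive" if k / n > p0 else "negative")
        else:
            labels.append("neutral")
    return SiteSelectionSummary(
        n_sites=L,
        syn_changes=syn,
        nonsyn_changes=nonsyn,
        p_values=pvals,
        labels=labels,
        alpha=alpha,
        n_positive=labels.count("positive"),
        n_negative=labels.count("negative"),
        n_neutral=labels.count("neutral"),
    )


# ------------------------------------------------------------------ FASTA I/O


def read_codon_alignment(path) -> dict[str, str]:
    """In-frame codon alignment from FASTA (gap character '-')."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(s) for s in out.values()}
    if len(lengths) != 1 or next(iter(lengths)) % 3:
        raise ValueError("codon alignment must be equal-length, multiple of 3")
    return out
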