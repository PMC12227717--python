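"""Shared-lesion signatures and Dollo mapping of gene-loss events.

A lesion observed in several species is evidence of a single ancestral
mutation when the lesions are identical (same kind, exon, position bucket
and observed sequence).  Under Dollo parsimony the derived state (carrying
the lesion, or having lost the gene) can be gained on a branch but never
reverted, so the minimum number of independent events explaining a set of
carrier tips is the number of maximal subtrees whose tips are all carriers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

from . import treeutil
from .integrity import Lesion


@dataclass(frozen=True)
class LesionSignature:
    """Canonical identity of a lesion, comparable across species."""

    gene_id: str
    exon_number: int
    kind: str
    bucket: object  # boundary name for splice lesions, offset bucket otherwise
    observed: str

    def __str__(self):
        return f"{self.gene_id}:exon{self.exon_number}:{self.kind}:{self.bucket}:{self.observed or '-'}"


@dataclass
class EventPlacement:
    """A signature mapped onto the tree under Dollo parsimony."""

    signature: object
    carrier_tips: frozenset
    placement_node: str  # label of the carriers' MRCA
    n_events: int  # minimum number of independent origins
    monophyletic: bool
    event_branches: tuple[str, ...] = ()  # stems of the maximal carrier clades


def lesion_signature(
    lesion: Lesion,
    gene_id: str,
    offset_tolerance: Optional[int] = None,
) -> LesionSignature:
    """Deterministic canonical form of a lesion for cross-species matching.

    Splice lesions are identified by their boundary with tolerance 0 — shared
    ancestry requires an *identical* mutated splice site; indels and
    STOPs by an offset bucket of width ``offset_tolerance`` (default 3 nt for
    indels, 0 for STOP codons), absorbing small alignment jitter.
    """
    if lesion.kind in ("SPLICE_DONOR_MUT", "SPLICE_ACCEPTOR_MUT"):
        bucket = lesion.boundary or "boundary"
        observed = lesion.observed
    elif lesion.kind == "EXON_MISSING":
        bucket = "absent"
        observed = ""
    else:
        tol = offset_tolerance
        if tol is None:
            tol = 3 if lesion.kind in ("FRAMESHIFT_INDEL", "INFRAME_INDEL") else 0
        off = lesion.offset or 0
        bucket = off // tol if tol > 0 else off
        observed = lesion.observed
    return LesionSignature(
        gene_id=gene_id,
        exon_number=lesion.exon_number,
        kind=lesion.kind,
        bucket=bucket,
        observed=observed,
    )


def _maximal_carrier_clades(tree: dendropy.Tree, carriers: set[str]):
    """Roots of the maximal subtrees whose tips are all carriers."""
    is_all = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            is_all[nd] = nd.taxon.label in carriers
        else:
            kids = nd.child_nodes()
            is_all[nd] = bool(kids) and all(is_all[k] for k in kids)
    roots = []
    for nd in tree.preorder_node_iter():
        if is_all[nd] and (nd.parent_node is None or not is_all[nd.parent_node]):
            roots.append(nd)
    return roots


def place_signature(
    tree: dendropy.Tree, signature, carriers: Iterable[str]
) -> EventPlacement:
    """Dollo placement of one signature: MRCA of carriers + minimum event count."""
    carriers = set(carriers)
    if not carriers:
        raise ValueError("no carriers for signature")
    node = treeutil.mrca(tree, carriers)
    clades = _maximal_carrier_clades(tree, carriers)
    n_events = len(clades)
    mono = n_events == 1 and set(treeutil.leaves_under(node)) == carriers
    return EventPlacement(
        signature=signature,
        carrier_tips=frozenset(carriers),
        placement_node=treeutil.branch_id(node),
        n_events=n_events,
        monophyletic=mono,
        event_branches=tuple(treeutil.branch_id(c) for c in clades),
    )


def map_events_on_tree(
    signatures_per_species: Mapping[str, Iterable],
    tree,
) -> list[EventPlacement]:
    """Place every distinct lesion signature on the species tree.

    ``signatures_per_species`` maps species id to its signatures (any
    hashable; typically :class:`LesionSignature`).  Species carrying no
    signature still constrain placements as non-carriers.  Raises if a
    carrier species is not a tip of the tree.
    """
    tree = treeutil.load_tree(tree)
    carriers_by_sig: dict[object, set[str]] = {}
    for sp, sigs in signatures_per_species.items():
        for sig in sigs:
            carriers_by_sig.setdefault(sig, set()).add(sp)
    missing = {
        sp
        for sigs in (signatures_per_species,)
        for sp in sigs
        if sp not in set(treeutil.tip_labels(tree))
    }
    if missing:
        raise KeyError(f"species absent from tree: {sorted(missing)}")
    placements = [
        place_signature(tree, sig, carriers)
        for sig, carriers in sorted(carriers_by_sig.items(), key=lambda kv: str(kv[0]))
    ]
    return placements


def min_loss_events(
    verdicts: Mapping[str, str],
    tree,
) -> tuple[int, list[str]]:
    """Minimum number of independent gene-loss events explaining the verdicts.

    ``verdicts`` maps species to a status string; PSEUDOGENE tips are loss
    carriers, INCOMPLETE tips are uninformative and are pruned before
    counting (Dollo: losses are gained on branches, never reverted).
    Returns (count, stem branch labels of the inferred loss clades).
    """
    tree = treeutil.load_tree(tree)
    tips = set(treeutil.tip_labels(tree))
    if not tips:
        raise ValueError("empty tree")
    unknown = set(verdicts) - tips
    if unknown:
        raise KeyError(f"species absent from tree: {sorted(unknown)}")
    excluded = {sp for sp, st in verdicts.items() if st == "INCOMPLETE"}
    carriers = {sp for sp, st in verdicts.items() if st == "PSEUDOGENE"}
    if excluded:
        keep = [sp for sp in tips if sp not in excluded]
        if not keep:
            raise ValueError("all tips INCOMPLETE; nothing to place")
        taxa = [tree.taxon_namespace.get_taxon(sp) for sp in keep]
        tree = tree.extract_tree_with_taxa(taxa=taxa)
        tree.is_rooted = True
        treeutil.label_nodes(tree)
    if not carriers:
        return 0, []
    clades = _maximal_carrier_clades(tree, carriers)
    return len(clades), [treeutil.branch_id(c) for c in clades]


def placements_to_tsv(placements: Sequence[EventPlacement]) -> str:
    rows = ["signature\tcarriers\tplacement_node\tn_events\tmonophyletic\tevent_branches"]
    for p in placements:
        rows.append(
            "\t".join(
                [
                    str(p.signature),
                    ",".join(sorted(p.carrier_tips)),
                    p.placement_node,
                    str(p.n_events),
                    "yes" if p.monophyletic else "no",
                    ",".join(p.event_branches) or ".",
                ]
            )
        )
    return "\n".join(rows) + "\n"


def annotated_newick(tree, placements: Sequence[EventPlacement]) -> str:
    """Newick with event marks (#signature) appended to branch labels."""
    tree = treeutil.load_tree(tree)
    marks: dict[str, list[str]] = {}
    for p in placements:
        for b in p.event_branches:
            marks.setdefault(b, []).append(str(p.signature))
    for nd in tree.preorder_node_iter():
        bid = treeutil.branch_id(nd)
        if bid in marks:
            tag = "|".join(sorted(marks[bid]))
            if nd.is_leaf():
                nd.taxon.label = f"{nd.taxon.label}#{tag}"
            else:
                nd.label = f"{bid}#{tag}"
    return tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
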