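"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation: codon pathway
counts are enumerated by recursive depth-first search over substitution
orders, and minimum Dollo event counts by exhaustive search over gain-edge
subsets.
"""

import itertools

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"

SENSE = sorted(_AA)


def oracle_site_counts(codon):
    """(n, s) fractional site counts over non-STOP single-nucleotide mutants."""
    s_total = 0.0
    for pos in range(3):
        mutants = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in _BASES
            if b != codon[pos]
        ]
        viable = [m for m in mutants if m not in _STOPS]
        if viable:
            s_total += sum(_AA[m] == _AA[codon] for m in viable) / len(viable)
    return 3.0 - s_total, s_total


def oracle_pathway_counts(c1, c2):
    """Pathway-averaged (nd, sd, ok) by recursive enumeration of orders."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results = []

    def rec(cur, n, s, remaining):
        if not remaining:
            results.append((n, s))
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                continue
            syn = _AA[nxt] == _AA[cur]
            rec(nxt, n + (0 if syn else 1), s + (1 if syn else 0),
                [p for p in remaining if p != pos])

    rec(c1, 0, 0, diffs)
    if not results:
        return 0.0, 0.0, False
    n = sum(r[0] for r in results) / len(results)
    s = sum(r[1] for r in results) / len(results)
    return n, s, True


def oracle_min_dollo_events(tree, carriers):
    """Exhaustive minimum over gain-edge subsets satisfying Dollo coverage.

    A gain on an edge makes every tip below it a carrier (no reversal), so a
    valid subset's descendant-tip sets must union exactly to the carrier set.
    """
    from pseudoscan import treeutil

    carriers = frozenset(carriers)
    # candidate gain edges: every branch of the tree plus the stem above the root
    nodes = treeutil.branch_nodes(tree) + [tree.seed_node]
    usable = [
        frozenset(treeutil.leaves_under(nd))
        for nd in nodes
        if set(treeutil.leaves_under(nd)) <= carriers
    ]
    if not carriers:
        return 0
    for k in range(1, len(usable) + 1):
        for combo in itertools.combinations(usable, k):
            u = frozenset().union(*combo)
            if u == carriers:
                return k
    raise AssertionError("no Dollo cover found (carriers not coverable)")
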