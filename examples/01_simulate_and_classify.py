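"""Simulate a small clade with planted lesions and classify every locus.

Builds a 12-exon ENaC-like reference gene, plants a splice-donor mutation on
an internal branch and a frameshift on one tip, evolves the locus along a
four-species tree with 0.5% background divergence, and runs the classifier.
"""

import numpy as np

import pseudoscan as ps
from pseudoscan import simulate as sim

model = ps.build_reference_model(n_exons=12, seed=2)
tree = "((A:1,B:1):0.5,(C:1,D:1):0.5);"
rng = np.random.default_rng(5)

planted = [
    sim.make_donor_mut("n1", 5, "AT"),  # stem of (A,B): both tips inherit it
    sim.make_frameshift("D", 8, 40, 2, insert=False, rng=rng),
]
loci, truth = ps.evolve_along_tree(model, tree, sub_rate=0.005, indel_rate=0.0,
                                   planted=planted, seed=7)

verdicts = ps.evaluate_dataset(model, loci)
print(ps.render_status_matrix(verdicts, tree=tree))
for sp in sorted(verdicts):
    v = verdicts[sp]
    primary = [(l.kind, l.exon_number) for l in v.primary_lesions]
    print(f"{sp}: {v.status:11s} primary lesions: {primary}")

r = ps.score_recovery(truth, verdicts)
print(f"\nrecovery vs simulator truth: sensitivity={r['sensitivity']:.2f} "
      f"precision={r['precision']:.2f} verdict accuracy={r['verdict_accuracy']:.2f}")
print("I = intact ORF, P = pseudogene; A and B share the planted AT donor after "
      "exon 5, D carries the 2-nt frameshift (its downstream STOPs are flagged "
      "secondary, not independent lesions).")
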