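"""Quantify cross-condition cluster switching against planted truth.

The comparison condition's stage profiles are projected onto the
centroids trained on the reference condition; a gene whose nearest
centroid changes is a "switch" (the alluvial-plot data). With 10% of
genes planted as switched, the transition table should show ~180
off-diagonal genes and the detected set should match the planted one.
"""

from stagetraj import RunConfig, SimDesign, analyse, simulate_counts

design = SimDesign(seed=2)  # switch_fraction=0.1 by default
counts, meta, truth = simulate_counts(design)
res = analyse(counts, meta, RunConfig(seed=2), "Natural", "IVF")

tt = res.transitions
print("reference-cluster x comparison-cluster gene counts:")
print(tt.counts.to_string())
print(f"\nswitched genes: {tt.n_switched} / {tt.n_genes} "
      f"({tt.n_switched / tt.n_genes:.1%}; planted fraction 10%)")

flagged = set(tt.switched_genes)
planted = set(truth.genes.index[truth.genes.is_switched])
universe = set(res.model.assignments.index)
tp = len(flagged & planted)
print(f"sensitivity = {tp / len(planted & universe):.3f}, "
      f"false-positive rate = {len(flagged - planted) / len(universe - planted):.4f}")
# Off-diagonal counts concentrate exactly where archetypes were swapped;
# near-1 sensitivity at near-0 FPR means projection onto reference
# centroids cleanly separates real trajectory changes from noise.
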