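"""Disjoint Venn-style regions of differentially-expressed gene lists.

Takes three named gene lists (e.g. DEGs at three developmental stages)
and enumerates every exclusive intersection region — the numbers behind
a 3-way Venn diagram, including the genes altered at all timepoints.
"""

from stagetraj import intersect_gene_sets

deg_sets = {
    "E18.5": ["Hfm1", "Spata22", "Star", "Esr1", "Gdf9", "Foxo3"],
    "12wk": ["Esr1", "Fmr1", "Star", "Brca1", "Foxo3"],
    "39wk": ["Esr1", "Foxo3", "Brca2", "Gdf9"],
}
overlap = intersect_gene_sets(deg_sets)

print(overlap.regions[["region", "n", "genes"]].to_string(index=False))
print(f"\nunion size: {overlap.union_size}")
print("consistently altered at all timepoints:",
      ", ".join(overlap.region(("E18.5", "12wk", "39wk"))))
# Region counts are disjoint and sum to the union; the all-way region
# lists the genes shared by every timepoint's DEG list.
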