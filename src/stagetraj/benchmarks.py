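"""Planted-truth benchmarks: run the pipeline on simulated data and score it.

These helpers wire ``simulate_counts`` to ``analyse`` and compare the
result with the generator's ground truth: did the elbow rule find the
planted number of archetypes, how well do reference-condition clusters
match the planted partition (adjusted Rand index), and how accurately are
condition-switched genes flagged (sensitivity / false-positive rate).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .io import RunConfig
from .pipeline import analyse
from .simulate import SimDesign, simulate_counts

__all__ = ["adjusted_rand_index", "evaluate_recovery", "k_recovery"]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    a = pd.Categorical(np.asarray(labels_a)).codes
    b = pd.Categorical(np.asarray(labels_b)).codes
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    n = len(a)
    contingency = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def evaluate_recovery(
    design: SimDesign,
    cfg: RunConfig | None = None,
    k_override: int | None = None,
) -> dict:
    """Simulate one dataset, run the full analysis, score against truth.

    Returns selected k, the elbow rule that fired, ARI of the reference
    clustering against the planted archetypes, and switched-gene
    sensitivity / false-positive rate, all on the clustered gene universe.
    """
    if cfg is None:
        cfg = RunConfig(seed=design.seed)
    counts, meta, truth = simulate_counts(design)
    res = analyse(
        counts,
        meta,
        cfg,
        design.reference_condition,
        design.comparison_condition,
        k_override=k_override,
    )
    genes = list(res.model.assignments.index)
    planted = truth.genes.loc[genes]
    ari = adjusted_rand_index(planted["archetype"], res.model.assignments.loc[genes])

    flagged = set(res.transitions.switched_genes)
    true_switched = set(planted.index[planted["is_switched"]])
    stable = set(genes) - true_switched
    sensitivity = (
        len(flagged & true_switched) / len(true_switched) if true_switched else np.nan
    )
    fpr = len(flagged & stable) / len(stable) if stable else np.nan
    return {
        "selected_k": res.selected_k,
        "rule": res.rationale["rule"],
        "ari": ari,
        "switch_sensitivity": sensitivity,
        "switch_fpr": fpr,
        "n_genes_clustered": len(genes),
        "result": res,
    }


def k_recovery(design: SimDesign, seeds, cfg_seed_offset: int = 0) -> list[int]:
    """Selected k per seed for replicates of one design (seed swapped in)."""
    out = []
    for seed in seeds:
        d = replace(design, seed=int(seed))
        cfg = RunConfig(seed=int(seed) + cfg_seed_offset)
        counts, meta, _ = simulate_counts(d)
        res = analyse(
            counts, meta, cfg, d.reference_condition, d.comparison_condition
        )
        out.append(res.selected_k)
    return out
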