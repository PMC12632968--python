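"""Cross-condition cluster membership: projection, transitions, overlaps.

The comparison condition is not re-clustered: its stage profiles are
projected onto the centroids trained on the reference condition, so a
"switch" is simply a gene whose nearest centroid differs between the two
conditions. The k x k transition table is the plot-ready input for an
alluvial diagram. A small utility enumerates the disjoint regions of 2-3
named gene sets (Venn-style intersections).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterModel, _sq_distances
from .preprocess import StageProfileMatrix

__all__ = [
    "TransitionTable",
    "GeneSetOverlap",
    "assign_to_centroids",
    "transition_table",
    "intersect_gene_sets",
]


def assign_to_centroids(
    profiles: StageProfileMatrix, model: ClusterModel
) -> pd.DataFrame:
    """Nearest-centroid (squared-Euclidean) assignment of each profile.

    Ties break toward the lowest cluster label. Returns a DataFrame
    indexed by gene id with columns ``cluster`` and ``sq_distance``.
    """
    if profiles.stages != model.stages:
        raise ValueError(
            f"stage mismatch: profiles have {profiles.stages}, "
            f"model centroids have {model.stages}"
        )
    x = profiles.values
    centers = model.centroids.to_numpy(dtype=float)
    d2 = _sq_distances(x, centers)
    idx = d2.argmin(axis=1)
    labels = model.centroids.index.to_numpy()[idx]
    out = pd.DataFrame(
        {"cluster": labels, "sq_distance": d2[np.arange(len(x)), idx]},
        index=profiles.profiles.index,
    )
    out.index.name = "gene_id"
    return out


@dataclass
class TransitionTable:
    """Gene flow between reference and comparison cluster memberships.

    ``counts[i, j]`` is the number of genes in reference cluster i and
    comparison cluster j; off-diagonal genes are the switched set.
    """

    counts: pd.DataFrame
    switched: pd.DataFrame
    excluded_from_ref: list[str] = field(default_factory=list)
    excluded_from_cmp: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_switched(self) -> int:
        return len(self.switched)

    @property
    def switched_genes(self) -> list[str]:
        return list(self.switched.index)

    def to_frame(self) -> pd.DataFrame:
        return self.counts


def transition_table(
    ref_assign: pd.Series | pd.DataFrame,
    cmp_assign: pd.Series | pd.DataFrame,
    clusters: list[int] | None = None,
) -> TransitionTable:
    """Tally genes from reference cluster i to comparison cluster j.

    Genes present in only one assignment are excluded and reported; the
    grand total of the table equals the size of the shared gene universe.
    """
    if isinstance(ref_assign, pd.DataFrame):
        ref_assign = ref_assign["cluster"]
    if isinstance(cmp_assign, pd.DataFrame):
        cmp_assign = cmp_assign["cluster"]
    ref_genes, cmp_genes = set(ref_assign.index), set(cmp_assign.index)
    shared = ref_genes & cmp_genes
    if not shared:
        raise ValueError("assignments have disjoint gene universes")
    only_ref = sorted(ref_genes - shared)
    only_cmp = sorted(cmp_genes - shared)
    genes = [g for g in ref_assign.index if g in shared]

    ref = ref_assign.loc[genes].astype(int)
    cmp_ = cmp_assign.loc[genes].astype(int)
    if clusters is None:
        clusters = sorted(set(ref) | set(cmp_))
    idx = pd.Index(clusters, name="ref_cluster")
    cols = pd.Index(clusters, name="cmp_cluster")
    counts = (
        pd.crosstab(ref, cmp_)
        .reindex(index=idx, columns=cols, fill_value=0)
        .astype(int)
    )
    moved = ref != cmp_
    switched = pd.DataFrame(
        {"ref_cluster": ref[moved], "cmp_cluster": cmp_[moved]},
        index=pd.Index(ref.index[moved], name="gene_id"),
    )
    return TransitionTable(counts, switched, only_ref, only_cmp)


@dataclass
class GeneSetOverlap:
    """Disjoint intersection regions of 2-3 named gene sets."""

    set_names: list[str]
    regions: pd.DataFrame  # region, n, genes (comma-joined)

    @property
    def union_size(self) -> int:
        return int(self.regions["n"].sum())

    def region(self, names: tuple[str, ...] | list[str] | str) -> list[str]:
        if isinstance(names, str):
            names = (names,)
        label = "&".join(n for n in self.set_names if n in set(names))
        row = self.regions.loc[self.regions["region"] == label]
        if row.empty:
            raise KeyError(f"no region {label!r}")
        genes = row["genes"].iloc[0]
        return genes.split(",") if genes else []

    def to_frame(self) -> pd.DataFrame:
        return self.regions.set_index("region")


def intersect_gene_sets(sets: dict[str, list[str] | set[str]]) -> GeneSetOverlap:
    """Enumerate every exclusive membership region of 2-3 named sets.

    Region "A&B" contains genes in A and B but in no other supplied set;
    regions are disjoint and their counts sum to the union size. Gene
    matching is case-sensitive; duplicates within a set are ignored.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("intersect_gene_sets expects 2 or 3 named sets")
    for name in sets:
        if not str(name):
            raise ValueError("set names must be non-empty strings")
    names = list(sets)
    dedup = {n: set(map(str, s)) for n, s in sets.items()}

    membership: dict[str, tuple[str, ...]] = {}
    for g in set().union(*dedup.values()):
        membership[g] = tuple(n for n in names if g in dedup[n])

    rows = []
    # all non-empty subsets, ordered by size desc then set order
    subsets: list[tuple[str, ...]] = []
    n = len(names)
    for mask in range(1, 2**n):
        subsets.append(tuple(names[i] for i in range(n) if mask >> i & 1))
    subsets.sort(key=lambda s: (-len(s), tuple(names.index(x) for x in s)))
    for sub in subsets:
        genes = sorted(g for g, m in membership.items() if m == sub)
        rows.append(
            {"region": "&".join(sub), "n": len(genes), "genes": ",".join(genes)}
        )
    return GeneSetOverlap(names, pd.DataFrame(rows))
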