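"""K-means over stage-mean profiles with a WCSS sweep and elbow selection.

The number of temporal clusters is chosen by sweeping k over a range
(default 2..15), fitting k-means with many random restarts at each k,
recording the within-cluster sum of squares (WCSS), and taking the
smallest k beyond which one more cluster improves WCSS by less than a
relative gain threshold (default 5%).

Lloyd's algorithm is implemented directly so its determinism contract is
explicit: initial centres are k distinct data rows drawn uniformly from a
seeded generator per restart, nearest-centroid ties break toward the
lowest centroid index, an emptied cluster is reseeded with the point
farthest from its current centroid, and the restart with the lowest WCSS
wins (first such restart on ties). Identical seeds give bit-identical
models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import RunConfig
from .preprocess import StageProfileMatrix

__all__ = [
    "WcssCurve",
    "ClusterModel",
    "kmeans_fit",
    "wcss_sweep",
    "select_k",
    "label_clusters",
]

# wcss(k+1) may exceed wcss(k) by at most this relative slack before the
# sweep is declared unreliable (too few restarts).
_MONOTONE_TOL = 1e-9


@dataclass
class WcssCurve:
    """WCSS per k plus relative gains between consecutive k."""

    k_values: np.ndarray
    wcss: np.ndarray

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.wcss = np.asarray(self.wcss, dtype=float)
        if self.k_values.ndim != 1 or self.k_values.shape != self.wcss.shape:
            raise ValueError("k_values and wcss must be 1-D and equal length")
        if len(self.k_values) and (np.diff(self.k_values) != 1).any():
            raise ValueError("k_values must be consecutive integers")
        if (self.wcss < 0).any():
            raise ValueError("wcss values must be non-negative")

    @property
    def gains(self) -> dict[int, float]:
        """gains[k] = relative WCSS reduction achieved moving to k from k-1."""
        out: dict[int, float] = {}
        for i in range(1, len(self.k_values)):
            prev = self.wcss[i - 1]
            out[int(self.k_values[i])] = (
                (prev - self.wcss[i]) / prev if prev > 0 else 0.0
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        gains = self.gains
        return pd.DataFrame(
            {
                "k": self.k_values,
                "wcss": self.wcss,
                "gain": [gains.get(int(k), np.nan) for k in self.k_values],
            }
        ).set_index("k")


@dataclass
class ClusterModel:
    """A fitted k-means model over stage profiles.

    ``centroids`` is a (k x n_stages) DataFrame indexed by cluster label
    1..k; ``assignments`` maps gene id -> cluster label.
    """

    k: int
    centroids: pd.DataFrame
    assignments: pd.Series
    wcss: float
    seed: int
    n_restarts: int

    @property
    def stages(self) -> list[str]:
        return list(self.centroids.columns)

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().reindex(
            self.centroids.index, fill_value=0
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.assignments.rename("cluster").to_frame()
        df.index.name = "gene_id"
        return df


def _sq_distances(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, shape (n_points, n_centers)."""
    diff = x[:, None, :] - centers[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def _lloyd(
    x: np.ndarray, centers: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run from given centres; returns (labels0, centers, wcss)."""
    k = centers.shape[0]
    labels = None
    for _ in range(max_iter):
        d2 = _sq_distances(x, centers)
        new_labels = d2.argmin(axis=1)  # argmin ties -> lowest index
        counts = np.bincount(new_labels, minlength=k)
        # Reseed each empty cluster with the point farthest from its
        # currently assigned centroid, one at a time.
        while (counts == 0).any():
            empty = int(np.flatnonzero(counts == 0)[0])
            assigned_d2 = d2[np.arange(len(x)), new_labels]
            # only points from clusters with >1 member may move
            movable = counts[new_labels] > 1
            assigned_d2 = np.where(movable, assigned_d2, -np.inf)
            far = int(assigned_d2.argmax())
            counts[new_labels[far]] -= 1
            new_labels[far] = empty
            counts[empty] = 1
            centers[empty] = x[far]
            d2[:, empty] = ((x - x[far]) ** 2).sum(axis=1)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        sums = np.zeros((k, x.shape[1]))
        np.add.at(sums, labels, x)
        centers = sums / counts[:, None]
    d2 = _sq_distances(x, centers)
    labels = d2.argmin(axis=1)
    wcss = float(d2[np.arange(len(x)), labels].sum())
    return labels, centers, wcss


def kmeans_fit(
    profiles: StageProfileMatrix,
    k: int,
    n_restarts: int = 50,
    max_iter: int = 1000,
    seed: int = 0,
) -> ClusterModel:
    """Best-of-``n_restarts`` Lloyd's k-means on the profile rows."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    x = profiles.values
    distinct = np.unique(x, axis=0)
    if k > distinct.shape[0]:
        raise ValueError(
            f"k={k} exceeds the number of distinct profile rows "
            f"({distinct.shape[0]})"
        )
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_restarts):
        init_idx = rng.choice(distinct.shape[0], size=k, replace=False)
        labels, centers, wcss = _lloyd(x, distinct[init_idx].copy(), max_iter)
        if best is None or wcss < best[2]:
            best = (labels, centers, wcss)
    labels, centers, wcss = best

    # after convergence each centroid is exactly the mean of its members;
    # recompute to make the invariant hold bit-for-bit
    k_labels = np.arange(k)
    means = np.vstack([x[labels == c].mean(axis=0) for c in k_labels])
    centroids = pd.DataFrame(
        means, index=pd.Index(k_labels + 1, name="cluster"), columns=profiles.stages
    )
    assignments = pd.Series(
        labels + 1, index=profiles.profiles.index, name="cluster"
    )
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments=assignments,
        wcss=wcss,
        seed=seed,
        n_restarts=n_restarts,
    )


def _subseed(seed: int, k: int) -> int:
    """Stable per-k sub-seed so adding k values never perturbs others."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0])


def wcss_sweep(
    profiles: StageProfileMatrix, cfg: RunConfig
) -> tuple[WcssCurve, dict[int, ClusterModel]]:
    """Fit k-means at every k in cfg.k_min..cfg.k_max; return curve + models."""
    n_distinct = np.unique(profiles.values, axis=0).shape[0]
    if cfg.k_max > n_distinct:
        raise ValueError(
            f"k_max={cfg.k_max} exceeds the number of distinct profile rows "
            f"({n_distinct})"
        )
    ks = list(range(cfg.k_min, cfg.k_max + 1))
    models: dict[int, ClusterModel] = {}
    for k in ks:
        models[k] = kmeans_fit(
            profiles,
            k,
            n_restarts=cfg.n_restarts,
            max_iter=cfg.max_iter,
            seed=_subseed(cfg.seed, k),
        )
    curve = WcssCurve(np.array(ks), np.array([models[k].wcss for k in ks]))
    return curve, models


def select_k(curve: WcssCurve, gain_threshold: float = 0.05) -> tuple[int, dict]:
    """Elbow rule: smallest k whose NEXT step gains less than the threshold.

    Returns ``(k, rationale)`` where the rationale records the rule used
    ("elbow" or "no-elbow"), the threshold, and the full gain table so the
    choice can be audited. A WCSS increase beyond numerical tolerance is a
    hard error: it signals too few restarts to trust the curve.
    """
    if len(curve.k_values) < 2:
        raise ValueError("WCSS curve needs at least 2 entries to select k")
    if curve.wcss[0] <= 0:
        raise ValueError("wcss at k_min must be positive to compute gains")
    rises = np.diff(curve.wcss) > _MONOTONE_TOL * np.maximum(curve.wcss[:-1], 1.0)
    if rises.any():
        bad_k = int(curve.k_values[1:][rises][0])
        raise ValueError(
            f"WCSS increases at k={bad_k}; the curve is not monotone — "
            "increase n_restarts"
        )
    gains = curve.gains
    rationale = {"gain_threshold": gain_threshold, "gains": gains}
    for k in curve.k_values[:-1]:
        if gains[int(k) + 1] < gain_threshold:
            rationale["rule"] = "elbow"
            rationale["selected_k"] = int(k)
            return int(k), rationale
    k_max = int(curve.k_values[-1])
    rationale["rule"] = "no-elbow"
    rationale["selected_k"] = k_max
    return k_max, rationale


def label_clusters(model: ClusterModel) -> ClusterModel:
    """Relabel clusters deterministically.

    Clusters are sorted by centroid value at the first stage (ascending),
    ties by size (descending); the permutation leaves geometry and WCSS
    untouched.
    """
    sizes = model.cluster_sizes
    order = sorted(
        model.centroids.index,
        key=lambda c: (model.centroids.loc[c].iloc[0], -sizes[c]),
    )
    mapping = {old: new + 1 for new, old in enumerate(order)}
    centroids = model.centroids.rename(index=mapping).sort_index()
    assignments = model.assignments.map(mapping)
    return replace(model, centroids=centroids, assignments=assignments)
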