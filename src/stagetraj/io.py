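"""Tabular input/output and validated domain containers.

The pipeline consumes two plain-text inputs: a gene-by-sample raw count
matrix (TSV, first column gene id, header row of sample ids) and a sample
metadata table (sample_id, stage, condition, replicate). Developmental
stages cannot be ordered lexically ("E18.5" vs "12wk"), so the stage order
is always an explicit argument, never inferred.

Gene identifiers are opaque strings; no symbol/ID mapping happens here.
Gzip-compressed inputs are accepted transparently (by file extension).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleTable",
    "RunConfig",
    "read_counts",
    "read_sample_table",
    "write_table",
    "check_samples_match",
]


def _find_duplicates(values) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for v in values:
        if v in seen and v not in dups:
            dups.append(v)
        seen.add(v)
    return dups


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample count matrix.

    ``counts`` is a DataFrame indexed by gene id with sample ids as
    columns. Row/column order is meaningful and preserved.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] < 1:
            raise ValueError("count matrix must contain at least 1 gene")
        if df.shape[1] < 2:
            raise ValueError("count matrix must contain at least 2 samples")
        dup_g = _find_duplicates(df.index)
        if dup_g:
            raise ValueError(f"duplicate gene id(s): {', '.join(map(str, dup_g))}")
        dup_s = _find_duplicates(df.columns)
        if dup_s:
            raise ValueError(f"duplicate sample id(s): {', '.join(map(str, dup_s))}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("count matrix contains non-numeric values")
        bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid count {values[g, s]!r} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}: counts must be non-negative integers"
            )
        if not np.issubdtype(values.dtype, np.integer):
            self.counts = df.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SampleTable:
    """Per-sample metadata: ordered stage, condition, replicate label.

    ``table`` is indexed by sample_id; the ``stage`` column is an ordered
    pandas Categorical following the stage order supplied at read time.
    """

    table: pd.DataFrame

    REQUIRED = ("stage", "condition", "replicate")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing column(s): {', '.join(missing)}")
        dup = _find_duplicates(df.index)
        if dup:
            raise ValueError(f"duplicate sample id(s): {', '.join(map(str, dup))}")
        stage = df["stage"]
        if not (isinstance(stage.dtype, pd.CategoricalDtype) and stage.cat.ordered):
            raise ValueError(
                "stage must be an ordered categorical; use read_sample_table or "
                "SampleTable.from_frame with an explicit stage_order"
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, stage_order: list[str]) -> "SampleTable":
        dup_order = _find_duplicates(stage_order)
        if dup_order:
            raise ValueError(f"duplicate stage label(s) in stage_order: {dup_order}")
        df = df.copy()
        unknown = sorted(set(df["stage"].astype(str)) - set(stage_order))
        if unknown:
            raise ValueError(
                f"stage label(s) {unknown} not in declared stage_order {stage_order}"
            )
        df["stage"] = pd.Categorical(
            df["stage"].astype(str), categories=stage_order, ordered=True
        )
        return cls(df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def stages(self) -> list[str]:
        """Declared stage order (all categories, whether or not populated)."""
        return list(self.table["stage"].cat.categories)

    @property
    def stages_present(self) -> list[str]:
        present = set(self.table["stage"])
        return [s for s in self.stages if s in present]

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.table["condition"]))

    def samples_of(self, condition: str | None = None, stage: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if condition is not None:
            mask &= self.table["condition"] == condition
        if stage is not None:
            mask &= self.table["stage"] == stage
        return list(self.table.index[mask])


@dataclass
class RunConfig:
    """Tunable parameters of the trajectory-clustering pipeline.

    Defaults reproduce the published procedure: genes kept when CPM >= 1
    in at least 20% of samples (minimum 2) and detected in every stage;
    k-means swept over k = 2..15 with 50 restarts and up to 1000 Lloyd
    iterations; elbow rule accepts the first k whose next step gains < 5%.
    """

    cpm_threshold: float = 1.0
    prevalence_fraction: float = 0.20
    min_prevalent_samples: int = 2
    k_min: int = 2
    k_max: int = 15
    n_restarts: int = 50
    max_iter: int = 1000
    gain_threshold: float = 0.05
    seed: int = 0
    # Z-scores pool both conditions onto one scale by default so that the
    # two conditions' profiles are comparable against shared centroids.
    zscore_within_condition: bool = False
    # Standardise log2(CPM+1) rather than raw CPM: on the raw scale a
    # gene's peak stage dominates its mean and variance, distorting
    # trajectory shapes. Disable for pipelines that Z-score CPM directly.
    log_cpm: bool = True

    def __post_init__(self) -> None:
        if self.cpm_threshold <= 0:
            raise ValueError("cpm_threshold must be strictly positive")
        if not 0 < self.prevalence_fraction <= 1:
            raise ValueError("prevalence_fraction must be in (0, 1]")
        if self.min_prevalent_samples < 0:
            raise ValueError("min_prevalent_samples must be >= 0")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.gain_threshold < 1:
            raise ValueError("gain_threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column gene id, header sample ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty count file: {path}") from exc
    if df.shape[0] == 0:
        raise ValueError(f"count file contains no gene rows: {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def read_sample_table(path: str | Path, stage_order: list[str]) -> SampleTable:
    """Read sample metadata; stages are coded per the explicit stage_order."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty sample table: {path}") from exc
    if "sample_id" not in df.columns:
        raise ValueError("sample table missing column(s): sample_id")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleTable.from_frame(df, stage_order)


def check_samples_match(counts: CountMatrix, meta: SampleTable) -> None:
    """Require identical sample universes in counts and metadata."""
    a, b = set(counts.sample_ids), set(meta.sample_ids)
    if a != b:
        only_counts = sorted(a - b)
        only_meta = sorted(b - a)
        raise ValueError(
            "sample ids differ between counts and metadata; "
            f"only in counts: {only_counts}; only in metadata: {only_meta}"
        )


def _as_frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    if isinstance(obj, pd.Series):
        return obj.to_frame()
    if isinstance(obj, CountMatrix):
        return obj.counts
    if isinstance(obj, SampleTable):
        return obj.table
    to_frame = getattr(obj, "to_frame", None)
    if callable(to_frame):
        return to_frame()
    raise TypeError(f"cannot serialise object of type {type(obj).__name__}")


def write_table(obj, path: str | Path, index_label: str | None = None) -> None:
    """Write a pipeline table as TSV (UTF-8, '.' decimal, stable order)."""
    df = _as_frame(obj)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", encoding="utf-8", index_label=index_label)
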