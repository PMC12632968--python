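"""Expression filtering, CPM transform, Z-scoring and stage-mean profiles.

The clustering input is built in four steps:

1. counts -> CPM, using each sample's total counts over ALL genes
   (pre-filter library sizes);
2. prevalence filter: a gene is kept iff its CPM reaches a threshold in
   at least ``max(ceil(prevalence_fraction * n_samples),
   min_prevalent_samples)`` samples AND it has a raw count > 0 in at
   least one sample of every stage;
3. gene-wise Z-scores (mean-centred, variance-scaled with the n-1
   sample standard deviation), by default of log2(CPM + 1); genes with
   zero variance are dropped and reported rather than propagated as
   NaN. Standardising raw CPM is available as an option, but a gene's
   highest-expression stage then dominates both its mean and its
   variance, which distorts trajectory shapes and makes within-cluster
   noise strongly anisotropic;
4. stage-mean profiles: per gene, the mean Z over the samples of one
   condition at each stage, columns in declared stage order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, RunConfig, SampleTable, check_samples_match

__all__ = [
    "CpmMatrix",
    "ZMatrix",
    "StageProfileMatrix",
    "compute_cpm",
    "log2_cpm",
    "filter_genes",
    "zscore_genes",
    "stage_profiles",
]


@dataclass
class CpmMatrix:
    """Counts-per-million matrix (genes x samples); columns sum to 1e6."""

    cpm: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cpm.columns)


@dataclass
class ZMatrix:
    """Gene-wise Z-scored expression (per retained gene: mean 0, sd 1)."""

    z: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


@dataclass
class StageProfileMatrix:
    """Gene x ordered-stage matrix of stage-mean Z-scores for one condition."""

    profiles: pd.DataFrame
    condition: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.profiles.to_numpy()).all():
            raise ValueError("stage profiles contain non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def stages(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def values(self) -> np.ndarray:
        return self.profiles.to_numpy(dtype=float)


def compute_cpm(counts: CountMatrix) -> CpmMatrix:
    """Scale each sample to counts per million of its total library.

    Library sizes are totals over every gene in ``counts``; run this on
    the unfiltered matrix so later filtering cannot change the scale.
    """
    df = counts.counts
    libsize = df.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(
            f"zero library size for sample(s): {', '.join(map(str, zero.index))}"
        )
    cpm = df.div(libsize, axis=1) * 1e6
    return CpmMatrix(cpm)


def log2_cpm(cpm: CpmMatrix, pseudocount: float = 1.0) -> CpmMatrix:
    """log2(CPM + pseudocount), the standard scale for expression profiles."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return CpmMatrix(np.log2(cpm.cpm + pseudocount))


def filter_genes(
    counts: CountMatrix, meta: SampleTable, cfg: RunConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply the prevalence + per-stage detection filter.

    Returns the filtered CountMatrix and a per-gene report with columns
    ``retained`` (0/1), ``n_samples_passing_cpm`` and ``failed_stage``
    (first stage with no detected sample, empty string if none).
    """
    check_samples_match(counts, meta)
    df = counts.counts
    cpm = compute_cpm(counts).cpm
    n_samples = df.shape[1]
    n_required = max(
        math.ceil(cfg.prevalence_fraction * n_samples), cfg.min_prevalent_samples
    )

    n_passing = (cpm >= cfg.cpm_threshold).sum(axis=1)
    prevalent = n_passing >= n_required

    failed_stage = pd.Series("", index=df.index, dtype=object)
    detected_everywhere = pd.Series(True, index=df.index)
    for stage in meta.stages_present:
        cols = meta.samples_of(stage=stage)
        detected = (df[cols] > 0).any(axis=1)
        newly_failed = detected_everywhere & ~detected
        failed_stage[newly_failed & (failed_stage == "")] = stage
        detected_everywhere &= detected

    retained = prevalent & detected_everywhere
    report = pd.DataFrame(
        {
            "retained": retained.astype(int),
            "n_samples_passing_cpm": n_passing.astype(int),
            "failed_stage": failed_stage,
        },
        index=df.index,
    )
    report.index.name = "gene_id"
    return CountMatrix(df.loc[retained]), report


def zscore_genes(cpm: CpmMatrix) -> tuple[ZMatrix, list[str]]:
    """Mean-centre and variance-scale each gene's CPM row (ddof=1).

    Genes with zero sample variance carry no trajectory information and
    are dropped; their ids are returned alongside the Z matrix.
    """
    df = cpm.cpm
    if df.shape[1] < 2:
        raise ValueError("Z-scoring requires at least 2 samples")
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    constant = sd == 0
    dropped = list(df.index[constant])
    kept = df.loc[~constant]
    z = kept.sub(mean[~constant], axis=0).div(sd[~constant], axis=0)
    return ZMatrix(z), dropped


def stage_profiles(
    z: ZMatrix, meta: SampleTable, condition: str
) -> StageProfileMatrix:
    """Mean Z per stage over one condition's samples, in stage order."""
    df = z.z
    missing = set(df.columns) - set(meta.sample_ids)
    if missing:
        raise ValueError(f"samples absent from metadata: {sorted(missing)}")
    profile_cols = {}
    for stage in meta.stages_present:
        cols = [s for s in meta.samples_of(condition=condition, stage=stage) if s in df.columns]
        if not cols:
            raise ValueError(
                f"condition {condition!r} has no samples at stage {stage!r}"
            )
        profile_cols[stage] = df[cols].mean(axis=1)
    profiles = pd.DataFrame(profile_cols, index=df.index)
    profiles.index.name = "gene_id"
    return StageProfileMatrix(profiles, condition)
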