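"""Synthetic inputs with the statistical structure the pipeline assumes.

``simulate_counts`` draws a negative-binomial gene x sample count matrix
in which every gene follows one of a small set of stage-trajectory
archetypes on the log-mean scale, with sample-specific library sizes and
a configurable fraction of genes whose archetype differs between the two
conditions (the planted "switched" genes). Defaults emulate the ovary
time-course design: 3 ordered stages, 6 samples per stage per condition,
nine archetype shapes, 200 genes per archetype, amplitude 2 Z-units,
dispersion 0.1, 10% switched genes.

The nine default archetypes are evenly spaced unit vectors in the plane
orthogonal to the flat trajectory (spanned by the orthonormalised linear
and quadratic stage contrasts), so they cover monotone up/down, early and
late peaks and intermediate transient shapes.

``simulate_ct`` and ``simulate_bisulfite`` generate the auxiliary assay
tables (qPCR cycle thresholds with a known log2 copy-number effect;
per-CpG bisulfite read counts with known percent methylation).

All generators are pure functions of their design and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleTable

__all__ = [
    "SimDesign",
    "SimTruth",
    "default_archetypes",
    "simulate_counts",
    "simulate_ct",
    "simulate_bisulfite",
]

DEFAULT_STAGES = ("E18.5", "12wk", "39wk")
DEFAULT_CONDITIONS = ("Natural", "IVF")


def _contrast_basis(n_stages: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(n_stages, dtype=float)
    lin = t - t.mean()
    lin /= np.linalg.norm(lin)
    quad = (t - t.mean()) ** 2
    quad -= quad.mean()
    quad -= (quad @ lin) * lin
    quad /= np.linalg.norm(quad)
    return lin, quad


def default_archetypes(n_stages: int = 3, n_archetypes: int = 9) -> np.ndarray:
    """Evenly spaced unit-norm trajectory shapes over ``n_stages`` stages.

    Shapes live in the plane orthogonal to the constant (flat) vector,
    spanned by the orthonormalised linear and quadratic stage contrasts;
    archetype i points at angle 2*pi*i/n in that plane. For the default
    nine shapes over three stages this covers monotone up/down, early and
    late peaks, transient spikes/dips and the intermediate ramps.

    Trajectories are injected on the log-mean scale, so after the
    pipeline's log-CPM Z-standardisation the expected stage profiles are
    (up to a common norm) the archetypes themselves, and even angular
    spacing in this plane is even spacing of the standardised profiles.
    """
    if n_stages < 3:
        raise ValueError("need at least 3 stages for trajectory archetypes")
    lin, quad = _contrast_basis(n_stages)
    angles = 2 * np.pi * np.arange(n_archetypes) / n_archetypes
    return np.outer(np.cos(angles), lin) + np.outer(np.sin(angles), quad)


@dataclass
class SimDesign:
    """Design of a simulated two-condition developmental time course."""

    n_stages: int = 3
    samples_per_stage_per_condition: int = 6
    archetypes: np.ndarray | None = None  # (n_archetypes, n_stages); default 9 shapes
    genes_per_archetype: int = 200
    switch_fraction: float = 0.1
    amplitude: float = 2.0
    baseline_log_mean: float = 4.6  # ~100 counts at unit scale
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    conditions: tuple[str, str] = DEFAULT_CONDITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetypes is None:
            self.archetypes = default_archetypes(self.n_stages)
        self.archetypes = np.asarray(self.archetypes, dtype=float)
        if self.archetypes.ndim != 2 or self.archetypes.shape[1] != self.n_stages:
            raise ValueError("archetypes must be (n_archetypes, n_stages)")
        if len(np.unique(self.archetypes, axis=0)) != len(self.archetypes):
            raise ValueError("archetype vectors must be distinct")
        if len(self.stage_labels) != self.n_stages:
            raise ValueError("stage_labels length must equal n_stages")
        if len(set(self.stage_labels)) != self.n_stages:
            raise ValueError("stage_labels must be distinct")
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise ValueError("exactly two distinct conditions required")
        if not 0 <= self.switch_fraction < 1:
            raise ValueError("switch_fraction must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.samples_per_stage_per_condition < 1 or self.genes_per_archetype < 1:
            raise ValueError("sample and gene counts must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be a positive interval")
        if len(self.archetypes) < 2 and self.switch_fraction > 0:
            raise ValueError("switching requires >= 2 archetypes")

    @property
    def n_genes(self) -> int:
        return len(self.archetypes) * self.genes_per_archetype

    @property
    def reference_condition(self) -> str:
        return self.conditions[0]

    @property
    def comparison_condition(self) -> str:
        return self.conditions[1]


@dataclass
class SimTruth:
    """Planted ground truth of a simulated dataset.

    ``genes``: archetype, cmp_archetype and is_switched per gene.
    ``samples``: stage, condition and library-size scale per sample.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion*mu^2."""
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(design: SimDesign) -> tuple[CountMatrix, SampleTable, SimTruth]:
    """Draw a count matrix, its metadata, and the planted truth."""
    rng = np.random.default_rng(design.seed)
    n_arch = len(design.archetypes)
    n_genes = design.n_genes
    n_per = design.samples_per_stage_per_condition

    # genes: archetype blocks, then a uniformly chosen switched subset
    gene_ids = [f"gene{g + 1:05d}" for g in range(n_genes)]
    src_arch = np.repeat(np.arange(n_arch), design.genes_per_archetype)
    n_switched = round(design.switch_fraction * n_genes)
    switched_idx = rng.choice(n_genes, size=n_switched, replace=False)
    cmp_arch = src_arch.copy()
    if n_switched:
        # switch target drawn uniformly among the other archetypes
        offsets = rng.integers(1, n_arch, size=n_switched)
        cmp_arch[switched_idx] = (src_arch[switched_idx] + offsets) % n_arch

    # samples: stage-major, condition, replicate within cell
    rows = []
    for stage in design.stage_labels:
        for cond in design.conditions:
            for rep in range(1, n_per + 1):
                rows.append(
                    {
                        "sample_id": f"{cond}_{stage}_r{rep}",
                        "stage": stage,
                        "condition": cond,
                        "replicate": f"r{rep}",
                    }
                )
    meta_df = pd.DataFrame(rows).set_index("sample_id")
    n_samples = len(meta_df)

    lo, hi = design.library_size_range
    libsizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    scale = libsizes / np.median(libsizes)

    baseline = rng.normal(design.baseline_log_mean, design.baseline_log_sd, n_genes)

    stage_idx = meta_df["stage"].map(
        {s: i for i, s in enumerate(design.stage_labels)}
    ).to_numpy()
    is_cmp = (meta_df["condition"] == design.comparison_condition).to_numpy()

    # per-sample archetype id per gene: source for reference samples,
    # switch target for comparison samples
    arch_per_sample = np.where(is_cmp[None, :], cmp_arch[:, None], src_arch[:, None])
    shape = design.archetypes[arch_per_sample, stage_idx[None, :]]
    mu = np.exp(baseline[:, None] + design.amplitude * shape) * scale[None, :]
    counts = _nb_draw(rng, mu, design.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=meta_df.index)
    counts_df.index.name = "gene_id"
    cm = CountMatrix(counts_df)
    st = SampleTable.from_frame(meta_df, list(design.stage_labels))

    genes_truth = pd.DataFrame(
        {
            "archetype": src_arch + 1,
            "cmp_archetype": cmp_arch + 1,
            "is_switched": src_arch != cmp_arch,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    samples_truth = meta_df.assign(library_size_scale=scale)
    return cm, st, SimTruth(genes_truth, samples_truth)


def simulate_ct(
    groups: dict[str, int] | None = None,
    effect_log2: float = 1.0,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    mt_targets: tuple[str, ...] = ("ND1", "Cox3"),
    nuclear_target: str = "18S",
    nuclear_ct: float = 15.0,
    base_delta_ct: float = -5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Ct table with a known log2 mtDNA copy-number effect.

    The first key of ``groups`` is the reference group; comparison-group
    ΔCt is shifted by +``effect_log2`` so the true relative ratio is
    2^(−effect_log2). Gaussian noise of ``noise_sd`` cycles is added per
    replicate measurement.
    """
    if groups is None:
        groups = {"Natural": 6, "IVF": 6}
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    group_names = list(groups)
    rows = []
    for gi, group in enumerate(group_names):
        shift = 0.0 if gi == 0 else effect_log2
        for s in range(1, groups[group] + 1):
            sample = f"{group}_{s}"
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": sample,
                        "target": nuclear_target,
                        "replicate": rep,
                        "ct": nuclear_ct + rng.normal(0, noise_sd),
                        "group": group,
                    }
                )
                for t in mt_targets:
                    rows.append(
                        {
                            "sample_id": sample,
                            "target": t,
                            "replicate": rep,
                            "ct": nuclear_ct
                            + base_delta_ct
                            + shift
                            + rng.normal(0, noise_sd),
                            "group": group,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_bisulfite(
    amplicons: dict[str, int] | None = None,
    true_percent: dict[str, dict[str, float]] | None = None,
    coverage_mean: float = 200.0,
    n_samples_per_group: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Targeted-bisulfite count table with known percent methylation.

    ``amplicons`` maps amplicon name -> number of CpGs; ``true_percent``
    maps group -> amplicon -> percent in [0, 100]. Coverage per CpG is
    Poisson(coverage_mean); methylated reads are Binomial(coverage, p).
    """
    if amplicons is None:
        amplicons = {"Esr1": 12, "LINE1": 20, "IAP": 15}
    if true_percent is None:
        true_percent = {
            "Natural": {a: 60.0 for a in amplicons},
            "IVF": {a: 45.0 for a in amplicons},
        }
    rng = np.random.default_rng(seed)
    rows = []
    for group, percents in true_percent.items():
        for a, n_cpg in amplicons.items():
            p = percents[a] / 100.0
            if not 0 <= p <= 1:
                raise ValueError(f"percent for {a!r} in {group!r} outside [0, 100]")
            for s in range(1, n_samples_per_group + 1):
                sample = f"{group}_{s}"
                cov = rng.poisson(coverage_mean, size=n_cpg)
                meth = rng.binomial(cov, p)
                for i in range(n_cpg):
                    rows.append(
                        {
                            "amplicon": a,
                            "cpg_index": i + 1,
                            "methylated": int(meth[i]),
                            "unmethylated": int(cov[i] - meth[i]),
                            "sample_id": sample,
                            "group": group,
                        }
                    )
    return pd.DataFrame(rows)
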