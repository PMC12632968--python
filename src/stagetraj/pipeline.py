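"""Config-driven orchestration of the full trajectory analysis.

``run_trajectory_analysis`` executes filter -> CPM -> Z -> reference
stage profiles -> WCSS sweep -> elbow selection -> deterministic cluster
labelling -> comparison-condition projection -> transition table, writing
every tabular artifact plus a JSON run manifest (config echo, seed, input
checksums, per-stage gene counts, selected k with its gain table) that
suffices to re-run the analysis bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assays import ddct_ratio, methylation_summary
from .clustering import label_clusters, select_k, wcss_sweep
from .io import (
    CountMatrix,
    RunConfig,
    SampleTable,
    check_samples_match,
    read_counts,
    read_sample_table,
    write_table,
)
from .preprocess import (
    compute_cpm,
    filter_genes,
    log2_cpm,
    stage_profiles,
    zscore_genes,
)
from .switching import assign_to_centroids, transition_table

__all__ = [
    "TrajectoryResult",
    "run_trajectory_analysis",
    "analyse",
    "run_ddct",
    "run_methylation",
    "load_config",
]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML mapping of field name -> value."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Log:
    def __init__(self, path: Path | None):
        self.path = path
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)

    def __call__(self, msg: str) -> None:
        if self.path is not None:
            stamp = _dt.datetime.now().isoformat(timespec="seconds")
            with open(self.path, "a") as fh:
                fh.write(f"{stamp}\t{msg}\n")


@dataclass
class TrajectoryResult:
    """Everything the trajectory pipeline computed, plus the manifest."""

    selected_k: int
    rationale: dict
    model: object  # labelled ClusterModel
    curve: object  # WcssCurve
    ref_assignments: pd.DataFrame
    cmp_assignments: pd.DataFrame
    transitions: object  # TransitionTable
    filter_report: pd.DataFrame
    dropped_zero_variance: list
    manifest: dict


def analyse(
    counts: CountMatrix,
    meta: SampleTable,
    cfg: RunConfig,
    reference_condition: str,
    comparison_condition: str,
    k_override: int | None = None,
    log=lambda msg: None,
) -> TrajectoryResult:
    """Run the full in-memory analysis on validated inputs."""
    check_samples_match(counts, meta)
    for cond in (reference_condition, comparison_condition):
        if cond not in set(meta.table["condition"]):
            raise ValueError(f"condition {cond!r} has no samples in the metadata")
    log(f"input: {counts.shape[0]} genes x {counts.shape[1]} samples")

    filtered, report = filter_genes(counts, meta, cfg)
    log(f"filter: retained {filtered.shape[0]} / {counts.shape[0]} genes")

    cpm_full = compute_cpm(counts)
    cpm = type(cpm_full)(cpm_full.cpm.loc[filtered.gene_ids])
    if cfg.log_cpm:
        cpm = log2_cpm(cpm)

    if cfg.zscore_within_condition:
        parts, dropped_sets = [], []
        for cond in (reference_condition, comparison_condition):
            cols = meta.samples_of(condition=cond)
            zc, dc = zscore_genes(type(cpm)(cpm.cpm[cols]))
            parts.append(zc.z)
            dropped_sets.append(set(dc))
        from .preprocess import ZMatrix

        dropped = sorted(set().union(*dropped_sets))
        keep = [g for g in cpm.gene_ids if g not in set(dropped)]
        zm = ZMatrix(pd.concat([p.reindex(keep) for p in parts], axis=1))
    else:
        zm, dropped = zscore_genes(cpm)
    log(f"zscore: dropped {len(dropped)} zero-variance genes")

    ref_profiles = stage_profiles(zm, meta, reference_condition)
    cmp_profiles = stage_profiles(zm, meta, comparison_condition)

    if k_override is not None:
        from .clustering import kmeans_fit, _subseed

        log(f"k override: fitting k={k_override}, sweep skipped")
        model = kmeans_fit(
            ref_profiles,
            k_override,
            n_restarts=cfg.n_restarts,
            max_iter=cfg.max_iter,
            seed=_subseed(cfg.seed, k_override),
        )
        curve = None
        selected_k, rationale = k_override, {"rule": "override", "selected_k": k_override}
    else:
        curve, models = wcss_sweep(ref_profiles, cfg)
        selected_k, rationale = select_k(curve, cfg.gain_threshold)
        model = models[selected_k]
        log(f"sweep: k={cfg.k_min}..{cfg.k_max}; selected k={selected_k} "
            f"({rationale['rule']})")
    model = label_clusters(model)

    ref_assign = assign_to_centroids(ref_profiles, model)
    cmp_assign = assign_to_centroids(cmp_profiles, model)
    transitions = transition_table(
        ref_assign, cmp_assign, clusters=list(model.centroids.index)
    )
    log(f"transitions: {transitions.n_switched} / {transitions.n_genes} "
        "genes switched cluster")

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "reference_condition": reference_condition,
        "comparison_condition": comparison_condition,
        "k_override": k_override,
        "n_genes_input": counts.shape[0],
        "n_samples": counts.shape[1],
        "n_genes_filtered": filtered.shape[0],
        "n_genes_zero_variance": len(dropped),
        "n_genes_clustered": len(model.assignments),
        "selected_k": selected_k,
        "selection": {
            "rule": rationale.get("rule"),
            "gains": {str(k): g for k, g in rationale.get("gains", {}).items()},
        },
        "n_switched": transitions.n_switched,
    }
    return TrajectoryResult(
        selected_k=selected_k,
        rationale=rationale,
        model=model,
        curve=curve,
        ref_assignments=ref_assign,
        cmp_assignments=cmp_assign,
        transitions=transitions,
        filter_report=report,
        dropped_zero_variance=list(dropped),
        manifest=manifest,
    )


def run_trajectory_analysis(
    counts_path: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    cfg: RunConfig | str | Path | None = None,
    stage_order: list[str] | None = None,
    reference_condition: str = "Natural",
    comparison_condition: str = "IVF",
    k_override: int | None = None,
) -> TrajectoryResult:
    """File-to-file pipeline run; writes all artifacts into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")
    if cfg is None:
        cfg = RunConfig()
    elif not isinstance(cfg, RunConfig):
        cfg = load_config(cfg)
    if stage_order is None:
        stage_order = ["E18.5", "12wk", "39wk"]

    log(f"seed={cfg.seed} counts={counts_path} metadata={metadata_path}")
    counts = read_counts(counts_path)
    meta = read_sample_table(metadata_path, stage_order)
    res = analyse(
        counts, meta, cfg, reference_condition, comparison_condition,
        k_override=k_override, log=log,
    )

    write_table(res.filter_report, out / "filter_report.tsv")
    if res.curve is not None:
        write_table(res.curve.to_frame(), out / "wcss_curve.tsv")
    write_table(res.model.to_frame(), out / "assignments.tsv")
    write_table(res.model.centroids, out / "centroids.tsv")
    write_table(res.cmp_assignments, out / "cmp_assignments.tsv")
    write_table(res.transitions.counts, out / "transition.tsv")
    switched = res.transitions.switched.copy()
    switched["sq_distance_ref"] = res.ref_assignments["sq_distance"].reindex(
        switched.index
    )
    switched["sq_distance_cmp"] = res.cmp_assignments["sq_distance"].reindex(
        switched.index
    )
    write_table(switched, out / "switched_genes.tsv")

    manifest = dict(res.manifest)
    manifest["inputs"] = {
        "counts": {"path": str(counts_path), "sha256": _sha256(counts_path)},
        "metadata": {"path": str(metadata_path), "sha256": _sha256(metadata_path)},
    }
    manifest["stage_order"] = stage_order
    res.manifest = manifest
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log("done")
    return res


def run_ddct(
    ct_path: str | Path,
    out_dir: str | Path,
    nuclear_target: str = "18S",
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Read a Ct table, compute ΔΔCt ratios, write ratios.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct = pd.read_csv(ct_path, sep="\t")
    ratios = ddct_ratio(ct, nuclear_target=nuclear_target,
                        reference_group=reference_group)
    ratios.to_csv(out / "ratios.tsv", sep="\t", index=False)
    return ratios


def run_methylation(
    counts_path: str | Path, out_dir: str | Path, min_coverage: int = 10
):
    """Read bisulfite counts, summarise, write the percent tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mc = pd.read_csv(counts_path, sep="\t")
    summary = methylation_summary(mc, min_coverage=min_coverage)
    summary.per_cpg.to_csv(out / "methylation_per_cpg.tsv", sep="\t", index=False)
    summary.per_amplicon.to_csv(
        out / "methylation_percent.tsv", sep="\t", index=False
    )
    summary.group_means.to_csv(
        out / "methylation_group_means.tsv", sep="\t", index=False
    )
    return summary
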