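"""Closed-form assay summaries: ΔΔCt copy-number ratios and amplicon methylation.

``ddct_ratio`` implements the ΔΔCt method for mitochondrial-to-nuclear
DNA copy number from qPCR cycle thresholds: per sample,
ΔCt = Ct(mt target) − Ct(nuclear target); ΔΔCt centres ΔCt on the
reference group's mean; the relative ratio is 2^(−ΔΔCt), so the reference
group has geometric-mean ratio 1 by construction.

``methylation_summary`` turns per-CpG methylated/unmethylated read counts
from targeted bisulfite sequencing into percent methylation per CpG, a
coverage-weighted per-amplicon percent per sample, and unweighted group
means, with a minimum-coverage floor below which CpGs are flagged missing
rather than reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ddct_ratio",
    "methylation_summary",
    "MethylationSummary",
    "welch_ttest",
]

CT_RANGE = (0.0, 45.0)

_CT_COLUMNS = ("sample_id", "target", "ct", "group")
_METH_COLUMNS = (
    "amplicon",
    "cpg_index",
    "methylated",
    "unmethylated",
    "sample_id",
    "group",
)


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} missing column(s): {', '.join(missing)}")


def ddct_ratio(
    ct: pd.DataFrame,
    nuclear_target: str = "18S",
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Per-sample relative mtDNA/nDNA ratio by the ΔΔCt method.

    ``ct`` needs columns sample_id, target, ct, group (a replicate column
    is optional; replicate Cts are averaged per sample and target). Each
    non-nuclear target is normalised separately, and a combined
    ``mt_mean`` row reports the geometric mean of the per-target ratios.

    Returns a long DataFrame with columns sample_id, group, target,
    delta_ct, ddct, ratio.
    """
    _require_columns(ct, _CT_COLUMNS, "Ct table")
    ct = ct.copy()
    ct["ct"] = ct["ct"].astype(float)
    bad = ct[(ct["ct"] <= CT_RANGE[0]) | (ct["ct"] >= CT_RANGE[1])]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"Ct {r['ct']} out of range {CT_RANGE} for sample {r['sample_id']!r}, "
            f"target {r['target']!r}"
        )
    targets = sorted(set(ct["target"]))
    if nuclear_target not in targets:
        raise ValueError(f"nuclear target {nuclear_target!r} absent from Ct table")
    mt_targets = [t for t in targets if t != nuclear_target]
    if not mt_targets:
        raise ValueError("Ct table contains no mitochondrial target")
    groups = ct.groupby("sample_id")["group"].agg(set)
    multi = groups[groups.map(len) > 1]
    if len(multi):
        raise ValueError(f"sample {multi.index[0]!r} appears in multiple groups")
    group_of = groups.map(lambda s: next(iter(s)))
    if reference_group is None:
        reference_group = sorted(set(ct["group"]))[0]
    if reference_group not in set(ct["group"]):
        raise ValueError(f"empty reference group {reference_group!r}")

    mean_ct = ct.groupby(["sample_id", "target"])["ct"].mean().unstack("target")
    if mean_ct[nuclear_target].isna().any():
        missing = list(mean_ct.index[mean_ct[nuclear_target].isna()])
        raise ValueError(f"missing nuclear Ct for sample(s): {missing}")

    rows = []
    for target in mt_targets:
        delta = mean_ct[target] - mean_ct[nuclear_target]
        present = delta.dropna()
        ref_samples = [s for s in present.index if group_of[s] == reference_group]
        if not ref_samples:
            raise ValueError(
                f"reference group {reference_group!r} has no Ct for target {target!r}"
            )
        ddct = present - present.loc[ref_samples].mean()
        for sample, d in ddct.items():
            rows.append(
                {
                    "sample_id": sample,
                    "group": group_of[sample],
                    "target": target,
                    "delta_ct": float(present[sample]),
                    "ddct": float(d),
                    "ratio": float(2.0 ** (-d)),
                }
            )
    out = pd.DataFrame(rows)
    # combined mt estimate: geometric mean across mt targets per sample
    combined = (
        out.groupby("sample_id")
        .agg(
            group=("group", "first"),
            delta_ct=("delta_ct", "mean"),
            ddct=("ddct", "mean"),
        )
        .reset_index()
    )
    combined["target"] = "mt_mean"
    combined["ratio"] = 2.0 ** (-combined["ddct"])
    out = pd.concat([out, combined[out.columns]], ignore_index=True)
    return out.sort_values(["target", "group", "sample_id"]).reset_index(drop=True)


@dataclass
class MethylationSummary:
    """Per-CpG, per-amplicon and per-group percent-methylation tables."""

    per_cpg: pd.DataFrame
    per_amplicon: pd.DataFrame
    group_means: pd.DataFrame
    min_coverage: int

    def to_frame(self) -> pd.DataFrame:
        return self.per_amplicon


def methylation_summary(
    mc: pd.DataFrame, min_coverage: int = 10
) -> MethylationSummary:
    """Summarise targeted-bisulfite counts into percent methylation.

    Per CpG: methylated / (methylated + unmethylated) x 100 where
    coverage >= ``min_coverage``, else flagged ``low_coverage`` and
    excluded. Per amplicon (per sample): coverage-weighted mean over its
    qualifying CpGs; an amplicon with no qualifying CpG is reported
    missing (NaN), never zero. Group means are unweighted over samples.
    """
    _require_columns(mc, _METH_COLUMNS, "methylation count table")
    mc = mc.copy()
    for col in ("methylated", "unmethylated"):
        mc[col] = mc[col].astype(int)
        if (mc[col] < 0).any():
            raise ValueError(f"negative {col} count")
    mc["coverage"] = mc["methylated"] + mc["unmethylated"]
    mc["low_coverage"] = mc["coverage"] < min_coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        mc["percent"] = np.where(
            mc["low_coverage"],
            np.nan,
            100.0 * mc["methylated"] / mc["coverage"].replace(0, np.nan),
        )
    per_cpg = mc[
        ["sample_id", "group", "amplicon", "cpg_index", "coverage",
         "low_coverage", "percent"]
    ].reset_index(drop=True)

    rows = []
    for (sample, group, amp), sub in per_cpg.groupby(
        ["sample_id", "group", "amplicon"], sort=True
    ):
        ok = sub[~sub["low_coverage"]]
        if len(ok) == 0:
            pct, n_used = np.nan, 0
        else:
            pct = float(np.average(ok["percent"], weights=ok["coverage"]))
            n_used = len(ok)
        rows.append(
            {
                "sample_id": sample,
                "group": group,
                "amplicon": amp,
                "percent": pct,
                "n_cpgs_used": n_used,
                "n_cpgs_total": len(sub),
                "missing": n_used == 0,
            }
        )
    per_amplicon = pd.DataFrame(rows)

    group_means = (
        per_amplicon.groupby(["amplicon", "group"])["percent"]
        .agg(percent="mean", n_samples="count")
        .reset_index()
    )
    return MethylationSummary(per_cpg, per_amplicon, group_means, min_coverage)


def welch_ttest(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    group_a: str,
    group_b: str,
) -> dict:
    """Welch two-sample t-test between two labelled groups of values."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    a = values[groups == group_a]
    b = values[groups == group_b]
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {
        "group_a": group_a,
        "group_b": group_b,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "t": float(res.statistic),
        "p_value": float(res.pvalue),
        "df": float(res.df),
    }
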