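"""Comparative-Ct (2^-ddCt) relative expression analysis.

Raw threshold-cycle measurements are reduced per sample x gene by
replicate QC, normalized to a reference gene (dCt), scaled to a
calibrator (ddCt), and converted to fold changes 2^-ddCt under the
perfect-doubling assumption (amplification efficiency 2).  Group
comparisons use the equal-variance two-sample t-test; between-gene
relationships use pairwise Pearson correlation.

The calibrator is either a designated sample ID or, by default, the
pooled mean control dCt per gene (so the mean control fold change is
of order 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "CtRecord",
    "GroupComparison",
    "replicate_qc",
    "delta_ct",
    "relative_expression",
    "expression_table",
    "compare_groups",
    "group_comparison_table",
    "correlation_matrix",
]

SD_CUT_DEFAULT = 0.5  # cycles; common qPCR duplicate-agreement rule
REFERENCE_GENE_DEFAULT = "GUSB"
# Persistent-outlier exclusion targets gross technical failures (several
# cycles off, i.e. many group-SDs out).  At 4 SD the rule essentially
# never clips legitimate biological variation, so the downstream t-test
# keeps its nominal size; a 3-SD cut measurably inflates it.
PERSISTENT_OUTLIER_SD = 4.0


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    group: str  # "case" | "control"
    gene: str
    replicate: int
    ct: float


@dataclass(frozen=True)
class GroupComparison:
    mean_case: float
    sem_case: float
    mean_ctrl: float
    sem_ctrl: float
    t: float
    p: float


def replicate_qc(
    replicates: Sequence[float],
    sd_cut: float = SD_CUT_DEFAULT,
) -> tuple[float, str]:
    """Collapse technical replicates of one sample x gene to a mean Ct.

    Returns ``(mean, flag)`` where flag is ``"ok"``, ``"single"`` (one
    replicate, mean returned with a warning) or ``"outlier"`` (replicate
    SD exceeds `sd_cut`; the well should be excluded downstream).
    """
    if len(replicates) == 0:
        raise ValueError("replicate_qc requires at least one Ct value")
    arr = np.asarray(replicates, dtype=float)
    if arr.size == 1:
        warnings.warn("single replicate; no QC possible", stacklevel=2)
        return float(arr[0]), "single"
    sd = float(arr.std(ddof=1))
    mean = float(arr.mean())
    if sd > sd_cut:
        return mean, "outlier"
    return mean, "ok"


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """dCt = Ct(target) - Ct(reference gene)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return ct_target - ct_reference


def relative_expression(dct_sample: float, dct_calibrator: float) -> float:
    """Fold change 2^-(dCt_sample - dCt_calibrator)."""
    if not (math.isfinite(dct_sample) and math.isfinite(dct_calibrator)):
        raise ValueError("dCt values must be finite")
    return 2.0 ** -(dct_sample - dct_calibrator)


def _qc_means(ct: pd.DataFrame, sd_cut: float) -> pd.DataFrame:
    """Per sample x gene replicate means, outlier wells dropped."""
    grp = ct.groupby(["sample_id", "group", "gene"])["ct"]
    agg = grp.agg(mean="mean", sd="std", n="size").reset_index()
    agg["sd"] = agg["sd"].fillna(0.0)
    keep = agg[(agg["n"] == 1) | (agg["sd"] <= sd_cut)]
    return keep.rename(columns={"mean": "ct"})[["sample_id", "group", "gene", "ct"]]


def expression_table(
    ct: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE_DEFAULT,
    calibrator: str | None = None,
    sd_cut: float = SD_CUT_DEFAULT,
    drop_persistent_outliers: bool = True,
) -> pd.DataFrame:
    """Full comparative-Ct reduction of a long Ct table.

    Parameters
    ----------
    ct:
        Long table with columns sample_id, group, gene, replicate, ct.
    reference_gene:
        Endogenous control used for dCt normalization.
    calibrator:
        Sample ID whose dCt anchors the ddCt scale.  ``None`` uses the
        pooled mean control dCt per gene.
    sd_cut:
        Replicate-SD threshold; noisier wells are excluded.
    drop_persistent_outliers:
        Exclude samples whose dCt lies more than 3 group-SDs from the
        group mean for a gene.

    Returns
    -------
    Long table with columns sample_id, group, gene, dct, rel_expr.
    """
    required = {"sample_id", "group", "gene", "replicate", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")

    measured_ref = set(ct.loc[ct["gene"] == reference_gene, "sample_id"])
    never_measured = set(ct["sample_id"]) - measured_ref
    if never_measured:
        raise ValueError(
            f"missing reference gene {reference_gene!r} for samples: "
            f"{sorted(never_measured)}"
        )

    means = _qc_means(ct, sd_cut)
    ref = means[means["gene"] == reference_gene][["sample_id", "ct"]].rename(
        columns={"ct": "ct_ref"}
    )
    tgt = means[means["gene"] != reference_gene]
    merged = tgt.merge(ref, on="sample_id", how="left")
    qc_lost = merged[merged["ct_ref"].isna()]["sample_id"].unique()
    if len(qc_lost):
        # reference well failed replicate QC: the sample cannot be
        # normalized and is excluded like any persistent outlier
        warnings.warn(
            f"reference-gene well failed QC; dropping samples {sorted(qc_lost)}",
            stacklevel=2,
        )
        merged = merged[merged["ct_ref"].notna()]
    merged = merged.copy()
    merged["dct"] = merged["ct"] - merged["ct_ref"]

    if drop_persistent_outliers:
        stats = merged.groupby(["group", "gene"])["dct"].transform
        z = (merged["dct"] - stats("mean")) / stats("std").replace(0.0, np.nan)
        merged = merged[z.abs().fillna(0.0) <= PERSISTENT_OUTLIER_SD].copy()

    if calibrator is not None:
        cal = merged[merged["sample_id"] == calibrator].set_index("gene")["dct"]
        if cal.empty:
            raise ValueError(f"calibrator sample {calibrator!r} not found")
    else:
        cal = merged[merged["group"] == "control"].groupby("gene")["dct"].mean()
    merged["rel_expr"] = 2.0 ** -(merged["dct"] - merged["gene"].map(cal))
    return merged[["sample_id", "group", "gene", "dct", "rel_expr"]].reset_index(
        drop=True
    )


def compare_groups(
    case_values: Sequence[float],
    control_values: Sequence[float],
) -> GroupComparison:
    """Means +/- SEM per group and an equal-variance two-sided t-test."""
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("each group needs >= 2 values for a t-test")
    t, p = _sps.ttest_ind(case, ctrl, equal_var=True)
    return GroupComparison(
        mean_case=float(case.mean()),
        sem_case=float(case.std(ddof=1) / math.sqrt(case.size)),
        mean_ctrl=float(ctrl.mean()),
        sem_ctrl=float(ctrl.std(ddof=1) / math.sqrt(ctrl.size)),
        t=float(t),
        p=float(p),
    )


def group_comparison_table(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene case/control comparison of a long expression table.

    Group means and SEMs are reported on the fold-change scale
    (rel_expr), matching how relative expression is conventionally
    displayed.  The t-test runs on log2(rel_expr) — equivalently on
    -ddCt — because threshold cycles, not fold changes, are the
    normally distributed measurement scale; a t-test on raw fold
    changes would be anticonservative.  Positive t means higher
    expression in cases.
    """
    rows = []
    for gene, sub in expr.groupby("gene"):
        case = sub.loc[sub["group"] == "case", "rel_expr"].to_numpy()
        ctrl = sub.loc[sub["group"] == "control", "rel_expr"].to_numpy()
        linear = compare_groups(case, ctrl)
        logscale = compare_groups(np.log2(case), np.log2(ctrl))
        rows.append(
            {
                "gene": gene,
                "mean_case": linear.mean_case,
                "sem_case": linear.sem_case,
                "mean_ctrl": linear.mean_ctrl,
                "sem_ctrl": linear.sem_ctrl,
                "t": logscale.t,
                "p": logscale.p,
            }
        )
    return pd.DataFrame(rows)


def correlation_matrix(
    expr: pd.DataFrame,
    min_samples: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and p over a sample x gene wide table.

    Pairs with fewer than `min_samples` complete observations or a
    constant column are reported as missing (NaN).  Returns (r, p)
    DataFrames; r is symmetric with unit diagonal.
    """
    genes = list(expr.columns)
    r = pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes)
    p = pd.DataFrame(np.nan, index=genes, columns=genes)
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            pair = expr[[gi, gj]].dropna()
            if len(pair) < min_samples:
                r.loc[gi, gj] = r.loc[gj, gi] = np.nan
                continue
            x, y = pair[gi].to_numpy(), pair[gj].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r.loc[gi, gj] = r.loc[gj, gi] = np.nan
                continue
            rv, pv = _sps.pearsonr(x, y)
            r.loc[gi, gj] = r.loc[gj, gi] = rv
            p.loc[gi, gj] = p.loc[gj, gi] = pv
    return r, p
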