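"""Cross-cohort baseline stability of healthy-control expression.

Per-family log2 fold change of healthy-control mean RPM between two cohorts,
a two-sample Kolmogorov–Smirnov comparison of |log2FC| between miRNAs and the
noncanonical classes, and the linearity (R^2) of the log10 mean–mean
relationship per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import class_of_family

logger = logging.getLogger(__name__)


def divergence_log2fc(means_a: pd.Series, means_b: pd.Series,
                      eps: float = 0.01) -> pd.Series:
    """log2((mean_B + eps) / (mean_A + eps)) on the shared family universe.

    Families present in only one cohort are dropped (logged).  Both means zero
    gives exactly 0 by pseudocount symmetry.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    shared = means_a.index.intersection(means_b.index)
    dropped = len(means_a.index.union(means_b.index)) - len(shared)
    if dropped:
        logger.info("divergence_log2fc: dropped %d families absent from one cohort",
                    dropped)
    return pd.Series(
        np.log2((means_b[shared] + eps) / (means_a[shared] + eps)),
        index=shared, name="log2fc")


def ks_compare(x, y) -> tuple[float, float]:
    """Two-sample KS: D = sup |ECDF_x - ECDF_y|, asymptotic two-sided P."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("ks_compare requires nonempty samples")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def baseline_linearity(means_a: pd.Series, means_b: pd.Series,
                       eps: float = 0.01) -> float:
    """R^2 of OLS of log10(mean_B + eps) on log10(mean_A + eps)."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    shared = means_a.index.intersection(means_b.index)
    if len(shared) < 3:
        raise ValueError("baseline_linearity requires >= 3 shared families")
    x = np.log10(means_a[shared].to_numpy(dtype=float) + eps)
    y = np.log10(means_b[shared].to_numpy(dtype=float) + eps)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor (cohort A means)")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2)


@dataclass
class DivergenceSummary:
    ks_d: float
    ks_p: float
    r2_mirna: float
    r2_noncanonical: float
    n_mirna: int
    n_noncanonical: int

    def to_dict(self) -> dict:
        return {"ks_d": self.ks_d, "ks_p": self.ks_p,
                "r2_mirna": self.r2_mirna,
                "r2_noncanonical": self.r2_noncanonical,
                "n_mirna": self.n_mirna,
                "n_noncanonical": self.n_noncanonical}


def divergence_table(family_rpm_a: pd.DataFrame, metadata_a: pd.DataFrame,
                     family_rpm_b: pd.DataFrame, metadata_b: pd.DataFrame,
                     eps: float = 0.01, reference_group: str = "HC"
                     ) -> tuple[pd.DataFrame, DivergenceSummary]:
    """Full divergence analysis between the healthy controls of two cohorts.

    Convention: cohort A (first argument) is the denominator of the fold
    change.  Families split into miRNA vs noncanonical (tsRNA/rsRNA/ysRNA);
    the KS test compares |log2FC| of the two partitions and R^2 is reported
    per partition.
    """
    ids_a = metadata_a.index[metadata_a["group"] == reference_group]
    ids_b = metadata_b.index[metadata_b["group"] == reference_group]
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError(f"group {reference_group!r} missing from a cohort")
    means_a = family_rpm_a[ids_a].mean(axis=1)
    means_b = family_rpm_b[ids_b].mean(axis=1)
    log2fc = divergence_log2fc(means_a, means_b, eps)
    classes = log2fc.index.map(
        lambda f: "miRNA" if class_of_family(f) == "miRNA" else "noncanonical")
    table = pd.DataFrame({
        "class": classes,
        "mean_rpm_a": means_a[log2fc.index],
        "mean_rpm_b": means_b[log2fc.index],
        "log2fc": log2fc,
    })
    table.index.name = "family"
    mir = table[table["class"] == "miRNA"]
    nc = table[table["class"] == "noncanonical"]
    d, p = ks_compare(mir["log2fc"].abs(), nc["log2fc"].abs())
    summary = DivergenceSummary(
        ks_d=d, ks_p=p,
        r2_mirna=baseline_linearity(mir["mean_rpm_a"], mir["mean_rpm_b"], eps),
        r2_noncanonical=baseline_linearity(nc["mean_rpm_a"], nc["mean_rpm_b"], eps),
        n_mirna=len(mir), n_noncanonical=len(nc))
    return table, summary
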