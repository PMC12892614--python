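"""Covariate-adjusted differential expression and common-signature derivation.

Each family's RPM is regressed on a group indicator plus age and sex
(ordinary least squares, two-sided t-test on the group coefficient), P-values
are Bonferroni-corrected per contrast, and the signature is the set of
families significant in *both* case-vs-control contrasts with a consistent
direction.

The fit is on raw RPM by default (a log2(RPM+1) variant is available behind
``log_transform``).  Sex is encoded 0/1 with female = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class FamilyFit:
    coefficient: float
    t: float
    df: int
    p: float


@dataclass
class Signature:
    """Ordered set of (family, direction) pairs with derivation provenance."""

    entries: list            # [(family, "up" | "down"), ...]
    contrasts: tuple
    alpha: float

    @property
    def families(self) -> list:
        return [f for f, _ in self.entries]

    @property
    def directions(self) -> dict:
        return dict(self.entries)

    def __len__(self):
        return len(self.entries)


def design_matrix(metadata: pd.DataFrame, contrast: tuple[str, str]
                  ) -> tuple[np.ndarray, pd.Index]:
    """[intercept, case indicator, age, sex(M=1)] for the two contrast groups.

    Raises on a rank-deficient design, naming the collinear column.
    """
    control, case = contrast
    mask = metadata["group"].isin(contrast)
    meta = metadata[mask]
    if len(meta) < 5:
        raise ValueError(f"contrast {contrast}: needs >= 5 samples, got {len(meta)}")
    case_ind = (meta["group"] == case).astype(float).to_numpy()
    age = meta["age"].to_numpy(dtype=float)
    sex = (meta["sex"] == "M").astype(float).to_numpy()
    X = np.column_stack([np.ones(len(meta)), case_ind, age, sex])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for name, col in (("group", case_ind), ("age", age), ("sex", sex)):
            if np.ptp(col) == 0:
                raise ValueError(
                    f"rank-deficient design for contrast {contrast}: "
                    f"column {name!r} is constant")
        raise ValueError(f"rank-deficient design for contrast {contrast}")
    return X, meta.index


def _ols_group_stats(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized OLS of every column of Y on X; returns (coef, t, df) for the
    group-indicator column.  Zero-residual fits give t = 0 when the coefficient
    is 0 (P = 1) and t = +/-inf otherwise."""
    n, p = X.shape
    constant = np.ptp(Y, axis=0) == 0
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    rss = (resid ** 2).sum(axis=0)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2, 0.0) * XtX_inv[1, 1])
    coef = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / np.where(se > 0, se, 1.0),
                     np.where(np.isclose(coef, 0.0), 0.0,
                              np.sign(coef) * np.inf))
    # a constant response fits the intercept exactly: coefficient 0, no signal
    coef = np.where(constant, 0.0, coef)
    t = np.where(constant, 0.0, t)
    return coef, t, df


def fit_family_model(rpm: pd.Series, metadata: pd.DataFrame,
                     contrast: tuple[str, str],
                     log_transform: bool = False) -> FamilyFit:
    """OLS of one family's expression on [intercept, case, age, sex]."""
    X, ids = design_matrix(metadata, contrast)
    y = rpm.loc[ids].to_numpy(dtype=float)[:, None]
    if log_transform:
        y = np.log2(y + 1.0)
    coef, t, df = _ols_group_stats(X, y)
    p = float(2 * stats.t.sf(np.abs(t[0]), df)) if np.isfinite(t[0]) else 0.0
    if t[0] == 0 and np.isclose(coef[0], 0.0):
        p = 1.0
    return FamilyFit(float(coef[0]), float(t[0]), int(df), p)


def fit_all_families(family_rpm: pd.DataFrame, metadata: pd.DataFrame,
                     contrast: tuple[str, str],
                     log_transform: bool = False) -> pd.DataFrame:
    """Differential table for one contrast over every family.

    Columns: coefficient, t, df, p, p_bonferroni, direction.  Bonferroni m is
    the number of families tested in this contrast.
    """
    X, ids = design_matrix(metadata, contrast)
    Y = family_rpm[ids].T.to_numpy(dtype=float)
    if log_transform:
        Y = np.log2(Y + 1.0)
    coef, t, df = _ols_group_stats(X, Y)
    with np.errstate(invalid="ignore"):
        p = np.where(np.isfinite(t), 2 * stats.t.sf(np.abs(t), df), 0.0)
    p = np.where((t == 0) & np.isclose(coef, 0.0), 1.0, p)
    table = pd.DataFrame({
        "coefficient": coef, "t": t, "df": df, "p": p,
        "p_bonferroni": adjust_bonferroni(p),
        "direction": np.where(coef >= 0, "up", "down"),
    }, index=family_rpm.index)
    table.index.name = "family"
    return table


def adjust_bonferroni(p: np.ndarray) -> np.ndarray:
    """p_adj = min(1, p * m) with m the vector length."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("P-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def derive_signature(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     alpha: float = 0.05,
                     contrasts: tuple = ("HC_vs_UC", "HC_vs_CD"),
                     direction: str | None = None) -> Signature:
    """Families significant (Bonferroni-adjusted P < alpha) in BOTH contrasts
    with the same direction.

    ``direction`` = "up" restricts to commonly upregulated families; the
    default admits both directions and records each family's direction.
    """
    if set(table_a.index) != set(table_b.index):
        raise ValueError("differential tables cover different family sets")
    table_b = table_b.reindex(table_a.index)
    sig = ((table_a["p_bonferroni"] < alpha)
           & (table_b["p_bonferroni"] < alpha)
           & (table_a["direction"] == table_b["direction"]))
    if direction is not None:
        sig &= table_a["direction"] == direction
    entries = [(fam, table_a.loc[fam, "direction"]) for fam in table_a.index[sig]]
    return Signature(entries=entries, contrasts=contrasts, alpha=alpha)
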