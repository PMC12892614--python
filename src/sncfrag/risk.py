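"""Signature-based risk scoring, ROC/AUC, DeLong comparison and the
cross-validation harness.

The risk score of a sample is a signed sum of per-family z-scores:

    score = sum_i  d_i * (e_i - mu_i) / tau_i

where ``e_i`` is log2(RPM + 1) of signature family ``i`` in the sample,
``mu_i`` / ``tau_i`` are that family's mean / SD over a reference population,
and ``d_i`` is +1 for up- and -1 for down-regulated signature families.
Classification power is evaluated with repeated stratified five-fold
cross-validation in which the *entire* signature-derivation procedure and the
baseline are re-computed on the training folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import Signature, derive_signature, fit_all_families

logger = logging.getLogger(__name__)


def log_expression(family_rpm: pd.DataFrame) -> pd.DataFrame:
    """log2(RPM + 1), the expression scale of the risk score."""
    return np.log2(family_rpm + 1.0)


# ---------------------------------------------------------------------------
# baseline and score

def compute_baseline(log_expr: pd.DataFrame, population_ids,
                     signature: Signature) -> pd.DataFrame:
    """Per-family mean (mu) and n-1 SD (tau) of log2(RPM+1) over the reference
    population.  Zero-variance families are dropped with a warning.

    Returns a DataFrame indexed by family with columns mu, tau, direction.
    """
    population_ids = pd.Index(population_ids)
    if len(population_ids) < 2:
        raise ValueError("baseline population must contain >= 2 samples")
    missing = [f for f in signature.families if f not in log_expr.index]
    if missing:
        raise KeyError(f"signature families absent from expression matrix: {missing}")
    sub = log_expr.loc[signature.families, population_ids]
    mu = sub.mean(axis=1)
    tau = sub.std(axis=1, ddof=1)
    dropped = tau.index[tau == 0]
    if len(dropped):
        logger.warning("compute_baseline: dropping %d zero-variance families: %s",
                       len(dropped), ", ".join(map(str, dropped[:5])))
    keep = tau > 0
    directions = signature.directions
    baseline = pd.DataFrame({
        "mu": mu[keep], "tau": tau[keep],
        "direction": [directions[f] for f in mu.index[keep]],
    })
    baseline.index.name = "family"
    baseline.attrs["population_n"] = len(population_ids)
    return baseline


def risk_scores(log_expr: pd.DataFrame, baseline: pd.DataFrame) -> pd.Series:
    """Signed z-sum risk score for every sample (column) of ``log_expr``."""
    missing = [f for f in baseline.index if f not in log_expr.index]
    if missing:
        raise KeyError(f"expression matrix lacks signature families: {missing}")
    e = log_expr.loc[baseline.index]
    sign = baseline["direction"].map({"up": 1.0, "down": -1.0})
    z = e.sub(baseline["mu"], axis=0).div(baseline["tau"], axis=0).mul(sign, axis=0)
    return z.sum(axis=0).rename("risk_score")


def risk_score(sample_log_expr: pd.Series, baseline: pd.DataFrame) -> float:
    """Risk score of a single sample."""
    return float(risk_scores(sample_log_expr.to_frame(), baseline).iloc[0])


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC as the concordant-pair fraction (ties counted 1/2) and the ROC
    points at every distinct threshold.

    ``labels``: boolean/0-1, True = case.  Cases are expected to score higher;
    no orientation flip is applied, so AUC < 0.5 is possible.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    tps = np.cumsum(labels[order])
    fps = np.cumsum(~labels[order])
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    points = pd.DataFrame({
        "threshold": np.r_[np.inf, sorted_scores[distinct]],
        "tpr": np.r_[0.0, tps[distinct] / n_pos],
        "fpr": np.r_[0.0, fps[distinct] / n_neg],
    })
    return float(auc), points


# ---------------------------------------------------------------------------
# DeLong test for two correlated AUCs

@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p: float


def _placements(cases: np.ndarray, controls: np.ndarray
                ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus case- and control-side placement values (the V10/V01 of the
    DeLong construction)."""
    cmp = (cases[:, None] > controls[None, :]).astype(float)
    cmp += 0.5 * (cases[:, None] == controls[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return float(cmp.mean()), v10, v01


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong comparison of two AUCs computed on the same samples."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must share one shape")
    auc_a, v10_a, v01_a = _placements(scores_a[labels], scores_a[~labels])
    auc_b, v10_b, v01_b = _placements(scores_b[labels], scores_b[~labels])
    m, n = int(labels.sum()), int((~labels).sum())
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(d01, ddof=1) / n if n > 1 else 0.0)
    delta = auc_a - auc_b
    if var <= 0:
        if delta != 0:
            logger.warning("delong_test: zero variance with nonzero delta-AUC")
        return DeLongResult(auc_a, auc_b, delta, 0.0, 1.0)
    z = delta / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, delta, float(z), p)


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVReport:
    """Round-level mean AUCs and family prioritization frequencies."""

    round_auc_uc: np.ndarray
    round_auc_cd: np.ndarray
    prioritization: pd.Series      # family -> times selected (over rounds x folds)
    k: int
    rounds: int
    seed: int
    n_empty_folds: int = 0

    def median_auc(self) -> tuple[float, float]:
        def _med(v):
            v = v[~np.isnan(v)]
            return float(np.median(v)) if len(v) else float("nan")
        return _med(self.round_auc_uc), _med(self.round_auc_cd)

    def to_dict(self) -> dict:
        med_uc, med_cd = self.median_auc()
        return {
            "k": self.k, "rounds": self.rounds, "seed": self.seed,
            "median_auc_hc_uc": med_uc, "median_auc_hc_cd": med_cd,
            "round_auc_hc_uc": [None if np.isnan(v) else float(v)
                                for v in self.round_auc_uc],
            "round_auc_hc_cd": [None if np.isnan(v) else float(v)
                                for v in self.round_auc_cd],
            "n_empty_folds": self.n_empty_folds,
            "prioritization": {str(k): int(v)
                               for k, v in self.prioritization.items() if v > 0},
        }


def stratified_folds(metadata: pd.DataFrame, k: int,
                     rng: np.random.Generator,
                     groups=("HC", "UC", "CD")) -> pd.Series:
    """Random fold assignment stratified by group.

    Within each group the samples are shuffled and dealt into k folds; the
    remainder (n mod k) goes one sample per fold, lowest fold index first, so
    fold sizes are deterministic given the draw.
    """
    assignment = pd.Series(-1, index=metadata.index, dtype=int)
    for g in groups:
        ids = metadata.index[metadata["group"] == g].to_numpy()
        if len(ids) < k:
            raise ValueError(f"group {g}: needs >= {k} samples for {k}-fold CV")
        perm = rng.permutation(len(ids))
        sizes = np.full(k, len(ids) // k)
        sizes[: len(ids) % k] += 1
        stops = np.cumsum(sizes)
        starts = np.r_[0, stops[:-1]]
        for fold, (a, b) in enumerate(zip(starts, stops)):
            assignment[ids[perm[a:b]]] = fold
    return assignment[assignment >= 0]


def _fold_auc(log_expr: pd.DataFrame, meta_val: pd.DataFrame,
              baseline: pd.DataFrame, contrast_case: str) -> float:
    mask = meta_val["group"].isin(["HC", contrast_case])
    meta = meta_val[mask]
    if (meta["group"] == "HC").sum() == 0 or (meta["group"] == contrast_case).sum() == 0:
        return np.nan
    scores = risk_scores(log_expr[meta.index], baseline)
    auc, _ = roc_auc(scores.to_numpy(), (meta["group"] == contrast_case).to_numpy())
    return auc


def cross_validate(family_rpm: pd.DataFrame, metadata: pd.DataFrame,
                   k: int = 5, rounds: int = 1000, alpha: float = 0.05,
                   seed: int = 0, baseline_population: str = "train",
                   direction: str | None = None,
                   empty_signature: str = "exclude",
                   log_transform_fit: bool = False) -> CVReport:
    """Repeated stratified k-fold cross-validation of the z-sum classifier.

    Per fold, the full signature-derivation procedure (per-contrast OLS with
    age/sex adjustment, Bonferroni, common-dysregulation intersection) is
    re-run on the training folds; mu/tau come from the training samples
    (``baseline_population="train"``, the leakage-free choice) or from the full
    cohort (``"full"``, mirroring a fixed population convention); held-out
    samples are scored and HC-vs-UC / HC-vs-CD AUCs computed.

    Folds whose training signature is empty contribute no AUC by default
    (``empty_signature="exclude"``, logged).  With ``empty_signature="chance"``
    an empty signature is treated as the uninformative classifier it is — the
    constant zero score, whose all-ties AUC is exactly 0.5 — which keeps the
    round means defined on data without true signal.
    """
    if baseline_population not in ("train", "full"):
        raise ValueError("baseline_population must be 'train' or 'full'")
    if empty_signature not in ("exclude", "chance"):
        raise ValueError("empty_signature must be 'exclude' or 'chance'")
    meta = metadata[metadata["group"].isin(["HC", "UC", "CD"])]
    rpm = family_rpm[meta.index]
    log_expr = log_expression(rpm)
    rng = np.random.default_rng(seed)
    round_uc = np.full(rounds, np.nan)
    round_cd = np.full(rounds, np.nan)
    freq = pd.Series(0, index=family_rpm.index, dtype=int)
    n_empty = 0
    for rnd in range(rounds):
        folds = stratified_folds(meta, k, rng)
        fold_uc, fold_cd = [], []
        for fold in range(k):
            train_ids = folds.index[folds != fold]
            val_ids = folds.index[folds == fold]
            meta_train = meta.loc[train_ids]
            try:
                tab_uc = fit_all_families(rpm, meta_train, ("HC", "UC"),
                                          log_transform=log_transform_fit)
                tab_cd = fit_all_families(rpm, meta_train, ("HC", "CD"),
                                          log_transform=log_transform_fit)
            except ValueError as exc:
                # e.g. a single-sex training split; no classifier can be trained
                logger.warning("round %d fold %d: %s", rnd, fold, exc)
                n_empty += 1
                if empty_signature == "chance":
                    fold_uc.append(0.5)
                    fold_cd.append(0.5)
                continue
            signature = derive_signature(tab_uc, tab_cd, alpha=alpha,
                                         direction=direction)
            if len(signature) == 0:
                n_empty += 1
                logger.info("round %d fold %d: empty training signature", rnd, fold)
                if empty_signature == "chance":
                    fold_uc.append(0.5)
                    fold_cd.append(0.5)
                continue
            freq[signature.families] += 1
            pop_ids = train_ids if baseline_population == "train" else meta.index
            baseline = compute_baseline(log_expr, pop_ids, signature)
            if baseline.empty:
                n_empty += 1
                continue
            fold_uc.append(_fold_auc(log_expr, meta.loc[val_ids], baseline, "UC"))
            fold_cd.append(_fold_auc(log_expr, meta.loc[val_ids], baseline, "CD"))
        if fold_uc:
            round_uc[rnd] = np.nanmean(fold_uc)
        if fold_cd:
            round_cd[rnd] = np.nanmean(fold_cd)
    return CVReport(round_auc_uc=round_uc, round_auc_cd=round_cd,
                    prioritization=freq, k=k, rounds=rounds, seed=seed,
                    n_empty_folds=n_empty)
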