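"""Descriptive landscape of noncanonical small RNAs.

Class-total group comparisons and cross-class correlations, read-length
distributions, parental-RNA cleavage-position profiles, PCA over sncRNA
categories, and UC-vs-CD fold-change concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = (("HC", "SC"), ("HC", "UC"), ("HC", "CD"))
CLASS_PAIRS = (("tsRNA", "rsRNA"), ("tsRNA", "ysRNA"), ("rsRNA", "ysRNA"))


def _group_values(values: pd.Series, metadata: pd.DataFrame, group: str) -> np.ndarray:
    ids = metadata.index[metadata["group"] == group]
    if len(ids) == 0:
        raise ValueError(f"group {group!r} absent from metadata")
    return values.loc[ids].to_numpy(dtype=float)


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test; (t, P)=(0, 1) for two
    identical constant samples."""
    if np.ptp(x) == 0 and np.ptp(y) == 0 and len(x) and len(y) and x[0] == y[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def class_total_tests(class_totals: pd.DataFrame, metadata: pd.DataFrame,
                      contrasts=DEFAULT_CONTRASTS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Welch t-tests of per-class total RPM for each contrast, plus pairwise
    Spearman correlations between the noncanonical class totals.

    ``class_totals``: classes x samples.  Spearman is computed on raw totals
    (rank-invariant to the log axes used for display).
    """
    for g in {g for c in contrasts for g in c}:
        if not (metadata["group"] == g).any():
            raise ValueError(f"group {g!r} absent from metadata")
    t_rows = []
    for cls in class_totals.index:
        vals = class_totals.loc[cls]
        for ga, gb in contrasts:
            t, p = welch_t(_group_values(vals, metadata, ga),
                           _group_values(vals, metadata, gb))
            t_rows.append({"class": cls, "contrast": f"{ga}_vs_{gb}",
                           "t": t, "p": p})
    rho_rows = []
    for a, b in CLASS_PAIRS:
        if a in class_totals.index and b in class_totals.index:
            rho, p = stats.spearmanr(class_totals.loc[a], class_totals.loc[b])
            rho_rows.append({"class_a": a, "class_b": b,
                             "rho": float(rho), "p": float(p)})
    return pd.DataFrame(t_rows), pd.DataFrame(rho_rows)


# ---------------------------------------------------------------------------
# length distributions

def length_histograms(species_table: pd.DataFrame, denominators: pd.Series,
                      min_length: int = 15, max_length: int = 45) -> dict:
    """Per-class, per-sample RPM mass at each read length.

    Returns ``{class: DataFrame lengths x samples}``; bin sums per sample equal
    the class total RPM.
    """
    samples = denominators.index
    lengths = np.arange(min_length, max_length + 1)
    out = {}
    annotated = species_table[species_table["class"] != "unannotated"]
    from .cohort import class_of_family
    classes = annotated["family"].map(class_of_family)
    for cls in ("tsRNA", "rsRNA", "ysRNA", "miRNA"):
        sub = annotated[classes == cls]
        hist = pd.DataFrame(0.0, index=pd.Index(lengths, name="length"), columns=samples)
        if len(sub):
            for s in samples:
                rpm = sub[f"count:{s}"] * 1e6 / denominators[s]
                hist[s] = rpm.groupby(sub["length"]).sum().reindex(lengths, fill_value=0.0)
        out[cls] = hist
    return out


def length_distribution(species_table: pd.DataFrame, denominators: pd.Series,
                        metadata: pd.DataFrame,
                        min_length: int = 15, max_length: int = 45) -> pd.DataFrame:
    """Group mean and normal-approximation 95% CI of the per-length RPM mass.

    Tidy output: ``class, group, length, mean, ci_low, ci_high``.
    """
    hists = length_histograms(species_table, denominators, min_length, max_length)
    rows = []
    for cls, hist in hists.items():
        for g in metadata["group"].unique():
            ids = metadata.index[metadata["group"] == g]
            sub = hist[ids]
            mean = sub.mean(axis=1)
            sem = sub.std(axis=1, ddof=1) / np.sqrt(len(ids))
            for ln in hist.index:
                rows.append({"class": cls, "group": g, "length": int(ln),
                             "mean": float(mean[ln]),
                             "ci_low": float(mean[ln] - 1.96 * sem[ln]),
                             "ci_high": float(mean[ln] + 1.96 * sem[ln])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cleavage profiles

@dataclass
class CleavageProfile:
    parent_id: str
    length: int
    mean: dict           # group -> vector of per-position mean RPM coverage
    sem: dict            # group -> vector of per-position SEM
    contributing_species: int


def per_sample_coverage(species_table: pd.DataFrame, denominators: pd.Series,
                        parent_id: str, parent_length: int) -> pd.DataFrame:
    """Positions x samples coverage: each species adds its RPM over every
    matched locus on this parent."""
    samples = denominators.index
    cov = np.zeros((parent_length, len(samples)))
    count_cols = [f"count:{s}" for s in samples]
    n_contrib = 0
    for _, row in species_table.iterrows():
        loci = [l for l in row["loci"] if l[0] == parent_id]
        if not loci:
            continue
        n_contrib += 1
        rpm = row[count_cols].to_numpy(dtype=float) * 1e6 / denominators.to_numpy()
        for _, start, end in loci:
            cov[start:end, :] += rpm
    df = pd.DataFrame(cov, index=pd.RangeIndex(parent_length, name="position"),
                      columns=samples)
    df.attrs["contributing_species"] = n_contrib
    return df


def cleavage_profile(species_table: pd.DataFrame, refs, denominators: pd.Series,
                     metadata: pd.DataFrame, family_label: str) -> dict:
    """Group mean/SEM coverage per parent of the given family.

    SEM uses the n-1 standard deviation.  A family with no annotated species
    yields all-zero profiles (with a warning).
    """
    parents = [r for r in refs if r.family_label == family_label]
    if not parents:
        raise ValueError(f"family {family_label!r} not present in references")
    fam_species = species_table[species_table["family"] == family_label]
    if fam_species.empty:
        logger.warning("cleavage_profile: family %s has zero annotated species",
                       family_label)
    profiles = {}
    for parent in parents:
        cov = per_sample_coverage(fam_species, denominators, parent.parent_id,
                                  len(parent.sequence))
        mean, sem = {}, {}
        for g in metadata["group"].unique():
            ids = metadata.index[metadata["group"] == g]
            sub = cov[ids]
            mean[g] = sub.mean(axis=1).to_numpy()
            sem[g] = (sub.std(axis=1, ddof=1) / np.sqrt(len(ids))).to_numpy()
        profiles[parent.parent_id] = CleavageProfile(
            parent_id=parent.parent_id, length=len(parent.sequence),
            mean=mean, sem=sem,
            contributing_species=cov.attrs["contributing_species"])
    return profiles


def profiles_to_frame(profiles: dict) -> pd.DataFrame:
    """BedGraph-like tidy table: parent_id, start, end, group, mean, sem."""
    rows = []
    for pid, prof in profiles.items():
        for g in prof.mean:
            for pos in range(prof.length):
                rows.append({"parent_id": pid, "start": pos, "end": pos + 1,
                             "group": g, "mean": prof.mean[g][pos],
                             "sem": prof.sem[g][pos]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA over categories

@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # categories x components
    explained_variance: np.ndarray


def pca_categories(category_rpm: pd.DataFrame, metadata: pd.DataFrame,
                   contrasts=DEFAULT_CONTRASTS) -> tuple[PCAResult, pd.DataFrame]:
    """PCA of the samples x categories matrix (columns centered and scaled to
    unit variance, then SVD), plus Welch t-tests on PC1 per contrast.

    ``category_rpm``: categories x samples (transposed internally).
    """
    X = category_rpm.T
    if X.shape[0] < 3:
        raise ValueError("PCA requires at least 3 samples")
    sd = X.std(axis=0, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        logger.warning("pca_categories: dropping %d constant categories", len(constant))
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    if X.shape[1] < 2:
        raise ValueError("PCA requires at least 2 non-constant categories")
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    k = len(s)
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U * s, index=X.index, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comps)
    explained = s ** 2 / (s ** 2).sum()
    result = PCAResult(scores=scores, loadings=loadings, explained_variance=explained)

    rows = []
    for ga, gb in contrasts:
        ia = metadata.index[metadata["group"] == ga].intersection(scores.index)
        ib = metadata.index[metadata["group"] == gb].intersection(scores.index)
        if len(ia) < 2 or len(ib) < 2:
            continue
        t, p = welch_t(scores.loc[ia, "PC1"].to_numpy(),
                       scores.loc[ib, "PC1"].to_numpy())
        rows.append({"contrast": f"{ga}_vs_{gb}", "t": t, "p": p})
    return result, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fold-change concordance

def fold_change_concordance(family_rpm: pd.DataFrame, metadata: pd.DataFrame,
                            eps: float = 0.01,
                            groups=("UC", "CD"), reference: str = "HC"
                            ) -> tuple[pd.DataFrame, float, float]:
    """Per-family log2 fold change of each case group against the reference and
    their Spearman concordance.

    FC = (mean_group + eps) / (mean_reference + eps); families with zero mean
    in all groups are excluded.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    means = {}
    for g in (reference, *groups):
        ids = metadata.index[metadata["group"] == g]
        if len(ids) == 0:
            raise ValueError(f"group {g!r} absent from metadata")
        means[g] = family_rpm[ids].mean(axis=1)
    all_zero = sum(means.values()) == 0
    keep = ~all_zero
    table = pd.DataFrame(index=family_rpm.index[keep])
    for g in groups:
        table[f"log2fc_{g}"] = np.log2(
            (means[g][keep] + eps) / (means[reference][keep] + eps))
    rho, p = stats.spearmanr(table[f"log2fc_{groups[0]}"],
                             table[f"log2fc_{groups[1]}"])
    return table, float(rho), float(p)
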