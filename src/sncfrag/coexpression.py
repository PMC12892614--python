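"""sncRNA–gene co-expression, gene-set enrichment and per-sample pathway
scores.

Pairwise Spearman correlations between small-RNA families (log2(RPM+1)) and
genes are BH-adjusted over all tested pairs jointly; genes co-expressed with
at least ``min_families`` families (default 20) in a consistent direction form
the positively/negatively co-expressed gene sets; enrichment of a gene list in
user-supplied GMT sets is tested with a one-sided hypergeometric test; and a
rank-based single-sample pathway score (exponential weighting of the most
highly expressed genes) summarises each gene set per sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .landscape import welch_t

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Spearman pair table

def spearman_pair_table(family_log_expr: pd.DataFrame,
                        gene_expr: pd.DataFrame) -> pd.DataFrame:
    """All family x gene Spearman correlations with BH adjustment.

    Rank correlation with average ranks for ties; P from the t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2 df (P = 0 at |rho| = 1).
    Constant families or genes are skipped with a log message.  BH is applied
    across all retained pairs jointly.
    """
    samples = family_log_expr.columns.intersection(gene_expr.columns)
    n = len(samples)
    if n < 5:
        raise ValueError(f"need >= 5 shared samples, got {n}")
    F = family_log_expr[samples].to_numpy(dtype=float)
    G = gene_expr[samples].to_numpy(dtype=float)

    def _rank_z(M, names, what):
        R = np.apply_along_axis(stats.rankdata, 1, M)
        sd = R.std(axis=1, ddof=1)
        keep = sd > 0
        if (~keep).any():
            logger.info("spearman_pair_table: skipping %d constant %s",
                        int((~keep).sum()), what)
        Z = (R[keep] - R[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
        return Z, np.asarray(names)[keep]

    Zf, fams = _rank_z(F, family_log_expr.index, "families")
    Zg, genes = _rank_z(G, gene_expr.index, "genes")
    rho = (Zf @ Zg.T) / (n - 1)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2 * stats.t.sf(np.abs(t), n - 2))

    table = pd.DataFrame({
        "family": np.repeat(fams, len(genes)),
        "gene": np.tile(genes, len(fams)),
        "rho": rho.ravel(),
        "p": p.ravel(),
    })
    table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def select_coexpressed_genes(table: pd.DataFrame, alpha: float = 0.05,
                             min_families: int = 20
                             ) -> tuple[set, set, pd.DataFrame]:
    """Genes significantly co-expressed (BH-adjusted P < alpha) with at least
    ``min_families`` families, split by correlation sign.

    A gene appearing in both sets (each count met separately) is flagged.
    Returns (positive set, negative set, per-gene count table).
    """
    sig = table[table["p_bh"] < alpha]
    pos_counts = sig[sig["rho"] > 0].groupby("gene").size()
    neg_counts = sig[sig["rho"] < 0].groupby("gene").size()
    positive = set(pos_counts.index[pos_counts >= min_families])
    negative = set(neg_counts.index[neg_counts >= min_families])
    both = positive & negative
    if both:
        logger.warning("select_coexpressed_genes: %d genes meet both directions",
                       len(both))
    counts = pd.DataFrame({"n_positive": pos_counts, "n_negative": neg_counts}
                          ).fillna(0).astype(int)
    counts["in_both"] = counts.index.isin(both)
    return positive, negative, counts


# ---------------------------------------------------------------------------
# hypergeometric enrichment

def hypergeometric_enrichment(gene_list, gene_sets: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric (upper-tail) enrichment of ``gene_list`` in
    each gene set, BH-adjusted across sets.

    Sets are intersected with the universe; sets disjoint from it are skipped
    with a warning.  The gene list must be contained in the universe.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if not universe:
        raise ValueError("empty universe")
    if not gene_list:
        raise ValueError("empty gene list")
    outside = gene_list - universe
    if outside:
        raise ValueError(
            f"{len(outside)} genes of the list are outside the universe, "
            f"e.g. {sorted(outside)[:3]}")
    N, n = len(universe), len(gene_list)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            logger.warning("hypergeometric_enrichment: set %s disjoint from "
                           "universe, skipped", name)
            continue
        K = len(members)
        overlap = len(members & gene_list)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
        rows.append({"set": name, "overlap": overlap, "set_size": K,
                     "list_size": n, "universe_size": N, "p": p})
    result = pd.DataFrame(rows)
    if len(result):
        result["p_bh"] = multipletests(result["p"], method="fdr_bh")[1]
    return result


# ---------------------------------------------------------------------------
# rank-based per-sample pathway score

def faime_scores(gene_expr: pd.DataFrame, gene_sets: dict) -> pd.DataFrame:
    """Rank-based single-sample pathway scores.

    Per sample, genes are ranked by expression descending (average ranks for
    ties, rank 1 = highest) and weighted ``w_g = exp(-rank_g / (0.1 N))``; a
    set's score is ``mean(w in set) - mean(w in complement)``.  Higher scores
    mean overall upregulation of the set.  Sets with fewer than 2 usable genes
    in the set or in the complement are skipped.
    """
    genes = gene_expr.index
    N = len(genes)
    ranks = np.apply_along_axis(stats.rankdata, 0, -gene_expr.to_numpy(dtype=float))
    weights = np.exp(-ranks / (0.1 * N))
    rows, names = [], []
    for name, members in gene_sets.items():
        mask = np.asarray(genes.isin(set(members)))
        if mask.sum() < 2 or (~mask).sum() < 2:
            logger.warning("faime_scores: set %s has < 2 usable genes in set or "
                           "complement, skipped", name)
            continue
        rows.append(weights[mask].mean(axis=0) - weights[~mask].mean(axis=0))
        names.append(name)
    return pd.DataFrame(rows, index=pd.Index(names, name="set"),
                        columns=gene_expr.columns)


def pathway_group_comparison(scores: pd.DataFrame, metadata: pd.DataFrame,
                             contrasts=(("HC", "SC"), ("HC", "UC"), ("HC", "CD"))
                             ) -> pd.DataFrame:
    """Welch t-tests of pathway scores per set and contrast (positive t means
    higher in the case group)."""
    rows = []
    for ga, gb in contrasts:
        ia = metadata.index[metadata["group"] == ga].intersection(scores.columns)
        ib = metadata.index[metadata["group"] == gb].intersection(scores.columns)
        if len(ia) < 2 or len(ib) < 2:
            raise ValueError(f"contrast {ga} vs {gb}: each group needs >= 2 samples")
        for s in scores.index:
            t, p = welch_t(scores.loc[s, ib].to_numpy(), scores.loc[s, ia].to_numpy())
            rows.append({"set": s, "contrast": f"{ga}_vs_{gb}", "t": t, "p": p})
    return pd.DataFrame(rows)
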