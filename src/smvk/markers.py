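"""Cluster marker statistics and triple-positive panel selection.

The panel procedure mirrors how the STMN1/HMGN2/GPC3 panel was built:

1. rank genes by log2 fold change for the positive clusters versus the
   negative clusters, keep the top-n and among those the genes detected
   in >80% of positive-cluster units (pct.1 > 0.8);
2. take the survivor maximising pct.1 - pct.2 (detection specificity)
   as the seed marker;
3. pick the companion as the survivor whose expression correlates most
   strongly (Pearson) with the seed across an external bulk reference;
4. append an a-priori tumor-specificity marker.

Signature scoring follows the module-score convention: the mean
normalized expression of the gene set minus the mean of
expression-matched control genes drawn from equal-frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "lognorm_cp10k",
    "compute_marker_stats",
    "PanelSelection",
    "select_panel",
    "module_score",
    "jaccard_overlap",
    "upregulated_genes",
]

_EPS = 1e-9


def lognorm_cp10k(counts: np.ndarray) -> np.ndarray:
    """log1p counts-per-10k normalization (genes x units)."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * 1e4)


def compute_marker_stats(counts: np.ndarray, gene_ids, group_a, group_b,
                         norm: str = "lognorm_cp10k") -> pd.DataFrame:
    """Per-gene marker statistics for units in ``group_a`` vs ``group_b``.

    Returns a frame with columns gene, log2fc, pct1, pct2, p, q where
    log2fc compares mean normalized expression (with a 1e-9 floor), pct
    columns are detection fractions from raw counts, p is a two-sided
    Wilcoxon rank-sum on normalized values and q is Benjamini-Hochberg
    within this comparison.
    """
    if norm != "lognorm_cp10k":
        raise ValueError("only lognorm_cp10k normalization is supported")
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if len(set(group_a) & set(group_b)):
        raise ValueError("groups overlap")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 units")
    X = lognorm_cp10k(counts)
    A, B = X[:, group_a], X[:, group_b]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    log2fc = np.log2((mean_a + _EPS) / (mean_b + _EPS))
    raw = np.asarray(counts)
    pct1 = (raw[:, group_a] > 0).mean(axis=1)
    pct2 = (raw[:, group_b] > 0).mean(axis=1)
    res = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided", method="auto")
    p = np.atleast_1d(res.pvalue).astype(float)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"gene": np.asarray(gene_ids, dtype=object), "log2fc": log2fc,
         "pct1": pct1, "pct2": pct2, "p": p, "q": q}
    )


@dataclass
class PanelSelection:
    seed_gene: str
    companion_gene: str
    apriori_gene: str
    audit: dict = field(default_factory=dict)

    @property
    def genes(self):
        return (self.seed_gene, self.companion_gene, self.apriori_gene)


def select_panel(stats_df: pd.DataFrame, reference_bulk: pd.DataFrame,
                 apriori_gene: str, *, top_n: int = 30,
                 pct1_min: float = 0.8) -> PanelSelection:
    """Four-step marker panel selection (see module docstring).

    ``stats_df`` must hold one row per gene for the positive-vs-negative
    cluster comparison; ``reference_bulk`` is genes x samples. Ties in
    specificity break by larger log2fc then lexicographic gene id. The
    audit records every step's candidate set.
    """
    if apriori_gene not in set(stats_df["gene"]):
        raise ValueError(f"a-priori gene {apriori_gene!r} absent from stats")
    df = stats_df.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    top = df.head(top_n)
    survivors = top[top["pct1"] > pct1_min].copy()
    if len(survivors) == 0:
        raise ValueError("no specific marker: no top gene passes the pct.1 filter")
    audit = {
        "step1_top_by_log2fc": top["gene"].tolist(),
        "step1_survivors": survivors["gene"].tolist(),
    }
    survivors["specificity"] = survivors["pct1"] - survivors["pct2"]
    ranked = survivors.sort_values(
        ["specificity", "log2fc", "gene"], ascending=[False, False, True], kind="mergesort"
    )
    seed = str(ranked.iloc[0]["gene"])
    audit["step2_specificity"] = {str(g): float(s) for g, s in
                                  zip(ranked["gene"], ranked["specificity"])}
    audit["step2_seed"] = seed

    others = [g for g in survivors["gene"] if g != seed]
    if not others:
        raise ValueError("no specific marker: survivor set has a single gene")
    if seed not in reference_bulk.index:
        raise ValueError(f"reference bulk lacks seed gene {seed!r}")
    seed_expr = reference_bulk.loc[seed].to_numpy(float)
    corrs = {}
    for g in others:
        if g not in reference_bulk.index:
            continue
        r = stats.pearsonr(seed_expr, reference_bulk.loc[g].to_numpy(float)).statistic
        corrs[str(g)] = float(r)
    if not corrs:
        raise ValueError("reference bulk lacks all candidate companion genes")
    companion = sorted(corrs, key=lambda g: (-corrs[g], g))[0]
    audit["step3_reference_correlation"] = corrs
    audit["step3_companion"] = companion
    audit["step4_apriori"] = apriori_gene
    if len({seed, companion, apriori_gene}) != 3:
        raise ValueError("panel genes are not distinct")
    return PanelSelection(seed_gene=seed, companion_gene=companion,
                          apriori_gene=apriori_gene, audit=audit)


def module_score(counts: np.ndarray, gene_ids, gene_set, rng,
                 *, nbins: int = 24, nctrl: int = 100) -> np.ndarray:
    """Per-unit signature score of ``gene_set`` against matched controls.

    Genes are binned into ``nbins`` equal-frequency bins by mean
    normalized expression; each set gene contributes ``nctrl`` control
    genes from its bin (the whole bin when it holds fewer than nctrl).
    Score = mean normalized expression over the set minus the mean over
    the pooled controls.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    gene_set = list(gene_set)
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    missing = set(gene_set) - set(gene_ids)
    if missing:
        raise ValueError(f"genes not in matrix: {sorted(missing)}")
    X = lognorm_cp10k(counts)
    idx = {g: i for i, g in enumerate(gene_ids)}
    means = X.mean(axis=1)
    # equal-frequency binning with stable order for reproducibility
    order = np.lexsort((gene_ids.astype(str), means))
    bins = np.array_split(order, min(nbins, len(order)))
    bin_of = np.empty(len(gene_ids), dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b
    ctrl_idx = []
    for g in gene_set:
        members = bins[bin_of[idx[g]]]
        if len(members) <= nctrl:
            ctrl_idx.extend(members.tolist())
        else:
            ctrl_idx.extend(rng.choice(members, size=nctrl, replace=False).tolist())
    set_mean = X[[idx[g] for g in gene_set]].mean(axis=0)
    ctrl_mean = X[np.asarray(ctrl_idx)].mean(axis=0)
    return set_mean - ctrl_mean


def jaccard_overlap(set_a, set_b) -> float:
    """|A n B| / |A u B|; undefined (error) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def upregulated_genes(stats_df: pd.DataFrame, lfc_min: float = 1.0,
                      q_max: float = 0.05, use_adjusted: bool = True) -> set:
    """Genes with log2fc > lfc_min and (adjusted) p below q_max."""
    if lfc_min <= 0 and not np.isinf(lfc_min):
        raise ValueError("lfc_min must be > 0")
    if q_max <= 0:
        raise ValueError("q_max must be > 0")
    col = "q" if use_adjusted else "p"
    keep = (stats_df["log2fc"] > lfc_min) & (stats_df[col] < q_max)
    return set(stats_df.loc[keep, "gene"])
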