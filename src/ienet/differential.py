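"""Conventional per-feature statistics: rank tests, FDR, enrichment,
alpha diversity and PCA ordination.

All group tests are nonparametric (Wilcoxon rank-sum between two groups,
Kruskal-Wallis across several), as is standard for small-n relative-abundance
data; multiple testing is controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from skbio.diversity import alpha as skbio_alpha
from skbio.stats.composition import clr, multi_replace
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceTable, GeneAnnotation, SampleDesign
from .exceptions import GroupError, MarkerError, NotClosedError

EXACT_MAX_N = 10  # exact rank-sum null up to this group size (no ties)


def _bh(pvalues: np.ndarray) -> np.ndarray:
    if len(pvalues) == 0:
        return np.asarray([])
    return multipletests(pvalues, method="fdr_bh")[1]


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p-value: exact for small tie-free groups, else
    normal approximation with tie correction."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_differential(
    table: AbundanceTable,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    fdr_alpha: float | None = None,
) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum test between two groups.

    Features are selected at ``p < alpha``; pass ``fdr_alpha`` to require
    the BH-adjusted value below a threshold as well.
    """
    sa = design.samples_in(group_a)
    sb = design.samples_in(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise GroupError("both groups need at least 2 samples")
    A = table.data[sa].to_numpy()
    B = table.data[sb].to_numpy()
    n_feat = A.shape[0]
    stats_ = np.empty(n_feat)
    pvals = np.empty(n_feat)
    # vectorized exact path for tie-free features at small group sizes
    combined = np.sort(np.concatenate([A, B], axis=1), axis=1)
    tie_free = ~(np.diff(combined, axis=1) == 0).any(axis=1)
    exact_ok = max(A.shape[1], B.shape[1]) <= EXACT_MAX_N
    fast = tie_free if exact_ok else np.zeros(n_feat, dtype=bool)
    if fast.any():
        res = stats.mannwhitneyu(
            A[fast], B[fast], alternative="two-sided", method="exact", axis=-1
        )
        stats_[fast] = res.statistic
        pvals[fast] = res.pvalue
    for i in np.flatnonzero(~fast):
        stats_[i], pvals[i] = _rank_sum_p(A[i], B[i])
    fdr = _bh(pvals)
    selected = pvals < alpha
    if fdr_alpha is not None:
        selected &= fdr < fdr_alpha
    return pd.DataFrame(
        {
            "feature": table.data.index,
            "comparison": f"{group_a}_vs_{group_b}",
            "statistic": stats_,
            "p_value": pvals,
            "fdr": fdr,
            "selected": selected,
        }
    ).reset_index(drop=True)


def kruskal_wallis_differential(
    table: AbundanceTable,
    design: SampleDesign,
    alpha: float = 0.05,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis test across all design groups.

    Selection requires both ``p < alpha`` and BH ``fdr < fdr_alpha``.
    """
    groups = design.group_labels
    if len(groups) < 2:
        raise GroupError("need at least 2 groups")
    cols = []
    for g in groups:
        s = design.samples_in(g)
        if len(s) < 2:
            raise GroupError(f"group {g!r} has fewer than 2 samples")
        cols.append(table.data[s].to_numpy())
    stats_, pvals = [], []
    for i in range(table.data.shape[0]):
        arrays = [c[i] for c in cols]
        if np.ptp(np.concatenate(arrays)) == 0:
            stats_.append(0.0)
            pvals.append(1.0)
            continue
        h, p = stats.kruskal(*arrays)
        stats_.append(float(h))
        pvals.append(float(p))
    pvals = np.asarray(pvals)
    fdr = _bh(pvals)
    return pd.DataFrame(
        {
            "feature": table.data.index,
            "comparison": "all_groups",
            "statistic": stats_,
            "p_value": pvals,
            "fdr": fdr,
            "selected": (pvals < alpha) & (fdr < fdr_alpha),
        }
    ).reset_index(drop=True)


def hypergeometric_enrichment(
    selected_ids,
    background_ids,
    category_map: dict,
    alpha: float = 0.05,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of categories in a selection.

    For a category of size K in a background of size N, with n selected ids
    and k of them in the category, p = P[X >= k] for X ~ Hypergeom(N, K, n).
    """
    background = set(background_ids)
    selected = set(selected_ids)
    if not selected <= background:
        extra = sorted(selected - background, key=str)[:5]
        raise MarkerError(f"selection not a subset of the background: {extra}")
    N, n = len(background), len(selected)
    rows = []
    for cat, members in sorted(category_map.items(), key=lambda kv: str(kv[0])):
        cat_bg = set(members) & background
        K = len(cat_bg)
        if K == 0:
            continue
        k = len(cat_bg & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "category": cat,
                "hits": k,
                "category_size": K,
                "selection_size": n,
                "background_size": N,
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "category",
            "hits",
            "category_size",
            "selection_size",
            "background_size",
            "p_value",
        ],
    )
    df["fdr"] = _bh(df["p_value"].to_numpy())
    df["enriched"] = (df["p_value"] < alpha) & (df["fdr"] < fdr_alpha)
    return df


def category_abundance_test(
    gene_table: pd.DataFrame,
    annotation: GeneAnnotation,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum comparison of per-sample functional-category abundances.

    A category's per-sample value is the sum of its member genes'
    abundances; categories with no member genes in the table are skipped.
    """
    members = annotation.category_members()
    values = {}
    for cat, genes in sorted(members.items(), key=lambda kv: str(kv[0])):
        present = [g for g in genes if g in gene_table.index]
        if not present:
            continue
        values[cat] = gene_table.loc[present].sum(axis=0)
    if not values:
        raise MarkerError("no categories with member genes present")
    cat_table = AbundanceTable(pd.DataFrame(values).T, rank="category", closed=False)
    return wilcoxon_differential(
        cat_table, design, group_a, group_b, alpha=alpha, fdr_alpha=fdr_alpha
    )


def alpha_diversity(table: AbundanceTable, index: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity on closed relative abundances.

    shannon: -sum p ln p (natural log); simpson: 1 - sum p^2;
    richness: number of taxa with nonzero abundance.
    """
    if index not in ("shannon", "simpson", "richness"):
        raise ValueError(f"unknown index {index!r}")
    if not table.closed:
        raise NotClosedError("alpha diversity requires closed columns")
    fns = {
        "shannon": lambda p: skbio_alpha.shannon(p, base=np.e),
        "simpson": skbio_alpha.simpson,
        "richness": skbio_alpha.sobs,
    }
    fn = fns[index]
    vals = {s: float(fn(table.data[s].to_numpy())) for s in table.sample_ids}
    return pd.Series(vals, name=index)


def pca_embed(
    table: AbundanceTable,
    n_components: int = 2,
    use_clr: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples in taxon space.

    Features are mean-centered across samples before decomposition (done by
    the PCA itself). By default raw relative abundances enter the PCA; with
    ``use_clr`` the centered-log-ratio transform (with multiplicative zero
    replacement) is applied first, the standard compositional treatment.
    Returns (scores indexed by sample, explained-variance fractions).
    """
    X = table.to_samples_matrix().to_numpy()
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for {X.shape[0]} samples"
        )
    if use_clr:
        X = clr(multi_replace(X))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=table.sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )
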