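"""Key-gene calling: multi-study expression meta-analysis of the core
genes by median-rank combination, leave-one-out stability, and
crucial-pathway intersection.

Per gene and study a two-sided Welch t-test compares tumour vs normal
log2 expression. Within each study the genes are ranked by p (1 =
smallest); the combination statistic is the median rank across studies,
and its combined p is the permutation tail probability of a median rank
this small under independent uniform ranks, with the add-one correction
p = (b + 1)/(n_perm + 1). A gene is *stable* when the combined p and
every leave-one-study-out combined p fall below alpha; key genes are the
stable genes. Crucial pathways are the pathways shared by every key gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionStudy
from .enrich import GeneSetCollection

__all__ = [
    "gene_study_pvals",
    "median_rank_meta",
    "GeneMetaRecord",
    "keygene_influence",
    "crucial_pathways",
]


def gene_study_pvals(studies: list[ExpressionStudy], genes) -> pd.DataFrame:
    """Two-sided Welch t p-values, shape genes x studies; genes missing
    from a study get NaN there."""
    genes = list(genes)
    cols = {}
    for st in studies:
        st = st.to_log2()
        present = [g for g in genes if g in st.values.index]
        t_vals = st.values.loc[present, st.tumor_samples].to_numpy(float)
        n_vals = st.values.loc[present, st.normal_samples].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(t_vals, n_vals, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        p[~np.isfinite(p)] = 1.0
        col = pd.Series(np.nan, index=genes)
        col[present] = p
        cols[st.study_id] = col
    return pd.DataFrame(cols)


def _median_rank_stats(per_study_p: pd.DataFrame) -> pd.Series:
    ranks = per_study_p.rank(axis=0, method="average")
    return ranks.median(axis=1, skipna=True)


def median_rank_meta(
    per_study_p: pd.DataFrame,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Combined p per gene from the median of within-study p ranks.

    The permutation null draws, per gene configuration (number of studies
    it appears in), ``n_perm`` vectors of independent uniform ranks on
    1..m and takes their median; the tail is counted with the add-one
    correction, so the smallest attainable p is 1/(n_perm + 1).
    """
    if per_study_p.shape[1] < 2:
        raise ValueError("median-rank combination needs >= 2 studies")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = per_study_p.shape[0]
    obs = _median_rank_stats(per_study_p)
    k_per_gene = per_study_p.notna().sum(axis=1)
    combined = pd.Series(np.nan, index=per_study_p.index)
    for k in sorted(k_per_gene.unique()):
        if k < 1:
            continue
        null = np.median(rng.integers(1, m + 1, size=(n_perm, int(k))), axis=1)
        null.sort()
        idx = k_per_gene == k
        b = np.searchsorted(null, obs[idx].to_numpy(), side="right")
        combined[idx] = (b + 1.0) / (n_perm + 1.0)
    return combined


@dataclass(frozen=True)
class GeneMetaRecord:
    gene: str
    per_study_p: tuple
    combined_p: float
    loo_p: tuple  # one combined p per omitted study, in study order
    stable: bool
    key: bool


def keygene_influence(
    studies: list[ExpressionStudy],
    genes,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> list[GeneMetaRecord]:
    """Median-rank meta-analysis with leave-one-study-out stability.

    A gene is stable (and, here, key) when its combined p and all
    leave-one-out combined p's are below ``alpha``.
    """
    if len(studies) < 3:
        raise ValueError("influence analysis needs >= 3 studies")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pmat = gene_study_pvals(studies, genes)
    full = median_rank_meta(pmat, n_perm, rng)
    loo = {
        st: median_rank_meta(pmat.drop(columns=st), n_perm, rng)
        for st in pmat.columns
    }
    records = []
    for gene in pmat.index:
        loo_p = tuple(float(loo[st][gene]) for st in pmat.columns)
        stable = full[gene] < alpha and all(p < alpha for p in loo_p)
        records.append(
            GeneMetaRecord(
                gene,
                tuple(float(x) for x in pmat.loc[gene]),
                float(full[gene]),
                loo_p,
                bool(stable),
                bool(stable),
            )
        )
    return records


def crucial_pathways(key_genes, membership: GeneSetCollection) -> set[str]:
    """Pathways that contain every key gene (intersection of per-gene
    pathway sets)."""
    key_genes = list(key_genes)
    if not key_genes:
        raise ValueError("no key genes given")
    sets = [membership.sets_of(g) for g in key_genes]
    out = set.intersection(*sets)
    if not out:
        warnings.warn("no pathway contains every key gene")
    return out
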