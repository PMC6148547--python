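"""Candidate-gene screening: differential expression, multi-database
target-vote filtering, DEG/target intersection, and the clinical
association battery.

The DEG rule is |log2FC| > 1 with BH FDR < 0.05. The per-gene test is
Welch's t on log2 values — a deliberately plain, pluggable choice: the
cascade's contribution is the thresholding logic, not variance
moderation. A predicted target must be voted by at least 5 of the 12
prediction databases. Candidates are the intersection of both screens.

The clinical battery mirrors the standard TCGA-style table: Kruskal–Wallis
for multi-class covariates, Wilcoxon rank-sum for binary ones, Spearman
for continuous ones, and a Cox proportional-hazards model (via lifelines)
for overall survival, with one BH FDR column across the whole battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionStudy

__all__ = [
    "de_test",
    "vote_filter",
    "intersect_candidates",
    "VennCounts",
    "clinical_assoc",
]


def de_test(
    study: ExpressionStudy,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test with BH FDR and the DEG selection rule.

    Returns a DataFrame indexed by gene with columns log2fc, p, fdr,
    direction ('up'/'down'/'none') and selected. Constant genes get p = 1
    with a warning rather than NaN.
    """
    study = study.to_log2()
    t_vals = study.values[study.tumor_samples].to_numpy(float)
    n_vals = study.values[study.normal_samples].to_numpy(float)
    log2fc = t_vals.mean(axis=1) - n_vals.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(t_vals, n_vals, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        warnings.warn(
            f"{study.study_id}: {int(degenerate.sum())} constant gene rows; p set to 1"
        )
        p[degenerate] = 1.0
    fdr = multipletests(p, method="fdr_bh")[1]
    selected = (np.abs(log2fc) > lfc_threshold) & (fdr < fdr_threshold)
    direction = np.where(
        selected & (log2fc > 0), "up", np.where(selected & (log2fc < 0), "down", "none")
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr, "direction": direction,
         "selected": selected},
        index=study.values.index,
    )


def vote_filter(votes: pd.DataFrame, min_db: int = 5) -> set[str]:
    """Genes predicted by at least ``min_db`` databases (boolean gene x
    database matrix)."""
    if min_db < 1:
        raise ValueError("min_db must be >= 1")
    counts = votes.astype(bool).sum(axis=1)
    return set(counts.index[counts >= min_db])


@dataclass(frozen=True)
class VennCounts:
    deg_only: int
    predicted_only: int
    both: int


def intersect_candidates(
    degs: pd.DataFrame, predicted: set[str]
) -> tuple[set[str], VennCounts]:
    """Selected DEGs ∩ predicted targets, with Venn counts."""
    selected = set(degs.index[degs["selected"]])
    both = selected & set(predicted)
    counts = VennCounts(len(selected - both), len(set(predicted) - both), len(both))
    if not both:
        warnings.warn("empty candidate set: no overlap between DEGs and predictions")
    return both, counts


# ---------------------------------------------------------------------------
# clinical association battery


def _infer_kind(col: pd.Series) -> str:
    if pd.api.types.is_numeric_dtype(col):
        nuniq = col.dropna().nunique()
        if nuniq <= 1:
            return "constant"
        if nuniq == 2:
            return "binary"
        if nuniq <= 6 and np.allclose(col.dropna() % 1, 0):
            return "multiclass"
        return "continuous"
    nuniq = col.dropna().nunique()
    if nuniq <= 1:
        return "constant"
    return "binary" if nuniq == 2 else "multiclass"


def clinical_assoc(
    marker_expression: pd.Series,
    clinical: pd.DataFrame,
    survival_time_col: str = "os_time",
    survival_event_col: str = "os_event",
    kinds: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Association battery between a marker's expression and clinical items.

    Item type decides the method: multiclass -> Kruskal–Wallis (statistic
    H), binary -> Wilcoxon rank-sum (statistic: rank-biserial correlation),
    continuous -> Spearman (statistic rho); the survival pair is tested
    with a univariate Cox model (statistic: coefficient, Wald p). Types
    are inferred from dtypes unless given in ``kinds``. One BH FDR column
    spans the battery; rows sorted by p.
    """
    expr = marker_expression.astype(float)
    clinical = clinical.loc[expr.index]
    rows = []
    surv_cols = {survival_time_col, survival_event_col}
    for item in clinical.columns:
        if item in surv_cols:
            continue
        col = clinical[item]
        kind = (kinds or {}).get(item) or _infer_kind(col)
        mask = col.notna()
        x, e = col[mask], expr[mask]
        if kind == "constant":
            warnings.warn(f"clinical item {item!r} has a single level; skipped")
            continue
        if kind == "multiclass":
            groups = [e[x == lv].to_numpy() for lv in x.unique()]
            stat, p = stats.kruskal(*groups)
            method = "kruskal_wallis"
        elif kind == "binary":
            lv = sorted(x.unique(), key=str)
            a, b = e[x == lv[0]].to_numpy(), e[x == lv[1]].to_numpy()
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat = 2.0 * u / (len(a) * len(b)) - 1.0  # rank-biserial correlation
            method = "wilcoxon"
        else:
            stat, p = stats.spearmanr(e.to_numpy(), x.to_numpy(float))
            method = "spearman"
        rows.append({"item": item, "method": method, "statistic": float(stat),
                     "p": float(p)})
    if surv_cols <= set(clinical.columns):
        from lifelines import CoxPHFitter

        df = pd.DataFrame(
            {"expr": expr, "T": clinical[survival_time_col],
             "E": clinical[survival_event_col]}
        ).dropna()
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        rows.append(
            {"item": "overall_survival", "method": "cox",
             "statistic": float(cph.params_["expr"]),
             "p": float(cph.summary.loc["expr", "p"])}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no testable clinical items")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p").reset_index(drop=True)
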