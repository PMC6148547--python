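"""Standardized-mean-difference meta-analysis of marker expression.

Pools per-study Hedges *g* effect sizes (tumour minus normal) across
case/control expression studies with inverse-variance fixed-effect and
DerSimonian–Laird random-effects models, and provides the usual battery
around the pooled estimate: Cochran Q / I² heterogeneity, automatic model
selection, Egger's regression test for funnel-plot asymmetry, leave-one-out
influence analysis, a fixed-vs-random sensitivity switch, and subgroup
pooling.

Conventions
-----------
* Effect sizes are Hedges g: Cohen d with the small-sample correction
  J = 1 - 3 / (4(n1 + n2 - 2) - 1).
* Confidence intervals use the normal multiplier 1.96 (not Student t).
* I² is reported on the percent scale, truncated at 0.
* Model selection follows the "random iff P_Q < 0.05 or I² > 50" rule,
  with strict inequalities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StudyEffect",
    "MetaResult",
    "EggerResult",
    "InfluenceResult",
    "log2_transform",
    "compute_smd",
    "pool_fixed",
    "pool_random",
    "heterogeneity",
    "select_model",
    "egger_test",
    "influence_loo",
    "sensitivity_switch",
    "subgroup_pool",
]

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class StudyEffect:
    """One study's standardized mean difference (tumour minus normal)."""

    study_id: str
    g: float
    var_g: float
    n_tumor: int = 2
    n_normal: int = 2
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.var_g <= 0:
            raise ValueError(f"var_g must be > 0, got {self.var_g}")
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("each arm needs at least 2 samples")

    @property
    def se(self) -> float:
        return math.sqrt(self.var_g)


@dataclass(frozen=True)
class MetaResult:
    """Pooled SMD with CI, heterogeneity and the model used."""

    pooled: float
    ci_low: float
    ci_high: float
    p: float
    Q: float
    df: int
    I2: float
    tau2: float
    model: str  # "fixed" | "random"

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se_intercept: float
    p: float

    @property
    def significant(self) -> bool:
        # funnel asymmetry called at the conventional 0.1 level
        return self.p < 0.1


@dataclass(frozen=True)
class InfluenceResult:
    omitted_study: str
    result: MetaResult
    flagged: bool


def log2_transform(matrix, offset: float = 1.0):
    """log2(x + offset) on a nonnegative array/DataFrame (raw -> log2 scale)."""
    arr = np.asarray(matrix, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log2_transform requires nonnegative input")
    if hasattr(matrix, "values") and hasattr(matrix, "index"):  # DataFrame
        return np.log2(matrix + offset)
    return np.log2(arr + offset)


def compute_smd(
    tumor_values,
    normal_values,
    study_id: str = "study",
    subgroup: str | None = None,
) -> StudyEffect:
    """Hedges g for two groups, with the large-sample variance formula.

    g = J * (mean_t - mean_n) / s_pooled,
    var_g = (n_t + n_n)/(n_t n_n) + g^2 / (2 (n_t + n_n)).
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    nt, nn = t.size, n.size
    if nt < 2 or nn < 2:
        raise ValueError("need at least 2 values per group")
    sp2 = ((nt - 1) * t.var(ddof=1) + (nn - 1) * n.var(ddof=1)) / (nt + nn - 2)
    if sp2 <= 0:
        raise ValueError("pooled SD is zero: SMD undefined for constant groups")
    d = (t.mean() - n.mean()) / math.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * (nt + nn - 2) - 1.0)
    g = J * d
    var_g = (nt + nn) / (nt * nn) + g * g / (2.0 * (nt + nn))
    return StudyEffect(study_id, g, var_g, nt, nn, subgroup)


def _ivw(effects: list[StudyEffect], tau2: float, model: str) -> MetaResult:
    g = np.array([e.g for e in effects])
    w = 1.0 / (np.array([e.var_g for e in effects]) + tau2)
    pooled = float(np.sum(w * g) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    Q, df, _, I2 = heterogeneity(effects) if len(effects) > 1 else (0.0, 0, 1.0, 0.0)
    return MetaResult(pooled, pooled - Z95 * se, pooled + Z95 * se, p, Q, df, I2, tau2, model)


def pool_fixed(effects: list[StudyEffect]) -> MetaResult:
    """Inverse-variance fixed-effect pooling (weights 1/var_i)."""
    if not effects:
        raise ValueError("no effects to pool")
    return _ivw(list(effects), 0.0, "fixed")


def pool_random(effects: list[StudyEffect]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) with fixed-model
    weights; the pooled estimate then re-weights by 1/(var_i + tau2).
    """
    effects = list(effects)
    if len(effects) < 2:
        raise ValueError("random-effects pooling needs >= 2 studies")
    var = np.array([e.var_g for e in effects])
    w = 1.0 / var
    Q, df, _, _ = heterogeneity(effects)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
    return _ivw(effects, tau2, "random")


def heterogeneity(effects: list[StudyEffect]) -> tuple[float, int, float, float]:
    """Cochran Q, its df and chi-square p, and I² (percent, truncated at 0)."""
    effects = list(effects)
    if len(effects) < 2:
        raise ValueError("heterogeneity needs >= 2 studies")
    g = np.array([e.g for e in effects])
    w = 1.0 / np.array([e.var_g for e in effects])
    pooled = np.sum(w * g) / np.sum(w)
    Q = float(np.sum(w * (g - pooled) ** 2))
    df = len(effects) - 1
    p_Q = float(stats.chi2.sf(Q, df))
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return Q, df, p_Q, I2


def select_model(p_Q: float, I2: float) -> str:
    """'random' iff P_Q < 0.05 or I² > 50 (strict), else 'fixed'."""
    return "random" if (p_Q < 0.05 or I2 > 50.0) else "fixed"


def pool_auto(effects: list[StudyEffect]) -> MetaResult:
    """Pool with the model chosen by the heterogeneity rule."""
    effects = list(effects)
    if len(effects) == 1:
        return pool_fixed(effects)
    _, _, p_Q, I2 = heterogeneity(effects)
    if select_model(p_Q, I2) == "random":
        return pool_random(effects)
    return pool_fixed(effects)


def egger_test(effects: list[StudyEffect]) -> EggerResult:
    """Egger's weighted regression test for funnel-plot asymmetry.

    Regresses the standardized effect g_i/SE_i on precision 1/SE_i; the
    intercept is tested against 0 with a t reference on k - 2 df.
    """
    effects = list(effects)
    k = len(effects)
    if k < 3:
        raise ValueError("Egger's test needs >= 3 studies")
    se = np.array([e.se for e in effects])
    y = np.array([e.g for e in effects]) / se
    x = 1.0 / se
    X = np.column_stack([np.ones(k), x])
    beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (k - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se_int = math.sqrt(cov[0, 0])
    tstat = beta[0] / se_int if se_int > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(tstat), k - 2))
    return EggerResult(float(beta[0]), se_int, p)


def influence_loo(effects: list[StudyEffect], model: str = "auto") -> list[InfluenceResult]:
    """Leave-one-out re-pooling with a change-of-conclusion flag.

    An omission is flagged when the full-analysis pooled estimate falls
    outside the leave-one-out CI, or when significance at 0.05 flips.
    """
    effects = list(effects)
    if len(effects) < 3:
        raise ValueError("influence analysis needs >= 3 studies")
    full = _pool_by(effects, model)
    out = []
    for i, e in enumerate(effects):
        rest = effects[:i] + effects[i + 1 :]
        r = _pool_by(rest, model)
        outside = not (r.ci_low <= full.pooled <= r.ci_high)
        flips = r.significant != full.significant
        out.append(InfluenceResult(e.study_id, r, outside or flips))
    return out


def _pool_by(effects: list[StudyEffect], model: str) -> MetaResult:
    if model == "fixed":
        return pool_fixed(effects)
    if model == "random":
        return pool_random(effects)
    return pool_auto(effects)


def sensitivity_switch(effects: list[StudyEffect]) -> tuple[MetaResult, MetaResult, bool]:
    """Fixed and random results side by side; consistent iff the two models
    agree on significance at 0.05 and on the sign of the pooled estimate."""
    effects = list(effects)
    if len(effects) < 2:
        raise ValueError("sensitivity analysis needs >= 2 studies")
    fx = pool_fixed(effects)
    rn = pool_random(effects)
    consistent = (fx.significant == rn.significant) and (
        np.sign(fx.pooled) == np.sign(rn.pooled)
    )
    return fx, rn, bool(consistent)


def subgroup_pool(
    effects: list[StudyEffect], labels: list[str] | None = None
) -> dict[str, MetaResult]:
    """Pool within each subgroup by the auto-selected model.

    Labels default to each effect's own ``subgroup`` field. A subgroup with
    one study passes through as a single-study fixed result with a warning.
    """
    effects = list(effects)
    if labels is None:
        labels = [e.subgroup for e in effects]
    if any(l is None for l in labels) or len(labels) != len(effects):
        raise ValueError("every effect must carry a subgroup label")
    out: dict[str, MetaResult] = {}
    for lab in dict.fromkeys(labels):  # preserve first-seen order
        sub = [e for e, l in zip(effects, labels) if l == lab]
        if len(sub) == 1:
            warnings.warn(f"subgroup {lab!r} has a single study; passthrough")
            out[lab] = pool_fixed(sub)
        else:
            out[lab] = pool_auto(sub)
    return out
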