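"""Inverse-variance meta-analysis: fixed-effect and DerSimonian-Laird pooling,
Cochran's Q heterogeneity, and Egger's small-study-bias regression.

All pooling operates on (value, standard error) pairs on an additive scale —
log odds ratios or mean differences.  Confidence intervals are plain Wald
intervals, value +/- 1.96*se (no Knapp-Hartung adjustment), matching the
convention of the classical meta-analysis software this engine mirrors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

Z95 = 1.96  # conventional 95% normal quantile, used for every interval


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with heterogeneity diagnostics.

    ``pooled`` is on the analysis scale given by ``scale`` ("log_or",
    "mean_difference" or "percent_change"); ``or_value``/``or_ci`` exponentiate
    only when the scale is log-OR.
    """

    pooled: float
    se_pooled: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    q_df: int
    p_q: float
    k: int
    n_cases: int = 0
    n_controls: int = 0
    scale: str = "log_or"

    def __post_init__(self) -> None:
        if self.se_pooled <= 0:
            raise ValueError("se_pooled must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if not self.ci_low <= self.pooled <= self.ci_high:
            raise ValueError("CI must bracket the pooled estimate")

    @property
    def i2(self) -> float:
        """I-squared heterogeneity (%) derived from Q; descriptive only."""
        if self.q_df <= 0 or self.q <= 0:
            return 0.0
        return max(0.0, 100.0 * (self.q - self.q_df) / self.q)

    @property
    def or_value(self) -> float:
        if self.scale != "log_or":
            raise ValueError(f"or_value undefined on scale '{self.scale}'")
        return math.exp(self.pooled)

    @property
    def or_ci(self) -> tuple[float, float]:
        if self.scale != "log_or":
            raise ValueError(f"or_ci undefined on scale '{self.scale}'")
        return math.exp(self.ci_low), math.exp(self.ci_high)

    @property
    def significant(self) -> bool:
        """95% CI excludes the null (0 on the additive scale)."""
        return self.ci_low > 0 or self.ci_high < 0


@dataclass(frozen=True)
class EggerResult:
    """Intercept of the Egger regression of standardized effect on precision."""

    intercept: float
    se_intercept: float
    p: float
    k: int

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")
        if self.se_intercept <= 0:
            raise ValueError("se_intercept must be positive")


def _as_arrays(effects: Sequence) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Extract (values, ses, pooled n_cases, pooled n_controls).

    Accepts EffectEstimate-like objects (``.log_or``/``.se`` or
    ``.value``/``.se``) or plain (value, se) pairs.
    """
    ys, ses, nca, nco = [], [], 0, 0
    for e in effects:
        if hasattr(e, "se"):
            ys.append(getattr(e, "log_or", None) if hasattr(e, "log_or") else e.value)
            ses.append(e.se)
            nca += getattr(e, "n_cases", 0) or 0
            nco += getattr(e, "n_controls", 0) or 0
        else:
            y, s = e
            ys.append(y)
            ses.append(s)
    y = np.asarray(ys, dtype=float)
    se = np.asarray(ses, dtype=float)
    if y.size == 0:
        raise ValueError("cannot pool an empty list of effects")
    if np.any(se <= 0) or not np.all(np.isfinite(y)) or not np.all(np.isfinite(se)):
        raise ValueError("all effects need finite values and positive standard errors")
    return y, se, nca, nco


def fixed_effect_pool(effects: Sequence, scale: str = "log_or") -> MetaResult:
    """Inverse-variance fixed-effect pooling: sum(w*y)/sum(w), w = 1/se^2."""
    y, se, nca, nco = _as_arrays(effects)
    w = 1.0 / se**2
    pooled = float(np.sum(w * y) / np.sum(w))
    se_pooled = float(1.0 / math.sqrt(np.sum(w)))
    k = y.size
    if k >= 2:
        q, df, p_q = cochran_q(effects)
    else:
        q, df, p_q = 0.0, 0, 1.0
    return MetaResult(
        pooled=pooled,
        se_pooled=se_pooled,
        ci_low=pooled - Z95 * se_pooled,
        ci_high=pooled + Z95 * se_pooled,
        tau2=0.0,
        q=q,
        q_df=df,
        p_q=p_q,
        k=k,
        n_cases=nca,
        n_controls=nco,
        scale=scale,
    )


def cochran_q(effects: Sequence) -> tuple[float, int, float]:
    """Cochran's Q = sum w_i*(y_i - y_FE)^2 with a chi-square(k-1) p-value."""
    y, se, _, _ = _as_arrays(effects)
    k = y.size
    if k < 2:
        raise ValueError("Cochran's Q needs at least two studies")
    w = 1.0 / se**2
    y_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - y_fe) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def dl_tau2(effects: Sequence) -> float:
    """DerSimonian-Laird between-study variance.

    tau2 = max(0, (Q - (k-1)) / C) with C = sum(w) - sum(w^2)/sum(w), using
    fixed-effect weights w = 1/se^2; the method-of-moments estimate truncated
    at zero.
    """
    y, se, _, _ = _as_arrays(effects)
    if y.size < 2:
        raise ValueError("tau2 estimation needs at least two studies")
    w = 1.0 / se**2
    q, df, _ = cochran_q(effects)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c <= 0:
        return 0.0
    return max(0.0, (q - df) / c)


def random_effects_pool(effects: Sequence, scale: str = "log_or") -> MetaResult:
    """DerSimonian-Laird random-effects pooling with weights 1/(se^2 + tau2).

    A single study passes through unchanged (tau2 = 0).
    """
    y, se, nca, nco = _as_arrays(effects)
    k = y.size
    if k == 1:
        pooled, se_pooled = float(y[0]), float(se[0])
        tau2, q, df, p_q = 0.0, 0.0, 0, 1.0
    else:
        tau2 = dl_tau2(effects)
        q, df, p_q = cochran_q(effects)
        w = 1.0 / (se**2 + tau2)
        pooled = float(np.sum(w * y) / np.sum(w))
        se_pooled = float(1.0 / math.sqrt(np.sum(w)))
    return MetaResult(
        pooled=pooled,
        se_pooled=se_pooled,
        ci_low=pooled - Z95 * se_pooled,
        ci_high=pooled + Z95 * se_pooled,
        tau2=tau2,
        q=q,
        q_df=df,
        p_q=p_q,
        k=k,
        n_cases=nca,
        n_controls=nco,
        scale=scale,
    )


def egger_test(effects: Sequence) -> EggerResult:
    """Egger's regression test for small-study (publication) bias.

    Ordinary least squares of the standardized effect y_i/se_i on precision
    1/se_i; the intercept's two-sided t-test (k-2 df) is the bias test.  A
    non-zero intercept indicates funnel-plot asymmetry.
    """
    y, se, _, _ = _as_arrays(effects)
    k = y.size
    if k < 3:
        raise ValueError("Egger's test needs at least three studies")
    prec = 1.0 / se
    if np.ptp(prec) < 1e-12 * np.max(prec):
        raise ValueError("Egger regression is singular: all precisions are equal")
    res = stats.linregress(prec, y / se)
    t = res.intercept / res.intercept_stderr
    p = float(2.0 * stats.t.sf(abs(t), k - 2))
    return EggerResult(
        intercept=float(res.intercept),
        se_intercept=float(res.intercept_stderr),
        p=p,
        k=k,
    )


@dataclass(frozen=True)
class _MeanDiff:
    value: float
    se: float
    n_cases: int
    n_controls: int


def pool_mean_difference(
    groups: Sequence[tuple[float, float, float, float, float, float]],
    scale: str = "mean_difference",
) -> MetaResult:
    """Random-effects pooled difference of group means.

    Each entry is (n1, mean1, sd1, n2, mean2, sd2); the per-study difference is
    mean1 - mean2 with se = sqrt(sd1^2/n1 + sd2^2/n2), pooled by
    DerSimonian-Laird.
    """
    diffs = []
    for n1, m1, s1, n2, m2, s2 in groups:
        if n1 < 2 or n2 < 2:
            raise ValueError(f"group sizes must be >= 2, got ({n1}, {n2})")
        if s1 <= 0 or s2 <= 0:
            raise ValueError(f"group SDs must be positive, got ({s1}, {s2})")
        se = math.sqrt(s1**2 / n1 + s2**2 / n2)
        diffs.append(_MeanDiff(m1 - m2, se, int(n1), int(n2)))
    return random_effects_pool(diffs, scale=scale)
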