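"""Cross-disease comparison of pooled genetic effects.

Pooled odds ratios for the same polymorphism in two diseases (e.g. ischemic
stroke and ischemic heart disease) are classified into four profiles based on
95% CI overlap and significance; when one disease shows an effect the other
may simply lack power, so the minimum case count for adequate power at the
other disease's effect size can be back-calculated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from scipy import stats

from .meta import MetaResult


class Profile(str, Enum):
    CONCORDANT_POSITIVE = "concordant_positive"    # both significant, same side, CIs overlap
    DISSOCIATED = "dissociated"                    # disjoint CIs, or significant in opposite directions
    UNDERPOWERED_OVERLAP = "underpowered_overlap"  # one significant, CIs overlap
    CONCORDANT_NULL = "concordant_null"            # neither significant

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DiseaseComparison:
    polymorphism_id: str
    result_a: MetaResult
    result_b: MetaResult
    profile: Profile
    required_cases: int | None = None

    def __post_init__(self) -> None:
        if (self.required_cases is not None) != (
            self.profile is Profile.UNDERPOWERED_OVERLAP
        ):
            raise ValueError(
                "required_cases must be present exactly when the profile is "
                "underpowered_overlap"
            )


def _side(r: MetaResult) -> int:
    """+1 if the CI sits above the null, -1 below, 0 if it spans the null."""
    if r.ci_low > 0:
        return 1
    if r.ci_high < 0:
        return -1
    return 0


def classify_profile(a: MetaResult, b: MetaResult) -> Profile:
    """Classify a pair of pooled log-OR results into a cross-disease profile."""
    if a.scale != "log_or" or b.scale != "log_or":
        raise ValueError(
            f"classify_profile needs log-OR scale results, got '{a.scale}' and '{b.scale}'"
        )
    overlap = a.ci_low <= b.ci_high and b.ci_low <= a.ci_high
    sa, sb = _side(a), _side(b)
    if not overlap or (sa != 0 and sb != 0 and sa != sb):
        return Profile.DISSOCIATED
    if sa != 0 and sb != 0:
        return Profile.CONCORDANT_POSITIVE
    if sa != 0 or sb != 0:
        return Profile.UNDERPOWERED_OVERLAP
    return Profile.CONCORDANT_NULL


def required_cases_for_power(
    p0: float,
    or_target: float,
    alpha: float = 0.05,
    power: float = 0.90,
    control_ratio: float = 1.0,
) -> int:
    """Minimum number of cases to detect ``or_target`` at a given power.

    Two-proportion normal-approximation sample size on the exposure frequency:
    the case exposure frequency implied by the OR is
    p1 = OR*p0 / (1 + p0*(OR - 1)), and with r controls per case

        n = ceil[ (z_{1-a/2}*sqrt((1 + 1/r)*pbar*qbar)
                   + z_{1-b}*sqrt(p1*q1 + p0*q0/r))^2 / (p1 - p0)^2 ]

    where pbar is the weighted average exposure frequency across arms.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    if or_target <= 0:
        raise ValueError("or_target must be positive")
    if or_target == 1:
        raise ValueError("or_target = 1 implies an infinite sample size")
    if control_ratio <= 0:
        raise ValueError("control_ratio must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")

    r = control_ratio
    p1 = or_target * p0 / (1.0 + p0 * (or_target - 1.0))
    pbar = (p1 + r * p0) / (1.0 + r)
    qbar = 1.0 - pbar
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    num = (
        z_a * math.sqrt((1.0 + 1.0 / r) * pbar * qbar)
        + z_b * math.sqrt(p1 * (1.0 - p1) + p0 * (1.0 - p0) / r)
    ) ** 2
    return math.ceil(num / (p1 - p0) ** 2)


def compare_diseases(
    polymorphism_id: str,
    a: MetaResult,
    b: MetaResult,
    p0: float | None = None,
    alpha: float = 0.05,
    power: float = 0.90,
    control_ratio: float = 1.0,
) -> DiseaseComparison:
    """Classify a polymorphism and, when underpowered, back-calculate cases.

    ``p0`` (control exposure frequency) is needed only for the power
    back-calculation; the OR used is that of the significant disease.
    """
    profile = classify_profile(a, b)
    required: int | None = None
    if profile is Profile.UNDERPOWERED_OVERLAP:
        if p0 is None:
            raise ValueError(
                f"{polymorphism_id}: p0 (control exposure frequency) is required "
                "to back-calculate power for an underpowered_overlap profile"
            )
        significant = a if a.significant else b
        required = required_cases_for_power(
            p0, significant.or_value, alpha=alpha, power=power, control_ratio=control_ratio
        )
    return DiseaseComparison(
        polymorphism_id=polymorphism_id,
        result_a=a,
        result_b=b,
        profile=profile,
        required_cases=required,
    )
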