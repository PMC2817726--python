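"""Mendelian-randomization triangulation of genotype, biomarker and disease.

The causal chain genotype -> intermediate phenotype (IP) -> stroke is probed
by comparing two odds ratios for the same genotype contrast:

* the *observed* OR, from pooling case-control genotype studies directly; and
* the *expected* OR, built from independent data: the pooled shift in the IP
  between genotypes (delta_x, rarer minus commoner), combined with published
  ORs of stroke per increment of the IP, each rescaled log-linearly from its
  own increment delta_ip to delta_x (exponent delta_x/delta_ip on the OR) and
  then pooled by random effects.

If the genotype acts on disease purely through the biomarker, expected and
observed risk agree; a genotype that shifts the biomarker one way but risk
the other (pleiotropy, linkage with another causal variant, ...) produces a
discordant pair.  delta_x may be an absolute difference (shared units) or a
percent change relative to the commoner genotype, for IPs measured in
incommensurable units across studies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from . import meta
from .effects import GeneticModel, GenotypeStudy, effects_from_studies
from .meta import MetaResult, pool_mean_difference, random_effects_pool

MODE_ABSOLUTE = "absolute"
MODE_PERCENT = "percent_change"


@dataclass(frozen=True)
class BiomarkerStudy:
    """IP levels by genotype group in disease-free subjects.

    Group "a" is the rarer genotype of the contrast (e.g. hom-variant or
    carrier), group "b" the commoner reference (hom-wild).
    """

    study_id: str
    genotype_a: str
    genotype_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    units: str

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError(f"{self.study_id}: group sizes must be >= 2")
        if self.sd_a <= 0 or self.sd_b <= 0:
            raise ValueError(f"{self.study_id}: group SDs must be positive")


@dataclass(frozen=True)
class IPRiskStudy:
    """Stroke OR per increment ``delta_ip`` of the intermediate phenotype.

    The OR must be oriented per *positive* unit (or percent) of IP change;
    ``delta_ip`` carries the increment the published OR refers to.
    """

    study_id: str
    or_value: float
    ci_low: float
    ci_high: float
    delta_ip: float
    n_cases: int = 0
    n_controls: int = 0

    def __post_init__(self) -> None:
        if self.or_value <= 0 or self.ci_low <= 0 or self.ci_high <= 0:
            raise ValueError(f"{self.study_id}: OR and CI bounds must be positive")
        if not self.ci_low <= self.or_value <= self.ci_high:
            raise ValueError(
                f"{self.study_id}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"bracket OR {self.or_value}"
            )
        if self.delta_ip == 0:
            raise ValueError(f"{self.study_id}: delta_ip must be non-zero")


@dataclass(frozen=True)
class ConcordanceVerdict:
    """Expected-vs-observed comparison with both containment checks reported.

    The headline verdict is whether the expected point estimate falls inside
    the observed 95% CI; the reverse containment is reported alongside as a
    diagnostic.
    """

    verdict: str  # "concordant" | "discordant"
    expected_within_observed: bool
    observed_within_expected: bool

    def __bool__(self) -> bool:
        return self.verdict == "concordant"


@dataclass(frozen=True)
class TriangulationResult:
    delta_x: float
    delta_x_ci: tuple[float, float]
    expected_or: float
    expected_ci: tuple[float, float]
    observed_or: float
    observed_ci: tuple[float, float]
    verdict: ConcordanceVerdict
    mode: str
    audit: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.expected_or <= 0 or self.observed_or <= 0:
            raise ValueError("expected and observed ORs must be positive")


def pool_ip_shift(
    studies: Sequence[BiomarkerStudy], mode: str = MODE_ABSOLUTE
) -> tuple[float, tuple[float, float], MetaResult]:
    """Random-effects pooled biomarker shift (rarer minus commoner genotype).

    absolute:       d = mean_a - mean_b, se = sqrt(sd_a^2/n_a + sd_b^2/n_b);
                    all studies must share units.
    percent_change: d = 100*(mean_a - mean_b)/mean_b with a delta-method se,
                    for IPs reported in different units across studies.
    """
    if not studies:
        raise ValueError("pool_ip_shift needs at least one study")
    if mode == MODE_ABSOLUTE:
        units = {s.units for s in studies}
        if len(units) > 1:
            raise ValueError(
                f"absolute pooling requires shared units, got {sorted(units)}"
            )
        result = pool_mean_difference(
            [(s.n_a, s.mean_a, s.sd_a, s.n_b, s.mean_b, s.sd_b) for s in studies]
        )
    elif mode == MODE_PERCENT:
        pairs = []
        for s in studies:
            if s.mean_b == 0:
                raise ValueError(f"{s.study_id}: reference mean is zero in percent mode")
            d = 100.0 * (s.mean_a - s.mean_b) / s.mean_b
            var = (100.0 / s.mean_b) ** 2 * s.sd_a**2 / s.n_a + (
                100.0 * s.mean_a / s.mean_b**2
            ) ** 2 * s.sd_b**2 / s.n_b
            pairs.append((d, math.sqrt(var)))
        result = random_effects_pool(pairs, scale="percent_change")
    else:
        raise ValueError(f"unknown mode '{mode}'")
    return result.pooled, (result.ci_low, result.ci_high), result


def se_from_ci(
    or_value: float, ci_low: float, ci_high: float, rel_tol: float = 0.05
) -> float:
    """Standard error of ln(OR) recovered from a published 95% CI.

    Symmetric on the log scale: (ln hi - ln lo) / (2*1.96).  A CI that is
    asymmetric around the OR on the log scale (beyond ``rel_tol``) triggers a
    warning and the wider half-width is used, conservatively.
    """
    lo_half = math.log(or_value / ci_low)
    hi_half = math.log(ci_high / or_value)
    if lo_half < 0 or hi_half < 0:
        raise ValueError("CI does not bracket the OR")
    mean_half = 0.5 * (lo_half + hi_half)
    if mean_half == 0:
        raise ValueError("degenerate CI of zero width")
    if abs(hi_half - lo_half) > rel_tol * mean_half:
        warnings.warn(
            f"asymmetric CI around OR {or_value:g} ({ci_low:g}-{ci_high:g}); "
            "using the wider half-width",
            stacklevel=2,
        )
        return max(lo_half, hi_half) / meta.Z95
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * meta.Z95)


def rescale_or(study: IPRiskStudy, delta_x: float) -> tuple[float, float]:
    """Rescale a per-increment OR log-linearly to the pooled shift delta_x.

    With f = delta_x/delta_ip: ln OR_scaled = f * ln OR, se_scaled = |f| * se.
    delta_x and delta_ip must be in the same units and direction convention.
    """
    f = delta_x / study.delta_ip
    se = se_from_ci(study.or_value, study.ci_low, study.ci_high)
    return f * math.log(study.or_value), abs(f) * se


def expected_or(
    studies: Sequence[IPRiskStudy], delta_x: float
) -> tuple[float, tuple[float, float], MetaResult]:
    """Expected genotype OR from IP-risk studies rescaled to delta_x.

    Each study's OR is rescaled log-linearly, then the scaled log-ORs are
    pooled by generic inverse-variance random effects and exponentiated.
    delta_x is treated as fixed at its pooled value; only the IP-risk OR
    uncertainty propagates into the CI.
    """
    if not studies:
        raise ValueError("expected_or needs at least one IP-risk study")
    scaled = [rescale_or(s, delta_x) for s in studies]
    pooled = random_effects_pool(scaled, scale="log_or")
    return pooled.or_value, pooled.or_ci, pooled


def concordance_verdict(
    expected: tuple[float, tuple[float, float]],
    observed: tuple[float, tuple[float, float]],
) -> ConcordanceVerdict:
    """Concordant when the expected point OR lies within the observed 95% CI.

    Both containment directions are evaluated and reported; the headline
    verdict uses expected-within-observed, the criterion under which a
    biomarker-predicted risk is judged consistent with the directly observed
    genotype risk.
    """
    (e_or, (e_lo, e_hi)) = expected
    (o_or, (o_lo, o_hi)) = observed
    if e_or <= 0 or o_or <= 0:
        raise ValueError("ORs must be positive")
    e_in_o = o_lo <= e_or <= o_hi
    o_in_e = e_lo <= o_or <= e_hi
    return ConcordanceVerdict(
        verdict="concordant" if e_in_o else "discordant",
        expected_within_observed=e_in_o,
        observed_within_expected=o_in_e,
    )


def run_triangulation(
    genotype_studies: Sequence[GenotypeStudy],
    biomarker_studies: Sequence[BiomarkerStudy],
    ip_risk_studies: Sequence[IPRiskStudy],
    model: GeneticModel,
    mode: str = MODE_ABSOLUTE,
    correction: float = 0.5,
) -> TriangulationResult:
    """Full triangulation chain with every intermediate kept for audit.

    observed OR  <- random-effects pooling of the genotype case-control studies;
    delta_x      <- pooled IP shift (rarer minus commoner genotype);
    expected OR  <- IP-risk ORs rescaled to delta_x, pooled;
    verdict      <- expected point estimate versus observed 95% CI.
    """
    try:
        obs_effects = effects_from_studies(genotype_studies, model, correction)
        obs = random_effects_pool(obs_effects)
    except Exception as exc:
        raise RuntimeError(f"observed-OR stage failed: {exc}") from exc
    try:
        delta_x, delta_ci, shift_meta = pool_ip_shift(biomarker_studies, mode)
    except Exception as exc:
        raise RuntimeError(f"biomarker-shift stage failed: {exc}") from exc
    try:
        exp_or, exp_ci, exp_meta = expected_or(ip_risk_studies, delta_x)
    except Exception as exc:
        raise RuntimeError(f"expected-OR stage failed: {exc}") from exc

    verdict = concordance_verdict((exp_or, exp_ci), (obs.or_value, obs.or_ci))
    audit = {
        "observed_meta": obs,
        "shift_meta": shift_meta,
        "expected_meta": exp_meta,
        "scale_factors": [delta_x / s.delta_ip for s in ip_risk_studies],
        "per_study_effects": obs_effects,
        "model": GeneticModel(model).value,
    }
    return TriangulationResult(
        delta_x=delta_x,
        delta_x_ci=delta_ci,
        expected_or=exp_or,
        expected_ci=exp_ci,
        observed_or=obs.or_value,
        observed_ci=obs.or_ci,
        verdict=verdict,
        mode=mode,
        audit=audit,
    )
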