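"""Per-study odds-ratio effect estimates from case-control genotype counts.

A candidate-gene association study reports genotype counts for cases and
controls, ordered (hom-risk, het, hom-wild).  A genetic model collapses the
three genotype classes into a two-level exposure (carrier status, homozygote
status, or allele counts), from which a 2x2 table and a log odds ratio with
its standard error are obtained.  The risk (variant) genotype always occupies
the first count slot; orientation is the caller's responsibility and is echoed
through to the outputs so a sign flip cannot happen silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence


class GeneticModel(str, Enum):
    """Rule for collapsing three genotype counts into a two-level exposure."""

    DOMINANT = "dominant"          # carriers (hom-risk + het) vs hom-wild
    RECESSIVE = "recessive"        # hom-risk vs (het + hom-wild)
    ALLELIC = "allelic"            # risk alleles vs wild alleles (2 per genotype)
    HOM_VS_HOM = "hom_vs_hom"      # hom-risk vs hom-wild, het excluded

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GenotypeStudy:
    """One case-control study's genotype counts plus metadata.

    ``case_counts``/``control_counts`` are (hom-risk, het, hom-wild) triples,
    or (risk-allele, wild-allele) pairs when ``allele_level`` is set (studies
    that only publish allele counts).
    """

    study_id: str
    polymorphism_id: str
    disease: str
    year: int
    case_counts: tuple[int, ...]
    control_counts: tuple[int, ...]
    allele_level: bool = False

    def __post_init__(self) -> None:
        width = 2 if self.allele_level else 3
        for name, counts in (("case", self.case_counts), ("control", self.control_counts)):
            if len(counts) != width:
                raise ValueError(
                    f"{self.study_id}: {name}_counts must have {width} entries "
                    f"({'allele' if self.allele_level else 'genotype'} level), got {len(counts)}"
                )
            if any(c < 0 for c in counts):
                raise ValueError(f"{self.study_id}: negative {name} count {counts}")
            if sum(counts) <= 0:
                raise ValueError(f"{self.study_id}: all {name} counts are zero")

    @property
    def n_cases(self) -> int:
        total = sum(self.case_counts)
        return total // 2 if self.allele_level else total

    @property
    def n_controls(self) -> int:
        total = sum(self.control_counts)
        return total // 2 if self.allele_level else total


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table: (cases-exposed, cases-unexposed, controls-exposed, controls-unexposed)."""

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")
        if self.a + self.b <= 0 or self.c + self.d <= 0:
            raise ValueError("2x2 table needs at least one case and one control")


@dataclass(frozen=True)
class EffectEstimate:
    """A log odds ratio with its standard error and provenance metadata."""

    log_or: float
    se: float
    n_cases: int
    n_controls: int
    study_id: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.log_or) and math.isfinite(self.se)):
            raise ValueError(f"{self.study_id}: non-finite effect estimate")
        if self.se <= 0:
            raise ValueError(f"{self.study_id}: se must be positive, got {self.se}")

    @property
    def or_value(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci(self) -> tuple[float, float]:
        half = 1.96 * self.se
        return math.exp(self.log_or - half), math.exp(self.log_or + half)


def collapse_to_2x2(study: GenotypeStudy, model: GeneticModel) -> TwoByTwo:
    """Collapse genotype (or allele) counts to a 2x2 exposure table.

    dominant:   exposed = hom-risk + het
    recessive:  exposed = hom-risk
    allelic:    exposed = risk alleles (each hom contributes 2, each het 1)
    hom_vs_hom: exposed = hom-risk, het column dropped entirely
    """
    model = GeneticModel(model)
    if study.allele_level:
        if model is not GeneticModel.ALLELIC:
            raise ValueError(
                f"{study.study_id}: model '{model.value}' requires genotype counts, "
                "but this study reports allele-level counts"
            )
        (ra, wa), (rc, wc) = study.case_counts, study.control_counts
        return TwoByTwo(ra, wa, rc, wc)

    (c2, c1, c0) = study.case_counts
    (k2, k1, k0) = study.control_counts
    if model is GeneticModel.DOMINANT:
        return TwoByTwo(c2 + c1, c0, k2 + k1, k0)
    if model is GeneticModel.RECESSIVE:
        return TwoByTwo(c2, c1 + c0, k2, k1 + k0)
    if model is GeneticModel.ALLELIC:
        return TwoByTwo(2 * c2 + c1, 2 * c0 + c1, 2 * k2 + k1, 2 * k0 + k1)
    if model is GeneticModel.HOM_VS_HOM:
        return TwoByTwo(c2, c0, k2, k0)
    raise ValueError(f"unknown genetic model: {model!r}")  # pragma: no cover


def log_odds_ratio(
    t: TwoByTwo,
    correction: float = 0.5,
    *,
    study_id: str = "",
    year: int = 0,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> EffectEstimate:
    """Log OR = ln(ad/bc) with se = sqrt(1/a + 1/b + 1/c + 1/d).

    When any cell is zero, ``correction`` is added to all four cells of the
    table (Haldane-Anscombe); a zero cell with ``correction=0`` is a hard
    error rather than an infinite estimate.
    """
    if correction < 0:
        raise ValueError("correction must be non-negative")
    a, b, c, d = t.a, t.b, t.c, t.d
    corrected = t.corrected
    if min(a, b, c, d) == 0:
        if correction == 0:
            raise ValueError(
                f"{study_id or 'table'}: zero cell in 2x2 table and correction=0 "
                "(degenerate odds ratio)"
            )
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
        corrected = True
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        log_or=log_or,
        se=se,
        n_cases=n_cases if n_cases is not None else round(t.a + t.b),
        n_controls=n_controls if n_controls is not None else round(t.c + t.d),
        study_id=study_id,
        year=year,
    )


def study_effect(
    study: GenotypeStudy, model: GeneticModel, correction: float = 0.5
) -> EffectEstimate:
    """Effect estimate for one study under a genetic model, metadata attached."""
    t = collapse_to_2x2(study, model)
    return log_odds_ratio(
        t,
        correction,
        study_id=study.study_id,
        year=study.year,
        n_cases=study.n_cases,
        n_controls=study.n_controls,
    )


def effects_from_studies(
    studies: Sequence[GenotypeStudy], model: GeneticModel, correction: float = 0.5
) -> list[EffectEstimate]:
    return [study_effect(s, model, correction) for s in studies]


def risk_genotype_frequency(
    studies: Sequence[GenotypeStudy], model: GeneticModel
) -> float:
    """Frequency of the risk exposure among pooled controls under ``model``.

    This is the prevalence that enters the population attributable risk: the
    carrier frequency (dominant), hom-risk frequency (recessive/hom-vs-hom) or
    risk-allele frequency (allelic) in the combined control groups.
    """
    exposed = total = 0.0
    for s in studies:
        t = collapse_to_2x2(s, model)
        exposed += t.c
        total += t.c + t.d
    if total <= 0:
        raise ValueError("no controls in pooled studies")
    return exposed / total
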