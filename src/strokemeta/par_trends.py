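"""Population attributable risk and temporal trends of candidate-gene studies.

The PAR of a risk genotype is the percentage of cases in the population that
would not occur if the exposure were absent:

    PAR = 100 * p*(OR - 1) / (p*(OR - 1) + 1)

with p the risk-genotype frequency among pooled controls (under the same
genetic model used for the OR).  Summing PARs across polymorphisms is the
conventional first-order total that ignores overlap between exposures.

The trend series counts, per publication year, cases recruited into studies of
polymorphisms that a meta-analysis ultimately judged associated versus
unassociated — a measure of how efficiently the candidate-gene approach picked
its targets over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .effects import GenotypeStudy

ASSOCIATED = "associated"
UNASSOCIATED = "unassociated"


@dataclass(frozen=True)
class ParResult:
    polymorphism_id: str
    or_value: float
    prevalence: float
    par_percent: float

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.or_value <= 0:
            raise ValueError("or_value must be positive")


@dataclass(frozen=True)
class TrendSeries:
    """One publication year's case counts by meta-analytic verdict.

    ``p_associated`` is the probability that a case recruited that year was
    tested for a polymorphism later found associated.  Cumulative fields run
    from the earliest year in the collection up to and including this one.
    """

    year: int
    cases_associated: int
    cases_unassociated: int
    p_associated: float
    cum_cases_associated: int
    cum_cases_unassociated: int
    cum_p_associated: float


def population_attributable_risk(or_value: float, prevalence: float) -> float:
    """PAR (%) = 100 * p*(OR-1) / (p*(OR-1) + 1)."""
    if or_value <= 0:
        raise ValueError("or_value must be positive")
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must lie in [0, 1]")
    excess = prevalence * (or_value - 1.0)
    return 100.0 * excess / (excess + 1.0)


def par_result(polymorphism_id: str, or_value: float, prevalence: float) -> ParResult:
    return ParResult(
        polymorphism_id=polymorphism_id,
        or_value=or_value,
        prevalence=prevalence,
        par_percent=population_attributable_risk(or_value, prevalence),
    )


def total_par(pars: Sequence[ParResult | float]) -> float:
    """Arithmetic sum of per-polymorphism PARs (%).

    A first-order approximation: overlapping exposures are double-counted, so
    the sum can exceed the PAR of the combined exposure (and 100%).
    """
    if len(pars) == 0:
        raise ValueError("total_par needs at least one PAR")
    return float(sum(p.par_percent if isinstance(p, ParResult) else float(p) for p in pars))


def cases_by_year(
    studies: Iterable[GenotypeStudy],
    verdicts: Mapping[str, str],
) -> list[TrendSeries]:
    """Per-year and cumulative case counts split by association verdict.

    ``verdicts`` maps polymorphism_id -> "associated" | "unassociated"
    (typically derived from random-effects pooling: significant pooled OR with
    no significant heterogeneity).  Years with no studies are omitted.
    """
    studies = list(studies)
    missing = sorted({s.polymorphism_id for s in studies} - set(verdicts))
    if missing:
        raise ValueError(f"no verdict for polymorphisms: {', '.join(missing)}")
    bad = {p: v for p, v in verdicts.items() if v not in (ASSOCIATED, UNASSOCIATED)}
    if bad:
        raise ValueError(f"verdicts must be '{ASSOCIATED}' or '{UNASSOCIATED}': {bad}")

    per_year: dict[int, list[int]] = {}
    for s in studies:
        row = per_year.setdefault(s.year, [0, 0])
        if verdicts[s.polymorphism_id] == ASSOCIATED:
            row[0] += s.n_cases
        else:
            row[1] += s.n_cases

    out: list[TrendSeries] = []
    cum_a = cum_u = 0
    for year in sorted(per_year):
        a, u = per_year[year]
        cum_a += a
        cum_u += u
        out.append(
            TrendSeries(
                year=year,
                cases_associated=a,
                cases_unassociated=u,
                p_associated=a / (a + u) if a + u > 0 else float("nan"),
                cum_cases_associated=cum_a,
                cum_cases_unassociated=cum_u,
                cum_p_associated=cum_a / (cum_a + cum_u) if cum_a + cum_u > 0 else float("nan"),
            )
        )
    return out


def trends_frame(series: Sequence[TrendSeries]) -> pd.DataFrame:
    """Trend series as a DataFrame, one row per year."""
    return pd.DataFrame([vars(t) for t in series])
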