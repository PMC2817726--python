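"""Report assembly: validation, per-polymorphism pooling, PAR and verdicts.

`run_primary_meta` reproduces the primary analysis layout: every polymorphism
with at least two studies gets a random-effects OR with CI, heterogeneity and
Egger diagnostics, control-group risk-genotype frequency and PAR; rows are
ordered by pooled case count and flagged as primary-reportable when the pooled
cases exceed a threshold (default 1000).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .effects import (
    GeneticModel,
    GenotypeStudy,
    effects_from_studies,
    risk_genotype_frequency,
)
from .io import GENOTYPE_COLUMNS
from .meta import egger_test, random_effects_pool
from .par_trends import ASSOCIATED, UNASSOCIATED, population_attributable_risk

_COUNT_COLS = [c for c in GENOTYPE_COLUMNS if "case_" in c or "control_" in c]
_HET_COLS = ["case_het", "control_het"]


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and options shared by the report-level entry points."""

    model: GeneticModel = GeneticModel.DOMINANT
    min_pooled_cases: int = 1000
    alpha: float = 0.05
    het_alpha: float = 0.05
    egger_alpha: float = 0.10
    correction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "het_alpha", "egger_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.min_pooled_cases < 0:
            raise ValueError("min_pooled_cases must be non-negative")


def validate_and_log(
    df: pd.DataFrame,
) -> tuple[list[GenotypeStudy], list[dict]]:
    """Parse a raw genotype study table into typed studies plus an issue log.

    Schema violations (missing columns) and negative counts are fatal with row
    references; rows whose het columns are both blank are read as allele-level
    counts and logged as such.  The log is a list of machine-readable dicts.
    """
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"study table is missing columns: {sorted(missing)}")
    log: list[dict] = []
    studies: list[GenotypeStudy] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        sid = str(row["study_id"])
        allele_level = bool(
            pd.isna(row["case_het"]) and pd.isna(row["control_het"])
        )
        cols = (
            ["case_hom_risk", "case_hom_wild", "control_hom_risk", "control_hom_wild"]
            if allele_level
            else _COUNT_COLS
        )
        vals = {}
        for c in cols:
            v = row[c]
            if pd.isna(v):
                raise ValueError(f"line {line} ({sid}): blank count in column '{c}'")
            v = float(v)
            if v < 0:
                raise ValueError(f"line {line} ({sid}): negative count {v:g} in '{c}'")
            if v != int(v):
                raise ValueError(f"line {line} ({sid}): non-integer count {v:g} in '{c}'")
            vals[c] = int(v)
        if allele_level:
            log.append({"line": line, "study_id": sid, "event": "allele_level_counts"})
            case_counts = (vals["case_hom_risk"], vals["case_hom_wild"])
            control_counts = (vals["control_hom_risk"], vals["control_hom_wild"])
        else:
            case_counts = (vals["case_hom_risk"], vals["case_het"], vals["case_hom_wild"])
            control_counts = (
                vals["control_hom_risk"], vals["control_het"], vals["control_hom_wild"]
            )
        try:
            studies.append(
                GenotypeStudy(
                    study_id=sid,
                    polymorphism_id=str(row["polymorphism"]),
                    disease=str(row["disease"]),
                    year=int(row["year"]),
                    case_counts=case_counts,
                    control_counts=control_counts,
                    allele_level=allele_level,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {line}: {exc}") from exc
    return studies, log


def run_primary_meta(
    studies: Sequence[GenotypeStudy],
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Per-polymorphism random-effects report, ordered by pooled case count.

    Polymorphisms with a single study are listed but not pooled.  Duplicate
    study ids within a polymorphism are rejected outright: de-duplication of
    overlapping publications is a curation decision, not something to resolve
    silently.
    """
    model = GeneticModel(config.model)
    by_poly: dict[str, list[GenotypeStudy]] = {}
    for s in studies:
        by_poly.setdefault(s.polymorphism_id, []).append(s)

    rows = []
    for poly, group in by_poly.items():
        ids = [s.study_id for s in group]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(
                f"{poly}: duplicate study ids {dupes}; discard overlapping "
                "publications before pooling"
            )
        n_cases = sum(s.n_cases for s in group)
        n_controls = sum(s.n_controls for s in group)
        row = {
            "polymorphism": poly,
            "k": len(group),
            "n_cases": n_cases,
            "n_controls": n_controls,
            "pooled": len(group) >= 2,
            "primary": n_cases > config.min_pooled_cases,
            "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "tau2": np.nan, "q": np.nan, "p_q": np.nan, "i2": np.nan,
            "egger_intercept": np.nan, "egger_p": np.nan,
            "prevalence": np.nan, "par_percent": np.nan,
            "verdict": UNASSOCIATED,
        }
        if len(group) >= 2:
            effects = effects_from_studies(group, model, config.correction)
            res = random_effects_pool(effects)
            prev = risk_genotype_frequency(group, model)
            row.update(
                {
                    "or": res.or_value,
                    "ci_low": res.or_ci[0],
                    "ci_high": res.or_ci[1],
                    "tau2": res.tau2,
                    "q": res.q,
                    "p_q": res.p_q,
                    "i2": res.i2,
                    "prevalence": prev,
                    "par_percent": population_attributable_risk(res.or_value, prev)
                    if res.or_value >= 1
                    else 0.0,
                }
            )
            if len(group) >= 3:
                try:
                    egger = egger_test(effects)
                    row["egger_intercept"] = egger.intercept
                    row["egger_p"] = egger.p
                except ValueError:
                    pass  # singular design: identical precisions
            if res.significant and res.p_q >= config.het_alpha:
                row["verdict"] = ASSOCIATED
        rows.append(row)

    report = pd.DataFrame(rows)
    return report.sort_values(
        "n_cases", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def verdicts_from_report(report: pd.DataFrame) -> dict[str, str]:
    """Polymorphism -> associated/unassociated map for the trend analysis."""
    return dict(zip(report["polymorphism"], report["verdict"]))


def render_report(report: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Presentation copy with ORs/CIs rounded; full precision stays in JSON."""
    out = report.copy()
    for c in ("or", "ci_low", "ci_high", "par_percent", "i2"):
        if c in out:
            out[c] = out[c].round(decimals)
    for c in ("tau2", "q", "p_q", "egger_intercept", "egger_p", "prevalence"):
        if c in out:
            out[c] = out[c].round(4)
    return out
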