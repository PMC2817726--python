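"""Readers and writers for the delimited study tables and JSON summaries.

Genotype study tables are CSV/TSV with header columns::

    study_id, polymorphism, disease, year,
    case_hom_risk, case_het, case_hom_wild,
    control_hom_risk, control_het, control_hom_wild

Blank het columns on a row signal allele-level counts (the *_hom_risk and
*_hom_wild columns then carry risk- and wild-allele counts).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .effects import GenotypeStudy
from .meta import MetaResult
from .triangulate import BiomarkerStudy, IPRiskStudy

GENOTYPE_COLUMNS = [
    "study_id", "polymorphism", "disease", "year",
    "case_hom_risk", "case_het", "case_hom_wild",
    "control_hom_risk", "control_het", "control_hom_wild",
]

BIOMARKER_COLUMNS = [
    "study_id", "genotype_a", "genotype_b", "n_a", "n_b",
    "mean_a", "mean_b", "sd_a", "sd_b", "units",
]

IP_RISK_COLUMNS = [
    "study_id", "or_value", "ci_low", "ci_high", "delta_ip",
    "n_cases", "n_controls",
]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV table, sniffing the delimiter."""
    return pd.read_csv(path, sep=None, engine="python")


def genotype_table(studies: Sequence[GenotypeStudy]) -> pd.DataFrame:
    rows = []
    for s in studies:
        if s.allele_level:
            ch, cw = s.case_counts
            kh, kw = s.control_counts
            counts = (ch, None, cw, kh, None, kw)
        else:
            counts = (*s.case_counts, *s.control_counts)
        rows.append((s.study_id, s.polymorphism_id, s.disease, s.year, *counts))
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def biomarker_table(studies: Sequence[BiomarkerStudy]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(s, c) for c in BIOMARKER_COLUMNS] for s in studies],
        columns=BIOMARKER_COLUMNS,
    )


def ip_risk_table(studies: Sequence[IPRiskStudy]) -> pd.DataFrame:
    return pd.DataFrame(
        [[s.study_id, s.or_value, s.ci_low, s.ci_high, s.delta_ip,
          s.n_cases, s.n_controls] for s in studies],
        columns=IP_RISK_COLUMNS,
    )


def read_biomarker_studies(path: str | Path) -> list[BiomarkerStudy]:
    df = read_table(path)
    missing = set(BIOMARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        BiomarkerStudy(
            study_id=str(r.study_id), genotype_a=str(r.genotype_a),
            genotype_b=str(r.genotype_b), n_a=int(r.n_a), n_b=int(r.n_b),
            mean_a=float(r.mean_a), mean_b=float(r.mean_b),
            sd_a=float(r.sd_a), sd_b=float(r.sd_b), units=str(r.units),
        )
        for r in df.itertuples(index=False)
    ]


def read_ip_risk_studies(path: str | Path) -> list[IPRiskStudy]:
    df = read_table(path)
    missing = set(IP_RISK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        IPRiskStudy(
            study_id=str(r.study_id), or_value=float(r.or_value),
            ci_low=float(r.ci_low), ci_high=float(r.ci_high),
            delta_ip=float(r.delta_ip), n_cases=int(r.n_cases),
            n_controls=int(r.n_controls),
        )
        for r in df.itertuples(index=False)
    ]


def meta_result_to_dict(r: MetaResult) -> dict:
    d = dataclasses.asdict(r)
    if r.scale == "log_or":
        d["or_value"] = r.or_value
        d["or_ci"] = list(r.or_ci)
    return d


def meta_result_from_dict(d: dict) -> MetaResult:
    fields = {f.name for f in dataclasses.fields(MetaResult)}
    return MetaResult(**{k: v for k, v in d.items() if k in fields})


def read_meta_result(path: str | Path) -> MetaResult:
    with open(path) as fh:
        return meta_result_from_dict(json.load(fh))


def write_meta_result(r: MetaResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(meta_result_to_dict(r), fh, indent=2)
        fh.write("\n")
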