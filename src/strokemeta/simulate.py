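"""Synthetic study-level datasets with known ground truth.

Every pipeline stage is exercised on generated data that mimics the
statistical structure of published candidate-gene literature:

* case-control genotype studies sharing a true log-OR with between-study
  variance tau2, controls in Hardy-Weinberg proportions, cases drawn from
  genotype-conditional odds that reproduce the target marginal OR;
* biomarker (intermediate phenotype) studies whose genotype-group means sit
  around fixed population means with sampling noise;
* IP-risk case-control studies in which disease risk is log-linear in the
  biomarker, each analysed by logistic regression and reported as an OR per
  stated increment.

All generators are pure functions of their ScenarioConfig: a single top-level
seed feeds a splittable SeedSequence, one independent sub-stream per
generator, so outputs are bit-identical across runs and across call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .effects import GeneticModel, GenotypeStudy
from .triangulate import MODE_ABSOLUTE, MODE_PERCENT, BiomarkerStudy, IPRiskStudy

# stable sub-stream keys; changing these changes every generated dataset
_STREAMS = {"genotype": 1, "biomarker": 2, "risk": 3}


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth parameters for a genotype -> biomarker -> risk scenario.

    ``risk_slope_per_unit`` is the log-OR of disease per unit of biomarker;
    ``direct_genotype_effect`` is the genotype log-OR *not* mediated by the
    biomarker (0 = fully mediated).  The marginal genotype log-OR implied by
    the chain is ``risk_slope_per_unit * (mean_a - mean_b) +
    direct_genotype_effect``; `simulate_triangulation_scenario` uses that as
    the generating OR, while `simulate_genotype_studies` on its own uses
    ``true_or`` directly.
    """

    seed: int = 0
    k_genotype: int = 26
    k_biomarker: int = 6
    k_risk: int = 9
    allele_freq: float = 0.025
    true_or: float = 1.30
    tau2: float = 0.0
    model: GeneticModel = GeneticModel.DOMINANT
    mode: str = MODE_ABSOLUTE
    study_size_range: tuple[int, int] = (300, 1000)   # cases per genotype study
    control_ratio: float = 2.0
    biomarker_cohort_range: tuple[int, int] = (300, 2000)
    risk_case_range: tuple[int, int] = (800, 1688)
    risk_control_range: tuple[int, int] = (5000, 30574)
    biomarker_mean_a: float = 2.26   # rarer genotype group
    biomarker_mean_b: float = 3.00   # commoner (reference) group
    biomarker_sd: float = 0.40
    units: str = "APTT ratio"
    risk_slope_per_unit: float = math.log(1.30) / -0.74
    direct_genotype_effect: float = 0.0
    delta_ip_choices: tuple[float, ...] = (0.5, 0.74, 1.0)
    year_range: tuple[int, int] = (1993, 2009)
    polymorphism_id: str = "rs_sim"
    disease: str = "ischemic stroke"

    def __post_init__(self) -> None:
        if not 0 < self.allele_freq < 1:
            raise ValueError("allele_freq must lie in (0, 1)")
        if self.true_or <= 0 or self.tau2 < 0 or self.biomarker_sd <= 0:
            raise ValueError("true_or > 0, tau2 >= 0 and biomarker_sd > 0 required")
        for lo, hi in (
            self.study_size_range,
            self.biomarker_cohort_range,
            self.risk_case_range,
            self.risk_control_range,
        ):
            if lo < 50 or hi < lo:
                raise ValueError("size ranges must satisfy 50 <= lo <= hi")
        if min(self.k_genotype, self.k_biomarker, self.k_risk) < 1:
            raise ValueError("study counts must be >= 1")
        if any(d == 0 for d in self.delta_ip_choices):
            raise ValueError("delta_ip_choices must be non-zero")

    @property
    def hwe(self) -> tuple[float, float, float]:
        """(hom-risk, het, hom-wild) Hardy-Weinberg proportions."""
        p = self.allele_freq
        return (p * p, 2 * p * (1 - p), (1 - p) * (1 - p))

    @property
    def delta_true(self) -> float:
        """True biomarker shift, rarer minus commoner genotype (absolute units)."""
        return self.biomarker_mean_a - self.biomarker_mean_b

    @property
    def chain_log_or(self) -> float:
        """Marginal genotype log-OR implied by mediation + direct effect."""
        return self.risk_slope_per_unit * self.delta_true + self.direct_genotype_effect


def _rng(cfg: ScenarioConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(_STREAMS[stream],))
    )


def _case_genotype_probs(
    hwe: tuple[float, float, float], model: GeneticModel, log_or: float
) -> np.ndarray:
    """Case genotype distribution reproducing the target exposure OR.

    Exact for dominant/recessive/hom_vs_hom 2x2 contrasts; under the allelic
    model the per-allele OR is applied to the allele frequency and genotypes
    are re-formed under HWE at the tilted frequency (an approximation,
    adequate for a population in HWE in both arms).
    """
    g2, g1, g0 = hwe
    e = math.exp(log_or)
    if model is GeneticModel.DOMINANT:
        p0 = g2 + g1
        odds = e * p0 / (1 - p0)
        p1 = odds / (1 + odds)
        return np.array([p1 * g2 / p0, p1 * g1 / p0, 1 - p1])
    if model is GeneticModel.RECESSIVE:
        p0 = g2
        odds = e * p0 / (1 - p0)
        p1 = odds / (1 + odds)
        rest = 1 - p1
        return np.array([p1, rest * g1 / (g1 + g0), rest * g0 / (g1 + g0)])
    if model is GeneticModel.HOM_VS_HOM:
        # exact for the hom-vs-hom contrast; het tilted by half the log-OR
        w = np.array([g2 * e, g1 * math.exp(log_or / 2), g0])
        return w / w.sum()
    if model is GeneticModel.ALLELIC:
        q = math.sqrt(g2)  # allele frequency
        odds = e * q / (1 - q)
        q1 = odds / (1 + odds)
        return np.array([q1 * q1, 2 * q1 * (1 - q1), (1 - q1) * (1 - q1)])
    raise ValueError(f"unknown model {model!r}")  # pragma: no cover


def simulate_genotype_studies(cfg: ScenarioConfig, true_log_or: float | None = None) -> list[GenotypeStudy]:
    """k_genotype case-control studies with per-study log-OR ~ N(ln OR, tau2)."""
    rng = _rng(cfg, "genotype")
    model = GeneticModel(cfg.model)
    mu = math.log(cfg.true_or) if true_log_or is None else true_log_or
    lo, hi = cfg.study_size_range
    y0, y1 = cfg.year_range
    studies = []
    for i in range(cfg.k_genotype):
        theta = rng.normal(mu, math.sqrt(cfg.tau2)) if cfg.tau2 > 0 else mu
        n_cases = int(rng.integers(lo, hi + 1))
        n_controls = int(round(cfg.control_ratio * n_cases))
        controls = rng.multinomial(n_controls, cfg.hwe)
        cases = rng.multinomial(n_cases, _case_genotype_probs(cfg.hwe, model, theta))
        studies.append(
            GenotypeStudy(
                study_id=f"geno{i + 1:03d}",
                polymorphism_id=cfg.polymorphism_id,
                disease=cfg.disease,
                year=int(rng.integers(y0, y1 + 1)),
                case_counts=tuple(int(x) for x in cases),
                control_counts=tuple(int(x) for x in controls),
            )
        )
    return studies


def _group_labels(model: GeneticModel) -> tuple[str, str]:
    if model is GeneticModel.RECESSIVE or model is GeneticModel.HOM_VS_HOM:
        return "hom-risk", "hom-wild"
    return "carrier", "hom-wild"


def _rarer_fraction(cfg: ScenarioConfig) -> float:
    """Population share of the rarer genotype group within the contrast."""
    g2, g1, g0 = cfg.hwe
    model = GeneticModel(cfg.model)
    if model is GeneticModel.DOMINANT:
        return (g2 + g1) / (g2 + g1 + g0)
    if model in (GeneticModel.RECESSIVE, GeneticModel.HOM_VS_HOM):
        return g2 / (g2 + g0)
    return g2 + g1  # allelic: carriers as the measured group


def simulate_biomarker_studies(cfg: ScenarioConfig) -> list[BiomarkerStudy]:
    """k_biomarker cross-sectional IP studies in disease-free subjects.

    Cohort sizes are drawn from ``biomarker_cohort_range`` and split between
    genotype groups in proportion to their population frequencies (floor 20
    per group); observed means carry sd/sqrt(n) noise and observed SDs are
    chi-square distributed around the true SD.
    """
    rng = _rng(cfg, "biomarker")
    model = GeneticModel(cfg.model)
    lab_a, lab_b = _group_labels(model)
    frac = _rarer_fraction(cfg)
    lo, hi = cfg.biomarker_cohort_range
    sd = cfg.biomarker_sd
    studies = []
    for i in range(cfg.k_biomarker):
        n = int(rng.integers(lo, hi + 1))
        n_a = max(20, int(round(n * frac)))
        n_b = max(20, n - n_a)
        mean_a = rng.normal(cfg.biomarker_mean_a, sd / math.sqrt(n_a))
        mean_b = rng.normal(cfg.biomarker_mean_b, sd / math.sqrt(n_b))
        sd_a = sd * math.sqrt(rng.chisquare(n_a - 1) / (n_a - 1))
        sd_b = sd * math.sqrt(rng.chisquare(n_b - 1) / (n_b - 1))
        studies.append(
            BiomarkerStudy(
                study_id=f"bio{i + 1:03d}",
                genotype_a=lab_a,
                genotype_b=lab_b,
                n_a=n_a,
                n_b=n_b,
                mean_a=float(mean_a),
                mean_b=float(mean_b),
                sd_a=float(sd_a),
                sd_b=float(sd_b),
                units=cfg.units,
            )
        )
    return studies


def simulate_ip_risk_studies(cfg: ScenarioConfig) -> list[IPRiskStudy]:
    """k_risk case-control studies of disease risk per biomarker increment.

    Disease risk is logistic in the biomarker with slope
    ``risk_slope_per_unit``; with Gaussian biomarker levels this makes case
    levels N(mu + slope*sd^2, sd^2) against control levels N(mu, sd^2).  Each
    study is analysed by logistic regression and its OR reported per an
    increment drawn from ``delta_ip_choices`` (absolute units, or percent of
    the control mean when the scenario mode is percent_change).
    """
    rng = _rng(cfg, "risk")
    sd = cfg.biomarker_sd
    mu = cfg.biomarker_mean_b
    slope = cfg.risk_slope_per_unit
    studies = []
    for i in range(cfg.k_risk):
        n1 = int(rng.integers(*cfg.risk_case_range, endpoint=True))
        n0 = int(rng.integers(*cfg.risk_control_range, endpoint=True))
        x0 = rng.normal(mu, sd, n0)
        x1 = rng.normal(mu + slope * sd * sd, sd, n1)
        x = np.concatenate([x0, x1])
        y = np.concatenate([np.zeros(n0), np.ones(n1)])
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        beta, se = float(fit.params[1]), float(fit.bse[1])
        if cfg.mode == MODE_PERCENT:
            # report per percent change relative to the control mean
            ref = float(np.mean(x0))
            beta, se = beta * ref / 100.0, se * ref / 100.0
        delta = float(rng.choice(cfg.delta_ip_choices))
        log_lo = (beta - 1.96 * se) * delta
        log_hi = (beta + 1.96 * se) * delta
        if delta < 0:
            log_lo, log_hi = log_hi, log_lo
        studies.append(
            IPRiskStudy(
                study_id=f"risk{i + 1:03d}",
                or_value=math.exp(beta * delta),
                ci_low=math.exp(log_lo),
                ci_high=math.exp(log_hi),
                delta_ip=delta,
                n_cases=n1,
                n_controls=n0,
            )
        )
    return studies


@dataclass(frozen=True)
class ScenarioBundle:
    """The three simulated study collections plus their generating truth."""

    genotype_studies: list[GenotypeStudy]
    biomarker_studies: list[BiomarkerStudy]
    ip_risk_studies: list[IPRiskStudy]
    ground_truth: dict


def simulate_triangulation_scenario(cfg: ScenarioConfig) -> ScenarioBundle:
    """Genotype -> biomarker -> risk chain with known mediation structure.

    The genotype studies are generated at the marginal log-OR implied by the
    chain (slope * shift + direct effect), so a fully-mediated configuration
    (direct_genotype_effect = 0) yields concordant expected and observed risk
    while an opposing direct effect yields discordance.
    """
    truth_log_or = cfg.chain_log_or
    delta = cfg.delta_true
    expected_log = cfg.risk_slope_per_unit * delta
    truth = {
        "delta_x": delta if cfg.mode == MODE_ABSOLUTE
        else 100.0 * delta / cfg.biomarker_mean_b,
        "observed_log_or": truth_log_or,
        "expected_log_or": expected_log,
        "observed_or": math.exp(truth_log_or),
        "expected_or": math.exp(expected_log),
        "risk_slope_per_unit": cfg.risk_slope_per_unit,
        "direct_genotype_effect": cfg.direct_genotype_effect,
        "mode": cfg.mode,
    }
    return ScenarioBundle(
        genotype_studies=simulate_genotype_studies(cfg, true_log_or=truth_log_or),
        biomarker_studies=simulate_biomarker_studies(cfg),
        ip_risk_studies=simulate_ip_risk_studies(cfg),
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# Named presets: the study conditions of the three reference scenarios.
# ---------------------------------------------------------------------------

def fvl_like(seed: int = 0) -> ScenarioConfig:
    """Fully-mediated thrombophilia scenario (factor-V-Leiden-like).

    Carriers of a low-frequency variant (allele frequency 2.5%) shift the
    activated-protein-C resistance ratio by -0.74 against a reference mean of
    3.0 (SD 0.40); a lower ratio raises stroke risk (log-OR ln(1.30)/-0.74
    per unit), with no direct genotype effect, so the marginal carrier OR is
    1.30 and expected and observed risk should agree.
    """
    return ScenarioConfig(seed=seed)


def pai1_like(seed: int = 0) -> ScenarioConfig:
    """Pleiotropy scenario (PAI-1-like): biomarker predicts the wrong way.

    The rarer homozygote lowers the biomarker by ~25% (15 vs 20 arbitrary
    units, SD 8) while higher levels raise risk (log-OR 0.047 per unit), yet a
    direct genotype effect pushes the marginal hom-vs-hom OR up to 1.30; the
    biomarker-predicted OR (~0.79) is therefore discordant with observation.
    Percent-change mode, as for analytes reported in incommensurable units.
    """
    slope = 0.047
    delta = 15.0 - 20.0
    direct = math.log(1.30) - slope * delta
    return ScenarioConfig(
        seed=seed,
        k_genotype=15,
        k_biomarker=8,
        k_risk=4,
        allele_freq=0.5,
        model=GeneticModel.HOM_VS_HOM,
        mode=MODE_PERCENT,
        study_size_range=(200, 800),
        control_ratio=2.0,
        biomarker_cohort_range=(200, 1200),
        risk_case_range=(500, 1500),
        risk_control_range=(1000, 5000),
        biomarker_mean_a=15.0,
        biomarker_mean_b=20.0,
        biomarker_sd=8.0,
        units="ng/ml",
        risk_slope_per_unit=slope,
        direct_genotype_effect=direct,
        delta_ip_choices=(10.0, 20.0, 25.0),  # percent increments
        polymorphism_id="pai1_4g5g_sim",
    )


def null_scenario(seed: int = 0) -> ScenarioConfig:
    """No genotype effect anywhere: OR 1, no biomarker shift, no risk slope."""
    return ScenarioConfig(
        seed=seed,
        true_or=1.0,
        tau2=0.0,
        biomarker_mean_a=3.0,
        biomarker_mean_b=3.0,
        risk_slope_per_unit=0.0,
        polymorphism_id="null_sim",
    )


PRESETS = {"fvl_like": fvl_like, "pai1_like": pai1_like, "null": null_scenario}
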