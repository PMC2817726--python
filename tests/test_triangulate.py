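import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokemeta import (
    BiomarkerStudy,
    IPRiskStudy,
    concordance_verdict,
    expected_or,
    pool_ip_shift,
    rescale_or,
    run_triangulation,
    se_from_ci,
)
from strokemeta.simulate import fvl_like, pai1_like, simulate_triangulation_scenario

from ._oracles import re_pool


def bio(mean_a, mean_b, n=100, sd=0.4, units="APTT ratio", sid="b1"):
    return BiomarkerStudy(
        study_id=sid, genotype_a="carrier", genotype_b="hom-wild",
        n_a=n, n_b=n, mean_a=mean_a, mean_b=mean_b, sd_a=sd, sd_b=sd, units=units,
    )


def risk(or_value, lo, hi, delta_ip, sid="r1"):
    return IPRiskStudy(
        study_id=sid, or_value=or_value, ci_low=lo, ci_high=hi,
        delta_ip=delta_ip, n_cases=500, n_controls=1000,
    )


class TestPoolIpShift:
    def test_identical_studies_recover_shift(self):
        studies = [bio(2.26, 3.0, sid="b1"), bio(2.26, 3.0, sid="b2")]
        delta, (lo, hi), _ = pool_ip_shift(studies, "absolute")
        assert delta == pytest.approx(-0.74, abs=1e-12)
        assert lo < delta < hi

    def test_percent_change_arithmetic(self):
        delta, _, res = pool_ip_shift([bio(7.5, 10.0, units="ng/ml")], "percent_change")
        assert delta == pytest.approx(-25.0, abs=1e-12)
        assert res.scale == "percent_change"

    def test_order_invariant(self):
        studies = [bio(2.1, 3.0, n=80, sid="b1"), bio(2.4, 2.9, n=200, sid="b2"),
                   bio(2.3, 3.1, n=50, sid="b3")]
        d1, _, _ = pool_ip_shift(studies)
        d2, _, _ = pool_ip_shift(studies[::-1])
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_unit_mismatch_rejected_in_absolute_mode(self):
        studies = [bio(2.26, 3.0, sid="b1"), bio(2.26, 3.0, units="nmol/L", sid="b2")]
        with pytest.raises(ValueError, match="units"):
            pool_ip_shift(studies, "absolute")


class TestRescaleOr:
    def test_identity_when_delta_matches_increment(self):
        s = risk(2.0, 1.5, 2.67, delta_ip=1.0)
        log_or, se = rescale_or(s, delta_x=1.0)
        assert log_or == pytest.approx(math.log(2.0), abs=1e-12)
        assert se == pytest.approx(se_from_ci(2.0, 1.5, 2.67), abs=1e-12)

    def test_doubling_increment_squares_or(self):
        s = risk(2.0, 1.5, 2.67, delta_ip=1.0)
        log_or, _ = rescale_or(s, delta_x=2.0)
        assert math.exp(log_or) == pytest.approx(4.0, abs=1e-10)

    def test_sign_reversal_inverts_or(self):
        s = risk(2.0, 1.5, 2.67, delta_ip=1.0)
        log_or, se = rescale_or(s, delta_x=-1.0)
        assert math.exp(log_or) == pytest.approx(0.5, abs=1e-10)
        assert se > 0

    @given(st.floats(0.1, 5.0), st.floats(-3.0, 3.0).filter(lambda f: abs(f) > 0.05))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_recovers_original(self, delta_ip, f):
        s = risk(1.8, 1.4, 2.32, delta_ip=delta_ip)
        log1, se1 = rescale_or(s, delta_x=f * delta_ip)
        # invert: rescale the scaled estimate back by 1/f
        log0, se0 = log1 / f, se1 / abs(f)
        assert log0 == pytest.approx(math.log(1.8), rel=1e-10)
        assert se0 == pytest.approx(se_from_ci(1.8, 1.4, 2.32), rel=1e-10)

    def test_asymmetric_ci_warns_and_widens(self):
        with pytest.warns(UserWarning, match="asymmetric"):
            se = se_from_ci(2.0, 1.8, 2.9)
        assert se == pytest.approx(math.log(2.9 / 2.0) / 1.96, rel=1e-10)


class TestExpectedOr:
    def test_single_study_pass_through(self):
        s = risk(1.31, 1.11, 1.546, delta_ip=-0.74)
        orv, (lo, hi), _ = expected_or([s], delta_x=-0.74)
        assert orv == pytest.approx(1.31, rel=1e-10)
        assert lo == pytest.approx(1.11, rel=1e-3)
        assert hi == pytest.approx(1.546, rel=1e-3)

    def test_replication_narrows_ci(self):
        s = risk(1.31, 1.11, 1.546, delta_ip=-0.74)
        many = [risk(1.31, 1.11, 1.546, delta_ip=-0.74, sid=f"r{i}") for i in range(4)]
        or1, (lo1, hi1), _ = expected_or([s], -0.74)
        or4, (lo4, hi4), _ = expected_or(many, -0.74)
        assert or4 == pytest.approx(or1, rel=1e-10)
        assert (hi4 - lo4) < (hi1 - lo1)

    def test_mixed_increments_match_hand_pooling(self):
        studies = [
            risk(1.5, 1.2, 1.875, delta_ip=1.0, sid="r1"),
            risk(2.2, 1.6, 3.02, delta_ip=2.0, sid="r2"),
            risk(1.2, 1.05, 1.37, delta_ip=0.5, sid="r3"),
        ]
        delta_x = 1.4
        ys, ses = [], []
        for s in studies:
            f = delta_x / s.delta_ip
            se = (math.log(s.ci_high) - math.log(s.ci_low)) / (2 * 1.96)
            ys.append(f * math.log(s.or_value))
            ses.append(abs(f) * se)
        mu, se_p = re_pool(ys, ses)
        orv, (lo, hi), _ = expected_or(studies, delta_x)
        assert math.log(orv) == pytest.approx(mu, abs=1e-10)
        assert math.log(hi) == pytest.approx(mu + 1.96 * se_p, abs=1e-10)

    def test_unit_equivariance(self):
        # expressing delta_ip and delta_x in different but consistent units
        studies_u = [risk(1.5, 1.2, 1.875, delta_ip=1.0, sid="r1"),
                     risk(1.8, 1.3, 2.49, delta_ip=2.0, sid="r2")]
        studies_v = [risk(1.5, 1.2, 1.875, delta_ip=10.0, sid="r1"),
                     risk(1.8, 1.3, 2.49, delta_ip=20.0, sid="r2")]
        or_u, ci_u, _ = expected_or(studies_u, 1.4)
        or_v, ci_v, _ = expected_or(studies_v, 14.0)
        assert or_u == pytest.approx(or_v, rel=1e-12)
        assert ci_u == pytest.approx(ci_v, rel=1e-12)


class TestConcordanceVerdict:
    def test_published_fvl_summary_concordant(self):
        v = concordance_verdict((1.31, (1.11, 1.54)), (1.30, (1.11, 1.51)))
        assert v.verdict == "concordant"
        assert v.expected_within_observed and v.observed_within_expected

    def test_disjoint_intervals_discordant(self):
        v = concordance_verdict((0.90, (0.85, 0.95)), (1.30, (1.11, 1.51)))
        assert v.verdict == "discordant"
        assert not v.expected_within_observed

    def test_identity_concordant(self):
        v = concordance_verdict((1.3, (1.1, 1.5)), (1.3, (1.1, 1.5)))
        assert v.verdict == "concordant"


class TestRunTriangulation:
    def test_hand_computed_single_study_chain(self):
        import strokemeta as sm

        geno = [
            sm.GenotypeStudy(
                study_id="g1", polymorphism_id="p", disease="stroke", year=2000,
                case_counts=(10, 52, 438), control_counts=(5, 44, 451),
            )
        ]
        biom = [bio(2.26, 3.0, n=500)]
        ips = [risk(1.31, 1.11, 1.546, delta_ip=-0.74)]
        res = run_triangulation(geno, biom, ips, "dominant", "absolute")
        # observed: single 2x2 dominant table
        e = sm.study_effect(geno[0], "dominant")
        assert res.observed_or == pytest.approx(math.exp(e.log_or), rel=1e-12)
        # expected: identity rescale (delta_x == delta_ip up to sampling noise)
        f = res.delta_x / -0.74
        assert math.log(res.expected_or) == pytest.approx(f * math.log(1.31), rel=1e-10)
        assert res.mode == "absolute"

    def test_fully_mediated_scenario_concordant(self):
        b = simulate_triangulation_scenario(fvl_like(11))
        res = run_triangulation(
            b.genotype_studies, b.biomarker_studies, b.ip_risk_studies,
            "dominant", "absolute",
        )
        assert res.verdict.verdict == "concordant"
        assert abs(math.log(res.expected_or) - math.log(res.observed_or)) < 0.15

    def test_pleiotropy_scenario_discordant(self):
        b = simulate_triangulation_scenario(pai1_like(11))
        res = run_triangulation(
            b.genotype_studies, b.biomarker_studies, b.ip_risk_studies,
            "hom_vs_hom", "percent_change",
        )
        assert res.verdict.verdict == "discordant"
        assert res.expected_or < 1 < res.observed_or

    def test_stage_errors_are_labelled(self):
        import strokemeta as sm

        geno = [
            sm.GenotypeStudy(
                study_id="g1", polymorphism_id="p", disease="stroke", year=2000,
                case_counts=(10, 52, 438), control_counts=(5, 44, 451),
            )
        ]
        biom = [bio(2.26, 3.0, sid="b1"), bio(2.26, 3.0, units="other", sid="b2")]
        with pytest.raises(RuntimeError, match="biomarker-shift stage"):
            run_triangulation(geno, biom, [], "dominant")
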