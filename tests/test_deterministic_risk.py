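"""Deterministic intake chain: CDI, RfD, HQ, HI, LCR and the cohort table."""

import numpy as np
import pytest

from indoair import deterministic_risk as det

M16_21 = det.DEFAULT_COHORTS[0]
BC_FINE_MG = det.ug_to_mg_per_m3(2.94) * det.BC_FINE_FRACTION


def naive_chain(CA, IR_daily, ET, EF, ED, BW, AT_years, RfC=None, SF=None):
    """Independent straight-line evaluation of the intake chain (oracle)."""
    cdi = CA * (IR_daily / 24.0) * ET * EF * ED / (BW * AT_years * 365.0)
    out = {"CDI": cdi}
    if RfC is not None:
        rfd = RfC * IR_daily / BW
        out["RfD"] = rfd
        out["HQ"] = cdi / rfd
    if SF is not None:
        out["LCR"] = cdi * SF
    return out


class TestChronicDailyIntake:
    def test_zero_concentration_gives_zero_intake(self):
        f = det.ExposureFactors(0, 17.21, 8, 313, 35, 77.3, 70)
        assert det.chronic_daily_intake(f) == 0

    def test_fine_bc_intake_for_young_males(self):
        f = det.ExposureFactors(BC_FINE_MG, 17.21, 8, 313, 35, 77.3, 70)
        assert det.chronic_daily_intake(f) == pytest.approx(6.24e-5, rel=1e-3)

    def test_pm10_intake_noncarcinogenic_convention(self):
        f = det.ExposureFactors(0.13129, 17.21, 8, 313, 35, 77.3, 35)
        assert det.chronic_daily_intake(f) == pytest.approx(8.355e-3, rel=1e-3)

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            det.ExposureFactors(0.1, -1, 8, 313, 35, 77.3, 35)
        with pytest.raises(ValueError):
            det.ExposureFactors(0.1, 17, 25, 313, 35, 77.3, 35)


class TestReferenceDose:
    def test_cpcb_pm10_for_young_males(self):
        g = det.lookup_guideline("PM10", "CPCB", "24h")
        assert det.reference_dose(g, M16_21) == pytest.approx(2.226e-2, rel=1e-3)

    def test_linearity_in_rfc(self):
        g = det.Guideline("PM10", "CPCB", "24h", 0.2)
        half = det.Guideline("PM10", "CPCB", "24h", 0.1)
        assert det.reference_dose(g, M16_21) == pytest.approx(
            2 * det.reference_dose(half, M16_21)
        )

    def test_ir_equal_bw_returns_rfc(self):
        c = det.CohortGroup("male", "30-40", 50.0, 50.0)
        g = det.Guideline("PM10", "CPCB", "24h", 0.123)
        assert det.reference_dose(g, c) == pytest.approx(0.123)

    def test_unknown_guideline_errors(self):
        with pytest.raises(KeyError):
            det.lookup_guideline("PM10", "EPA", "24h")


class TestHazardQuotient:
    @pytest.mark.parametrize(
        "ca_ug, pollutant, rfc_agency, expected",
        [
            (131.29, "PM10", ("CPCB", "24h"), 0.375),
            (54.51, "PM2.5", ("CPCB", "24h"), 0.2597),
        ],
    )
    def test_study_period_values(self, ca_ug, pollutant, rfc_agency, expected):
        g = det.lookup_guideline(pollutant, *rfc_agency)
        f = det.ExposureFactors(det.ug_to_mg_per_m3(ca_ug), M16_21.IR_daily, 8, 313, 35, M16_21.BW, 35)
        assert det.hazard_quotient(f, g, M16_21) == pytest.approx(expected, abs=1e-3)

    def test_unit_quotient_at_reference_conditions(self):
        g = det.Guideline("PM10", "CPCB", "24h", 0.1)
        f = det.ExposureFactors(0.1, M16_21.IR_daily, 24, 365, 35, M16_21.BW, 35)
        assert det.hazard_quotient(f, g, M16_21) == pytest.approx(1.0)

    def test_cohort_independence(self):
        # IR and BW cancel between CDI and RfD; HQ depends only on CA, RfC, ET, EF
        rng = np.random.default_rng(5)
        g = det.lookup_guideline("PM10", "CPCB", "24h")
        values = []
        for _ in range(20):
            c = det.CohortGroup("male", "30-40", rng.uniform(5, 30), rng.uniform(40, 120))
            f = det.ExposureFactors(0.13129, c.IR_daily, 8, 313, 35, c.BW, 35)
            values.append(det.hazard_quotient(f, g, c))
        np.testing.assert_allclose(values, values[0], rtol=1e-12)

    def test_requires_at_equal_ed(self):
        g = det.lookup_guideline("PM10", "CPCB", "24h")
        f = det.ExposureFactors(0.1, M16_21.IR_daily, 8, 313, 35, M16_21.BW, 70)
        with pytest.raises(ValueError, match="AT"):
            det.hazard_quotient(f, g, M16_21)

    def test_cross_guideline_rescaling_exact(self):
        # HQ_WHO / HQ_CPCB equals RfC_CPCB / RfC_WHO: 8x for PM2.5, 4x for PM10 annual
        for pol, factor in [("PM2.5", 8.0), ("PM10", 4.0)]:
            cpcb = det.lookup_guideline(pol, "CPCB", "annual")
            who = det.lookup_guideline(pol, "WHO", "annual")
            f = det.ExposureFactors(0.05, M16_21.IR_daily, 8, 313, 35, M16_21.BW, 35)
            hq_c = det.hazard_quotient(f, cpcb, M16_21)
            hq_w = det.hazard_quotient(f, who, M16_21)
            assert hq_w / hq_c == pytest.approx(factor, rel=1e-12)


class TestHazardIndex:
    def test_annual_addends_sum(self):
        assert det.hazard_index([0.987, 0.737, 2.25e-4]) == pytest.approx(1.72, abs=5e-3)

    def test_empty_and_simple(self):
        assert det.hazard_index([]) == 0
        assert det.hazard_index([0.5, 0.5]) == 1.0


class TestLifetimeCancerRisk:
    #: (sex, age_band, printed 3-significant-figure LCR) for fine-fraction BC
    TABLE = [
        ("male", "16-21", 6.86e-5),
        ("male", "21-30", 6.83e-5),
        ("male", "30-40", 7.19e-5),
        ("male", "40-50", 7.13e-5),
        ("male", "50-60", 7.20e-5),
        ("female", "16-21", 6.35e-5),
        ("female", "21-30", 6.24e-5),
        ("female", "30-40", 6.17e-5),
        ("female", "40-50", 6.47e-5),
        ("female", "50-60", 6.44e-5),
    ]

    @pytest.mark.parametrize("sex, band, expected", TABLE)
    def test_all_cohort_cells_to_3_significant_figures(self, sex, band, expected):
        c = next(x for x in det.DEFAULT_COHORTS if x.sex == sex and x.age_band == band)
        f = det.ExposureFactors(BC_FINE_MG, c.IR_daily, 8, 313, 35, c.BW, 70)
        lcr = det.lifetime_cancer_risk(f)
        assert lcr == pytest.approx(expected, abs=0.005e-5)

    def test_zero_slope_factor(self):
        f = det.ExposureFactors(BC_FINE_MG, 17.21, 8, 313, 35, 77.3, 70)
        assert det.lifetime_cancer_risk(f, slope_factor=0.0) == 0

    def test_monotone_in_each_factor(self):
        base = dict(CA=BC_FINE_MG, IR_daily=17.21, ET=8, EF=313, ED=35, BW=77.3, AT_years=70)
        lcr0 = det.lifetime_cancer_risk(det.ExposureFactors(**base))
        for name, sign in [("CA", 1), ("ET", 1), ("EF", 1), ("ED", 1), ("BW", -1), ("AT_years", -1)]:
            bumped = dict(base, **{name: base[name] * 1.01})
            delta = det.lifetime_cancer_risk(det.ExposureFactors(**bumped)) - lcr0
            assert np.sign(delta) == sign, name
        assert det.lifetime_cancer_risk(det.ExposureFactors(**base), 1.2) > lcr0


class TestClassifyRisk:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            ({"lcr": 1e-7}, "negligible"),
            ({"lcr": 7.2e-5}, "considerable"),
            ({"lcr": 2e-4}, "high"),
            ({"hq": 1.72}, "significant_noncancer"),
            ({"hq": 0.5}, "acceptable"),
        ],
    )
    def test_thresholds(self, kwargs, expected):
        assert det.classify_risk(**kwargs) == expected

    def test_neither_populated_errors(self):
        with pytest.raises(ValueError):
            det.classify_risk()


class TestCohortRiskTable:
    def test_lcr_span_matches_reported_range(self):
        tab = det.cohort_risk_table(
            {"BC": BC_FINE_MG}, slope_factors={"BC": det.DEFAULT_SLOPE_FACTOR}
        )
        assert tab["LCR"].min() == pytest.approx(6.17e-5, abs=0.005e-5)
        assert tab["LCR"].max() == pytest.approx(7.20e-5, abs=0.005e-5)

    def test_lcr_ordering_follows_ir_over_bw(self):
        tab = det.cohort_risk_table(
            {"BC": BC_FINE_MG}, slope_factors={"BC": det.DEFAULT_SLOPE_FACTOR}
        )
        ratio = [c.IR_daily / c.BW for c in det.DEFAULT_COHORTS]
        assert list(np.argsort(tab["LCR"].to_numpy())) == list(np.argsort(ratio))

    def test_identical_cohorts_identical_lcr(self):
        cohorts = [
            det.CohortGroup("male", "16-21", 17.0, 70.0),
            det.CohortGroup("female", "30-40", 17.0, 70.0),
        ]
        tab = det.cohort_risk_table(
            {"BC": BC_FINE_MG}, cohorts=cohorts, slope_factors={"BC": 1.1}
        )
        assert tab["LCR"].iloc[0] == tab["LCR"].iloc[1]

    def test_missing_guideline_errors(self):
        with pytest.raises(KeyError):
            det.cohort_risk_table({"PM10": 0.1})


class TestOracleEquivalence:
    def test_brute_force_agreement_on_random_factor_sets(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            CA = rng.uniform(1e-4, 1.0)
            IR = rng.uniform(5, 30)
            ET = rng.uniform(1, 24)
            EF = rng.uniform(1, 366)
            ED = rng.uniform(1, 70)
            BW = rng.uniform(40, 120)
            AT = rng.uniform(1, 80)
            RfC = rng.uniform(0.001, 5)
            SF = rng.uniform(0.1, 5)
            oracle = naive_chain(CA, IR, ET, EF, ED, BW, AT, RfC=RfC, SF=SF)
            f = det.ExposureFactors(CA, IR, ET, EF, ED, BW, AT)
            assert det.chronic_daily_intake(f) == pytest.approx(oracle["CDI"], rel=1e-12)
            g = det.Guideline("PM10", "CPCB", "24h", RfC)
            c = det.CohortGroup("male", "30-40", IR, BW)
            assert det.reference_dose(g, c) == pytest.approx(oracle["RfD"], rel=1e-12)
            f_nc = det.ExposureFactors(CA, IR, ET, EF, ED, BW, ED)
            oracle_nc = naive_chain(CA, IR, ET, EF, ED, BW, ED, RfC=RfC)
            assert det.hazard_quotient(f_nc, g, c) == pytest.approx(
                oracle_nc["HQ"], rel=1e-12
            )
            assert det.lifetime_cancer_risk(f, SF) == pytest.approx(
                oracle["LCR"], rel=1e-12
            )
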