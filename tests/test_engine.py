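"""Equation-level and property tests for the risk engine.

Expected values for the worked examples were either taken from the published
case-study tables or computed by hand division (frozen here).
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srftox import (
    Direction,
    EndpointKind,
    Medium,
    MediumKind,
    RiskClass,
    SrfToxError,
    ToxicityEndpoint,
    ValidationError,
    assess,
    classify,
    compare_batch,
    persistence_coefficient,
    pnec,
    risk_quotient,
    synthetic_risk_factor,
    validate_record,
)

positive = st.floats(
    min_value=1e-8, max_value=1e12, allow_nan=False, allow_infinity=False
)


class TestPersistenceCoefficient:
    @pytest.mark.parametrize(
        "half_life, t_cv, expected",
        [
            (8, 60, 7.5),  # carbendazim
            (60, 60, 1.0),  # half-life equals boundary value
            (151, 60, 60 / 151),  # imazalil
        ],
    )
    def test_examples(self, half_life, t_cv, expected):
        assert persistence_coefficient(half_life, t_cv) == pytest.approx(
            expected, rel=1e-12
        )

    def test_bisphenol_a_matches_published_two_sig_figs(self):
        c = persistence_coefficient(4.02e6, 60)
        assert c == pytest.approx(1.4925e-5, rel=1e-4)
        assert float(f"{c:.1e}") == 1.5e-5

    @pytest.mark.parametrize("args", [(0, 60), (-1, 60), (8, 0), (math.inf, 60)])
    def test_non_positive_rejected(self, args):
        with pytest.raises(ValidationError):
            persistence_coefficient(*args)


class TestPnec:
    @pytest.mark.parametrize(
        "kind, value, expected",
        [
            (EndpointKind.ACUTE_EC50, 1.0e6, 1000.0),
            (EndpointKind.CHRONIC_CHV, 100.0, 1.0),
            # back-calculated acute LC50 reproducing imazalil's PNEC of 92 ng/L
            (EndpointKind.ACUTE_LC50, 9.2e4, 92.0),
        ],
    )
    def test_assessment_factor_division(self, kind, value, expected):
        assert pnec(ToxicityEndpoint(kind, value)) == expected


class TestRiskQuotient:
    def test_imazalil_rounds_to_published_value(self):
        assert round(risk_quotient(61.01, 92), 2) == 0.66

    def test_zero_exposure_zero_risk(self):
        assert risk_quotient(0, 123.4) == 0.0

    def test_carbendazim_hand_division(self):
        assert risk_quotient(2.78, 1.5) == pytest.approx(1.85333333, rel=1e-8)

    def test_non_positive_pnec_rejected(self):
        with pytest.raises(ValidationError):
            risk_quotient(1.0, 0.0)


class TestSyntheticRiskFactor:
    def test_imazalil_with_table_rounded_c(self):
        assert round(synthetic_risk_factor(61.01, 92, 0.40), 2) == 1.66

    def test_testosterone_hand_arithmetic(self):
        # 6.5/100/5.1e-3 = 12.745…: minimal exposure quotient but high SRF
        srf = synthetic_risk_factor(6.5, 100, 5.1e-3)
        assert srf == pytest.approx(12.745098, rel=1e-6)
        assert classify(srf) == RiskClass.HIGH

    def test_non_positive_c_rejected(self):
        with pytest.raises(ValidationError):
            synthetic_risk_factor(1, 1, 0)

    @given(mec=positive, p=positive)
    @settings(max_examples=50, deadline=None)
    def test_unit_persistence_collapses_to_rq(self, mec, p):
        assert synthetic_risk_factor(mec, p, 1.0) == risk_quotient(mec, p)

    @given(mec=positive, p=positive, c=positive)
    @settings(max_examples=100, deadline=None)
    def test_identity_srf_equals_rq_over_c(self, mec, p, c):
        assert synthetic_risk_factor(mec, p, c) == pytest.approx(
            risk_quotient(mec, p) / c, rel=1e-12
        )

    @given(mec=positive, p=positive, c=positive, scale=positive)
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_under_joint_unit_change(self, mec, p, c, scale):
        base = synthetic_risk_factor(mec, p, c)
        scaled = synthetic_risk_factor(mec * scale, p * scale, c)
        assert scaled == pytest.approx(base, rel=1e-9)

    @given(
        mec=positive, p=positive, t_cv=positive,
        hl_low=positive, factor=st.floats(min_value=1.0 + 1e-9, max_value=1e6),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_half_life(self, mec, p, t_cv, hl_low, factor):
        """Longer persistence ⇒ higher assessed risk at fixed MEC and PNEC."""
        srf_low = synthetic_risk_factor(
            mec, p, persistence_coefficient(hl_low, t_cv)
        )
        srf_high = synthetic_risk_factor(
            mec, p, persistence_coefficient(hl_low * factor, t_cv)
        )
        assert srf_high > srf_low


class TestClassify:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0.0, RiskClass.NEGLIGIBLE),
            (0.005, RiskClass.NEGLIGIBLE),
            (0.01, RiskClass.NEGLIGIBLE),  # explicitly inclusive
            (0.010001, RiskClass.MINIMAL),
            (0.05, RiskClass.MINIMAL),
            (0.1, RiskClass.MEDIUM),  # boundary assigned to the higher band
            (0.99, RiskClass.MEDIUM),
            (1.0, RiskClass.HIGH),
            (1.66, RiskClass.HIGH),
        ],
    )
    def test_band_edges(self, value, band):
        assert classify(value) == band

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            classify(-0.1)

    @given(a=st.floats(min_value=0, max_value=100), b=st.floats(min_value=0, max_value=100))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_value(self, a, b):
        if a <= b:
            assert classify(a) <= classify(b)


def _record(**kw):
    base = dict(name="T", half_life=10, medium="water", mec=1.0, pnec=1.0)
    base.update(kw)
    return validate_record(base)


class TestAssess:
    def test_carbendazim_reclassified_down(self, ebro):
        res = assess(ebro[0])
        assert res.compound.name == "Carbendazim"
        assert (res.rq_class, res.srf_class) == (RiskClass.HIGH, RiskClass.MEDIUM)
        assert res.direction == Direction.DOWN and res.reclassified

    def test_imazalil_reclassified_up(self, ebro):
        res = assess(ebro[3])
        assert res.compound.name == "Imazalil"
        assert (res.rq_class, res.srf_class) == (RiskClass.MEDIUM, RiskClass.HIGH)
        assert res.direction == Direction.UP

    def test_tep_negligible_both_ways(self, tianjin_bohai):
        res = assess(tianjin_bohai[2])
        assert res.compound.name.startswith("Triethyl")
        assert res.rq == pytest.approx(1.683 / 9.0e5, rel=1e-9)
        assert res.rq_class == res.srf_class == RiskClass.NEGLIGIBLE
        assert res.direction == Direction.UNCHANGED

    def test_endpoint_route_derives_pnec(self):
        res = assess(_record(pnec=None, endpoint_kind="acute_ec50",
                             endpoint_value_ng_per_l="1e6"))
        assert res.pnec_ng_per_l == 1000.0

    def test_table_rounded_without_reference_rounds_computed_c(self):
        res = assess(_record(half_life=151), rounding_mode="table_rounded")
        assert res.c == 0.40

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            assess(_record(), rounding_mode="approximate")


class TestCompareBatch:
    def test_ebro_exactly_three_reclassified(self, ebro):
        cmp = compare_batch(ebro)
        moved = {r.compound.name: r.direction for r in cmp.reclassified}
        assert moved == {
            "Carbendazim": Direction.DOWN,
            "Hexythiazox": Direction.DOWN,
            "Imazalil": Direction.UP,
        }
        assert cmp.n_reclassified_up == 1 and cmp.n_reclassified_down == 2

    def test_order_preserved(self, ebro):
        cmp = compare_batch(ebro)
        assert [r.compound.name for r in cmp.results] == [r.name for r in ebro]

    def test_single_record_counts(self):
        cmp = compare_batch([_record(mec=5.0)])
        assert cmp.rq_class_counts[RiskClass.HIGH] == 1
        assert sum(cmp.rq_class_counts.values()) == 1

    def test_empty_input_raises(self):
        with pytest.raises(SrfToxError) as err:
            compare_batch([])
        assert err.value.code == "empty-after-validation"
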