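"""Parameter loading, validation, RRR derivation and the pandemic overlay."""

import io
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mouthwash_cea import (CONTROL, INTERVENTION, CovidOverlay, ParameterSet,
                           ProbabilityParam, ValidationError,
                           apply_covid_overlay, beta_from_counts,
                           derive_intervention_arm, load_parameter_set)
from mouthwash_cea.parameters import PROB_NODES, RRR_SCALED_NODES


class TestFixtureLoading:
    def test_control_pneumonia_counts(self, params):
        p = params.probabilities[(CONTROL, "pneumonia")]
        assert (p.events, p.total) == (39, 931)
        assert p.value == pytest.approx(39 / 931)

    def test_counts_match_printed_values_within_rounding(self, params):
        # Stored full-precision values are within the 2-dp print tolerance
        # of events/total for every count-backed row.
        for (arm, node), p in params.probabilities.items():
            if p.events is not None:
                assert abs(p.value - p.events / p.total) <= 0.005

    def test_completeness_error_names_missing_cost(self, params):
        costs = {k: v for k, v in params.costs.items() if k != "icu_day"}
        broken = ParameterSet(params.probabilities, costs, params.los)
        with pytest.raises(ValidationError, match="icu_day"):
            broken.validate()

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValidationError, match="pneumonia"):
            ProbabilityParam("pneumonia", 1.2)

    def test_bad_fixture_value_rejected(self):
        rows = io.StringIO(
            "name,arm,printed_value,events,total,distribution,derivation\n"
            "pneumonia,no_mouthwash,1.2,,,fixed,source\n"
        )
        with pytest.raises(ValidationError):
            load_parameter_set(probabilities=rows)

    def test_round_trip_serialization(self, params):
        again = ParameterSet.from_json(params.to_json())
        assert again.to_dict() == params.to_dict()
        assert again.prob(CONTROL, "pn_ccu") == params.prob(CONTROL, "pn_ccu")


class TestBetaFromCounts:
    def test_count_parameterization_and_mean(self):
        spec = beta_from_counts(39, 931)
        assert (spec.alpha, spec.beta) == (39, 892)
        assert spec.mean == pytest.approx(0.04189, abs=5e-6)
        assert not spec.degenerate

    @pytest.mark.parametrize("events,total,corrected",
                             [(0, 10, (0.5, 10.5)), (931, 931, (931.5, 0.5))])
    def test_degenerate_counts_get_continuity_correction(self, events, total, corrected):
        spec = beta_from_counts(events, total)
        assert spec.degenerate
        assert spec.sampling_params() == corrected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            beta_from_counts(11, 10)
        with pytest.raises(ValidationError):
            beta_from_counts(0, 0)


class TestRRRDerivation:
    def test_critical_care_probability_scaled(self, params):
        # 21/39 control critical-care admission scaled by 0.7 prints as 0.38.
        derived = derive_intervention_arm(params, 0.3)
        value = derived.prob(INTERVENTION, "pn_ccu")
        assert value == pytest.approx((21 / 39) * 0.7)
        assert round(value, 2) == 0.38

    def test_death_after_mv_scaled(self, params):
        derived = derive_intervention_arm(params, 0.3)
        value = derived.prob(INTERVENTION, "pn_died_mv")
        assert value == pytest.approx((10 / 21) * 0.7)
        assert round(value, 2) == 0.33

    def test_zero_rrr_is_identity(self, params):
        derived = derive_intervention_arm(params, 0.0)
        for node in PROB_NODES:
            assert derived.prob(INTERVENTION, node) == pytest.approx(
                derived.prob(CONTROL, node))

    def test_non_pneumonia_parameters_copied_unchanged(self, params):
        derived = derive_intervention_arm(params, 0.3)
        for node in PROB_NODES:
            if node not in RRR_SCALED_NODES:
                assert derived.prob(INTERVENTION, node) == derived.prob(CONTROL, node)

    def test_rrr_out_of_range_rejected(self, params):
        with pytest.raises(ValidationError):
            derive_intervention_arm(params, 1.0)

    @settings(max_examples=30, deadline=None)
    @given(r1=st.floats(0, 0.99), r2=st.floats(0, 0.99))
    def test_monotone_in_rrr(self, params, r1, r2):
        lo, hi = sorted((r1, r2))
        a = derive_intervention_arm(params, lo)
        b = derive_intervention_arm(params, hi)
        for node in RRR_SCALED_NODES:
            assert b.prob(INTERVENTION, node) <= a.prob(INTERVENTION, node) + 1e-15


class TestCovidOverlay:
    def test_null_overlay_is_identity(self, params):
        out = apply_covid_overlay(params, CovidOverlay(0.0, 0.0))
        assert out.prob(CONTROL, "pneumonia") == params.prob(CONTROL, "pneumonia")
        assert out.covid_cost_per_patient == 0.0

    def test_absolute_increment(self, params):
        out = apply_covid_overlay(params, CovidOverlay.absolute())
        assert out.prob(CONTROL, "pneumonia") == pytest.approx(39 / 931 + 0.018)

    def test_calibrated_increment_prints_published_proportion(self, params):
        out = apply_covid_overlay(params, CovidOverlay.calibrated())
        assert round(out.prob(CONTROL, "pneumonia"), 3) == 0.045

    def test_overflow_is_an_error_not_a_clamp(self, params):
        high = params.with_probability(CONTROL, "pneumonia", 0.995)
        with pytest.raises(ValidationError):
            apply_covid_overlay(high, CovidOverlay(0.018, 0.0))

    @settings(max_examples=25, deadline=None)
    @given(delta=st.floats(0, 0.5), rrr=st.floats(0, 0.9))
    def test_overlay_commutes_with_rrr_derivation(self, params, delta, rrr):
        # Overlaying the control then deriving equals deriving then adding
        # (1 - rrr) * delta to the intervention pneumonia probability.
        base = derive_intervention_arm(params, rrr)
        overlaid = apply_covid_overlay(base, CovidOverlay(delta, 0.0))
        direct = base.prob(INTERVENTION, "pneumonia") + (1 - rrr) * delta
        assert overlaid.prob(INTERVENTION, "pneumonia") == pytest.approx(direct)
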