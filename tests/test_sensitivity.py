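"""Deterministic sensitivity analysis: sweep, one-way, break-off, extremes."""

import pytest

from mouthwash_cea import (CONTROL, INTERVENTION, GEL_COST, breakoff_search,
                           evaluate_comparison, extreme, full_dsa_table,
                           load_dsa_bounds, one_way, rrr_sweep)
from mouthwash_cea.cea import COMPARATOR_DOMINATES, INTERVENTION_DOMINATES
from mouthwash_cea.parameters import derive_intervention_arm
from mouthwash_cea.sensitivity import DSATarget

RRR001_BENEFIT = 0.01 * 39 / 931  # prints as 0.0004


class TestRRRSweep:
    def test_published_sweep_values(self, params):
        rows = {r.tested_value: r for r in rrr_sweep(params, [0.2, 0.1])}
        assert rows[0.2].delta_cost == pytest.approx(-197, abs=12)
        assert round(rows[0.2].incremental_benefit, 4) == 0.0084
        assert rows[0.1].delta_cost == pytest.approx(-101, abs=10)

    def test_null_effect_limit_costs_the_gel(self, params):
        [row] = rrr_sweep(params, [0.0], with_breakoff=False)
        assert row.delta_cost == pytest.approx(params.cost("chlorhexidine"))
        assert row.incremental_benefit == 0.0

    def test_delta_cost_monotone_nonincreasing_in_rrr(self, params):
        rows = rrr_sweep(params, [0.05, 0.1, 0.2, 0.3], with_breakoff=False)
        deltas = [r.delta_cost for r in rows]
        assert all(b <= a + 1e-9 for a, b in zip(deltas, deltas[1:]))


class TestOneWay:
    def test_bound_equal_to_base_reproduces_base_row(self, params):
        base_ce = evaluate_comparison(derive_intervention_arm(params, 0.01))
        target = DSATarget("cost", "bed_day")
        row = one_way(params, target, params.cost("bed_day"))
        assert row.delta_cost == base_ce.delta_cost
        assert row.incremental_benefit == base_ce.delta_effect

    def test_incremental_benefit_exact_for_non_pneumonia_parameters(self, params):
        # Only the pneumonia split moves the effect axis, so every other
        # one-way row keeps rrr x 39/931 exactly (prints 0.0004).
        for target, lo, hi in load_dsa_bounds():
            if target.name == "pneumonia":
                continue
            for bound in (lo, hi):
                row = one_way(params, target, bound)
                assert row.incremental_benefit == pytest.approx(RRR001_BENEFIT,
                                                                abs=1e-12)
                assert round(row.incremental_benefit, 4) == 0.0004

    def test_published_pneumonia_cost_row(self, params):
        row = one_way(params, DSATarget("cost", "pneumonia_episode"), 121.0)
        assert row.classification == INTERVENTION_DOMINATES
        assert round(row.incremental_benefit, 4) == 0.0004

    def test_lower_control_pneumonia_flips_dominance(self, params):
        row = one_way(params, DSATarget("prob", "pneumonia", CONTROL), 0.03)
        assert row.incremental_benefit == pytest.approx(-0.0115, abs=5e-4)
        assert row.classification == COMPARATOR_DOMINATES

    def test_unknown_parameter_rejected(self, params):
        from mouthwash_cea.parameters import ValidationError
        with pytest.raises(ValidationError):
            one_way(params, DSATarget("prob", "nonexistent", CONTROL), 0.5)


class TestBreakoffSearch:
    def test_gel_cost_breakoff_at_base_rrr(self, params):
        res = breakoff_search(params, GEL_COST, rrr_context=0.3)
        assert res.status == "found"
        assert res.value == pytest.approx(289, abs=15)

    def test_gel_cost_breakoff_at_conservative_rrr(self, params):
        res = breakoff_search(params, GEL_COST, rrr_context=0.01)
        assert res.value == pytest.approx(11, abs=3)

    def test_breakoff_substituted_back_zeroes_delta_cost(self, params):
        res = breakoff_search(params, GEL_COST, rrr_context=0.3)
        base = derive_intervention_arm(params, 0.3)
        ce = evaluate_comparison(GEL_COST.apply(base, res.value))
        assert abs(ce.delta_cost) <= 0.5

    def test_breakoff_consistency_with_base_delta(self, params):
        # Gel break-off ~= current gel cost + |base delta cost|.
        res = breakoff_search(params, GEL_COST, rrr_context=0.3)
        ce = evaluate_comparison(derive_intervention_arm(params, 0.3))
        assert res.value == pytest.approx(
            params.cost("chlorhexidine") + abs(ce.delta_cost), abs=1.0)

    def test_cost_neutral_parameter_has_no_breakoff(self, params):
        # Death probabilities never touch costs (decedents accrue the full
        # class stay), so no sign change exists anywhere in range.
        res = breakoff_search(params, DSATarget("prob", "np_died_ward", CONTROL),
                              rrr_context=0.3)
        assert res.value is None
        assert res.status == "no_breakoff_in_range"


class TestExtremeScenarios:
    def test_no_ventilation_still_dominant_with_small_saving(self, params):
        ce = extreme(params, "no_mv")
        assert ce.classification == INTERVENTION_DOMINATES
        assert -50 < ce.delta_cost < 0
        assert round(ce.delta_effect, 4) == 0.0004

    def test_best_case_dominates(self, params):
        ce = extreme(params, "best_case")
        assert ce.classification == INTERVENTION_DOMINATES
        assert round(ce.delta_effect, 4) == pytest.approx(0.0119, abs=1e-4)

    def test_worst_case_is_dominated(self, params):
        ce = extreme(params, "worst_case")
        assert ce.classification == COMPARATOR_DOMINATES
        assert round(ce.delta_effect, 4) == pytest.approx(-0.0081, abs=1e-4)

    def test_unknown_label_rejected(self, params):
        from mouthwash_cea.parameters import ValidationError
        with pytest.raises(ValidationError):
            extreme(params, "middling_case")


def test_full_dsa_table_shape(params):
    table = full_dsa_table(params)
    bounds = load_dsa_bounds()
    # base + RRR sweep + lower/upper per bound + three extremes
    assert len(table) == 1 + 4 + 2 * len(bounds) + 3
    assert {"parameter", "delta_cost", "delta_cost_zar",
            "incremental_benefit", "classification"} <= set(table.columns)
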