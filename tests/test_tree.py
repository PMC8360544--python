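"""Pathway enumeration, costing, and cohort expected values."""

import dataclasses

import pytest

from mouthwash_cea import (CONTROL, INTERVENTION, enumerate_pathways,
                           evaluate_arm, pathway_cost)
from mouthwash_cea.parameters import LOS_CLASSES, derive_intervention_arm
from mouthwash_cea.tree import PATHWAY_TEMPLATES


def _find(pathways, **labels):
    [match] = [p for p in pathways
               if all(getattr(p, k) == v for k, v in labels.items())]
    return match


class TestEnumeration:
    def test_twelve_terminal_pathways_per_arm(self, params):
        for arm in (CONTROL, INTERVENTION):
            assert len(enumerate_pathways(params, arm)) == 12

    def test_probabilities_sum_to_one(self, params):
        for arm in (CONTROL, INTERVENTION):
            total = sum(p.joint_probability for p in enumerate_pathways(params, arm))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_pneumonia_critical_care_joint_probability(self, params):
        # (39/931) x (21/39) = 21/931 along the control branch.
        joint = sum(p.joint_probability
                    for p in enumerate_pathways(params, CONTROL)
                    if p.pneumonia and p.location == "ccu")
        assert joint == pytest.approx(21 / 931)
        assert joint == pytest.approx(0.02256, abs=5e-6)

    def test_deep_branch_joint_probability(self, params):
        p = _find(enumerate_pathways(params, CONTROL),
                  pneumonia=True, location="ccu", mv=True, outcome="died")
        assert p.joint_probability == pytest.approx(
            (39 / 931) * (21 / 39) * 0.25 * (10 / 21))
        assert p.joint_probability == pytest.approx(0.002686, abs=2e-6)

    def test_effect_coding_complements_pneumonia(self, params):
        for p in enumerate_pathways(params, CONTROL):
            assert p.effect == (0 if p.pneumonia else 1)


class TestPathwayCost:
    def test_ventilated_critical_care_pneumonia_cost(self, params):
        # procedure + pneumonia episode + 21.12 ICU days + ventilation episode
        cost = pathway_cost(params, CONTROL, pneumonia=True, location="ccu", mv=True)
        assert cost == pytest.approx(1423 + 3752 + 21.12 * 1210 + 89)
        assert cost == pytest.approx(30819.20)

    def test_uncomplicated_mouthwash_ward_cost(self, params):
        cost = pathway_cost(params, INTERVENTION, pneumonia=False,
                            location="ward", mv=None)
        assert cost == pytest.approx(1423 + 3 + 6.69 * 71)
        assert cost == pytest.approx(1900.99)

    def test_zero_unit_costs_give_zero_pathway_cost(self, params):
        zeroed = params
        for name in params.costs:
            zeroed = zeroed.with_cost(name, 0.0)
        for t in [(True, "ccu", True), (True, "ward", None), (False, "ccu", False)]:
            assert pathway_cost(zeroed, CONTROL, pneumonia=t[0], location=t[1],
                                mv=t[2]) == 0.0

    def test_decedents_and_survivors_cost_the_same_pathway_class(self, params):
        # Stay lengths are not published by outcome, so cost depends only on
        # (pneumonia, location, mv), never on died/discharged.
        for arm in (CONTROL, INTERVENTION):
            costs = {}
            for p in enumerate_pathways(params, arm):
                key = (p.pneumonia, p.location, p.mv)
                costs.setdefault(key, set()).add(round(p.cost, 6))
            assert all(len(v) == 1 for v in costs.values())


class TestEvaluateArm:
    def test_published_pneumonia_proportions(self, params):
        assert round(evaluate_arm(params, CONTROL).pneumonia_proportion, 3) == 0.042
        assert round(evaluate_arm(params, INTERVENTION).pneumonia_proportion, 3) == 0.029

    def test_published_control_arm_cost(self, params):
        assert evaluate_arm(params, CONTROL).expected_cost == pytest.approx(3958, abs=40)

    def test_delta_proportion_is_rrr_times_control_pneumonia(self, params):
        for rrr in (0.3, 0.2, 0.1, 0.01):
            p = derive_intervention_arm(params, rrr)
            dc = evaluate_arm(p, CONTROL).pneumonia_proportion
            di = evaluate_arm(p, INTERVENTION).pneumonia_proportion
            assert dc - di == pytest.approx(rrr * 39 / 931, abs=1e-12)

    def test_expected_cost_monotone_in_unit_costs_and_stays(self, params):
        base = evaluate_arm(params, CONTROL).expected_cost
        for name in params.costs:
            bumped = params.with_cost(name, params.cost(name) * 1.5)
            assert evaluate_arm(bumped, CONTROL).expected_cost >= base - 1e-9
        for cls in LOS_CLASSES:
            bumped = params.with_los(CONTROL, cls, params.los_days(CONTROL, cls) + 5)
            assert evaluate_arm(bumped, CONTROL).expected_cost >= base - 1e-9

    def test_pathway_frame_is_complete_audit_table(self, params):
        frame = evaluate_arm(params, CONTROL).pathway_frame()
        assert len(frame) == 12
        assert frame["joint_probability"].sum() == pytest.approx(1.0)
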