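"""Decision-tree structure: pathway enumeration and expected values.

Every patient follows one route through a fixed 30-day tree, identical in
shape for both arms: pneumonia {yes, no} -> location {critical care,
general ward} -> (critical care only) mechanical ventilation {yes, no} ->
outcome {died, discharged by 30 days}.  That yields 12 terminal pathways
per arm: six for pneumonia patients and six mirrored no-pneumonia routes.

Costing is additive per pathway: every patient accrues the procedure
cost; mouthwash-arm patients the chlorhexidine doses; pneumonia patients
one pneumonia-episode cost; everyone a per-day ward or critical-care cost
over the mean length of stay of their pathway class; ventilated patients
one ventilation-episode cost; and, in the pandemic scenario, a
per-patient pandemic-practices cost.  Decedents accrue the full class
mean length of stay (stay lengths are not published by outcome).

Effectiveness is the binary complement of pneumonia: a pathway scores 1
if the patient avoided postoperative pneumonia and 0 otherwise, so an
arm's expected effect is one minus its pneumonia proportion.

The probability/cost arithmetic is written against plain lookups so the
same pathway templates serve scalar evaluation here and vectorized
Monte-Carlo draws in :mod:`mouthwash_cea.psa`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .parameters import INTERVENTION, ParameterSet, ValidationError


class PathwayTemplate(NamedTuple):
    """Structural description of one terminal pathway (arm-agnostic)."""

    pneumonia: bool
    location: str            # "ccu" | "ward"
    mv: bool | None          # None on the ward
    outcome: str             # "died" | "discharged"
    #: (probability node, take_complement) factors whose product is the
    #: joint probability of the pathway.
    factors: tuple[tuple[str, bool], ...]
    los_class: str


def _build_templates() -> tuple[PathwayTemplate, ...]:
    templates = []
    for pneumonia in (True, False):
        px = "pn" if pneumonia else "np"
        los_px = "pneumonia" if pneumonia else "nopneumonia"
        pn_factor = ("pneumonia", not pneumonia)
        for died in (True, False):
            outcome = "died" if died else "discharged"
            for mv in (True, False):
                death_node = f"{px}_died_mv" if mv else f"{px}_died_ccu_nomv"
                templates.append(PathwayTemplate(
                    pneumonia, "ccu", mv, outcome,
                    (pn_factor, (f"{px}_ccu", False), (f"{px}_mv", not mv),
                     (death_node, not died)),
                    f"{los_px}_ccu_{'mv' if mv else 'nomv'}",
                ))
            templates.append(PathwayTemplate(
                pneumonia, "ward", None, outcome,
                (pn_factor, (f"{px}_ccu", True), (f"{px}_died_ward", not died)),
                f"{los_px}_ward",
            ))
    return tuple(templates)


PATHWAY_TEMPLATES = _build_templates()


@dataclass(frozen=True)
class Pathway:
    """One terminal route with its joint probability, cost and effect."""

    arm: str
    pneumonia: bool
    location: str
    mv: bool | None
    outcome: str
    joint_probability: float
    cost: float
    effect: int


@dataclass(frozen=True)
class ArmResult:
    """Cohort expected values for one strategy arm."""

    arm: str
    expected_cost: float
    pneumonia_proportion: float
    pathways: tuple[Pathway, ...]

    @property
    def expected_effect(self) -> float:
        return 1.0 - self.pneumonia_proportion

    def pathway_frame(self) -> pd.DataFrame:
        """Audit table: one row per terminal pathway."""
        return pd.DataFrame(
            [
                {
                    "arm": p.arm, "pneumonia": p.pneumonia, "location": p.location,
                    "mv": p.mv, "outcome": p.outcome,
                    "joint_probability": p.joint_probability,
                    "cost": p.cost, "effect": p.effect,
                }
                for p in self.pathways
            ]
        )


def template_cost(
    t: PathwayTemplate,
    arm: str,
    cost_of: Callable[[str], float],
    los_of: Callable[[str], float],
    covid_cost: float = 0.0,
):
    """Per-patient cost of a pathway template under arbitrary lookups.

    ``cost_of``/``los_of`` may return scalars or numpy arrays; the result
    broadcasts, which is what the probabilistic analysis exploits.
    """
    per_day = cost_of("icu_day") if t.location == "ccu" else cost_of("bed_day")
    total = cost_of("procedure") + los_of(t.los_class) * per_day + covid_cost
    if arm == INTERVENTION:
        total = total + cost_of("chlorhexidine")
    if t.pneumonia:
        total = total + cost_of("pneumonia_episode")
    if t.mv:
        total = total + cost_of("mv_episode")
    return total


def template_probability(t: PathwayTemplate, prob_of: Callable[[str], float]):
    """Joint probability of a template: product along its branch factors."""
    joint = 1.0
    for node, complement in t.factors:
        p = prob_of(node)
        joint = joint * ((1.0 - p) if complement else p)
    return joint


def pathway_cost(params: ParameterSet, arm: str, *, pneumonia: bool,
                 location: str, mv: bool | None = None) -> float:
    """Per-patient cost of the pathway with the given labels."""
    for t in PATHWAY_TEMPLATES:
        if (t.pneumonia, t.location, t.mv) == (pneumonia, location, mv):
            if t.los_class not in params.los:
                raise ValidationError(t.los_class, "missing length-of-stay class")
            return float(template_cost(
                t, arm, params.cost,
                lambda cls: params.los_days(arm, cls),
                params.covid_cost_per_patient,
            ))
    raise ValidationError("pathway", f"no pathway matches pneumonia={pneumonia}, "
                                     f"location={location!r}, mv={mv}")


def enumerate_pathways(params: ParameterSet, arm: str) -> list[Pathway]:
    """All 12 terminal pathways of one arm with probabilities and costs."""
    params.validate()
    prob_of = lambda node: params.prob(arm, node)
    los_of = lambda cls: params.los_days(arm, cls)
    out = []
    for t in PATHWAY_TEMPLATES:
        out.append(Pathway(
            arm=arm, pneumonia=t.pneumonia, location=t.location, mv=t.mv,
            outcome=t.outcome,
            joint_probability=float(template_probability(t, prob_of)),
            cost=float(template_cost(t, arm, params.cost, los_of,
                                     params.covid_cost_per_patient)),
            effect=0 if t.pneumonia else 1,
        ))
    total = sum(p.joint_probability for p in out)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(arm, f"pathway probabilities sum to {total}, not 1")
    return out


def evaluate_arm(params: ParameterSet, arm: str) -> ArmResult:
    """Cohort expected cost and pneumonia proportion for one arm."""
    pathways = enumerate_pathways(params, arm)
    expected_cost = sum(p.joint_probability * p.cost for p in pathways)
    pneumonia_proportion = sum(
        p.joint_probability for p in pathways if p.pneumonia
    )
    return ArmResult(arm, float(expected_cost), float(pneumonia_proportion),
                     tuple(pathways))


def expected_values_vectorized(
    prob_of: Callable[[str], np.ndarray],
    cost_of: Callable[[str], np.ndarray],
    los_of: Callable[[str], np.ndarray],
    arm: str,
    covid_cost: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(expected cost, pneumonia proportion) under array-valued lookups.

    Shares the pathway templates with :func:`evaluate_arm`, so a scalar
    call reproduces it exactly; with length-n arrays it evaluates n
    parameter draws in one pass.
    """
    expected_cost = 0.0
    pneumonia = 0.0
    for t in PATHWAY_TEMPLATES:
        joint = template_probability(t, prob_of)
        expected_cost = expected_cost + joint * template_cost(
            t, arm, cost_of, los_of, covid_cost)
        if t.pneumonia:
            pneumonia = pneumonia + joint
    return expected_cost, pneumonia
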