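"""Deterministic sensitivity analysis (DSA).

Four families, mirroring how the published analysis was organised:

* an RRR sweep - the base comparison re-run at progressively weaker
  effectiveness assumptions (0.3 down to 0.01), each with the mouthwash
  gel cost at which dominance would break;
* one-way variation - a single parameter moved to its lower or upper
  bound while everything else stays at base, evaluated at a conservative
  RRR of 0.01 (parameters bite hardest when the effect is nearly null).
  One-way overrides touch exactly one arm and do *not* re-derive the
  other arm, so varying a control-arm value leaves the intervention arm
  at its base-derived value;
* break-off search - the value of a target parameter at which the
  incremental cost crosses zero, found by bracketing root search;
* extreme scenarios - no patient ventilated, and best/worst cases that
  move a block of intervention-arm parameters and the two cost bounds
  simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
from scipy.optimize import brentq

from .cea import CEResult, compare_arms
from .parameters import (CONTROL, INTERVENTION, ParameterSet, ValidationError,
                         derive_intervention_arm)
from .tree import evaluate_arm

#: Root-search tolerances: $0.5 on costs, 0.05 days on stays.
BREAKOFF_XTOL = {"cost": 0.5, "los": 0.05, "prob": 1e-4}


@dataclass(frozen=True)
class DSATarget:
    """Addresses one variable parameter: kind, owning arm, and name.

    ``kind`` is ``"cost"`` (global cost item), ``"prob"`` (one arm's
    branch probability) or ``"los"`` (one arm's pathway-class stay).
    """

    kind: str
    name: str
    arm: str | None = None

    def apply(self, params: ParameterSet, value: float) -> ParameterSet:
        if self.kind == "cost":
            return params.with_cost(self.name, value)
        if self.kind == "prob":
            return params.with_probability(self.arm, self.name, value)
        if self.kind == "los":
            return params.with_los(self.arm, self.name, value)
        raise ValidationError(self.name, f"unknown DSA target kind {self.kind!r}")

    def base_value(self, params: ParameterSet) -> float:
        if self.kind == "cost":
            return params.cost(self.name)
        if self.kind == "prob":
            return params.prob(self.arm, self.name)
        if self.kind == "los":
            return params.los_days(self.arm, self.name)
        raise ValidationError(self.name, f"unknown DSA target kind {self.kind!r}")

    @property
    def label(self) -> str:
        return f"{self.arm or 'both'}:{self.name}"


GEL_COST = DSATarget("cost", "chlorhexidine")


@dataclass(frozen=True)
class DSARow:
    """One line of the DSA table."""

    parameter: str
    tested_value: float | None
    delta_cost: float
    delta_cost_zar: float
    incremental_benefit: float
    classification: str
    icer: float | None = None
    breakoff: float | None = None


@dataclass(frozen=True)
class ExtremeScenario:
    """Named block of simultaneous overrides (Table-of-bounds extremes)."""

    label: str
    overrides: tuple[tuple[DSATarget, float], ...]


def evaluate_comparison(params: ParameterSet) -> CEResult:
    """Mouthwash vs no-mouthwash comparison of a fully specified model."""
    return compare_arms(evaluate_arm(params, INTERVENTION),
                        evaluate_arm(params, CONTROL))


def _row(params: ParameterSet, parameter: str, tested_value, *,
         zar_factor: float = 17.35, breakoff=None) -> DSARow:
    ce = evaluate_comparison(params)
    return DSARow(
        parameter=parameter,
        tested_value=tested_value,
        delta_cost=ce.delta_cost,
        delta_cost_zar=ce.delta_cost * zar_factor,
        incremental_benefit=ce.delta_effect,
        classification=ce.classification,
        icer=ce.icer_value,
        breakoff=breakoff,
    )


def rrr_sweep(params: ParameterSet, rrr_values: Sequence[float],
              zar_factor: float = 17.35, with_breakoff: bool = True) -> list[DSARow]:
    """Re-evaluate the full comparison at each RRR value.

    Each row carries the gel-cost dominance break-off at that RRR (the
    published table reports one per sweep value).
    """
    rows = []
    for rrr in rrr_values:
        p = derive_intervention_arm(params, rrr)
        breakoff = None
        if with_breakoff:
            res = breakoff_search(params, GEL_COST, rrr_context=rrr)
            breakoff = res.value
        rows.append(_row(p, "rrr", rrr, zar_factor=zar_factor, breakoff=breakoff))
    return rows


def one_way(params: ParameterSet, target: DSATarget, bound: float,
            rrr_context: float = 0.01, zar_factor: float = 17.35) -> DSARow:
    """Single-parameter variation at a conservative RRR.

    For any target other than a pneumonia probability the incremental
    benefit is unchanged at ``rrr_context x control pneumonia
    probability`` (0.0004 at the default 0.01), because only the
    pneumonia split moves the effect axis.
    """
    base = derive_intervention_arm(params, rrr_context)
    return _row(target.apply(base, bound), target.label, bound, zar_factor=zar_factor)


@dataclass(frozen=True)
class BreakoffResult:
    value: float | None
    status: str  # "found" | "no_breakoff_in_range"


def breakoff_search(params: ParameterSet, target: DSATarget,
                    rrr_context: float = 0.3,
                    lower: float | None = None,
                    upper: float | None = None) -> BreakoffResult:
    """Parameter value at which the incremental cost crosses zero.

    Starts from the base value and widens the bracket geometrically (up
    to ten doublings in each direction) until the incremental cost
    changes sign, then solves with Brent's method to the kind-specific
    tolerance.  If no sign change appears in the bracket the search
    reports ``no_breakoff_in_range`` instead of guessing.
    """
    base_params = derive_intervention_arm(params, rrr_context)
    base_value = target.base_value(base_params)

    def delta_cost(v: float) -> float:
        return evaluate_comparison(target.apply(base_params, v)).delta_cost

    f0 = delta_cost(base_value)
    if f0 == 0.0:
        return BreakoffResult(base_value, "found")

    lo = base_value if lower is None else lower
    hi = base_value if upper is None else upper
    step = max(abs(base_value), 1.0)
    for _ in range(10):
        if delta_cost(hi) * f0 < 0 or (lo < base_value and delta_cost(lo) * f0 < 0):
            break
        hi = hi + step
        lo = max(0.0, lo - step)
        step *= 2.0
        if target.kind == "prob":
            hi = min(hi, 1.0)
    for a, b in ((base_value, hi), (lo, base_value)):
        if a == b:
            continue
        fa, fb = delta_cost(a), delta_cost(b)
        if fa * fb < 0:
            root = brentq(delta_cost, a, b, xtol=BREAKOFF_XTOL.get(target.kind, 0.5))
            return BreakoffResult(float(root), "found")
    return BreakoffResult(None, "no_breakoff_in_range")


# ---------------------------------------------------------------------------
# bound fixtures and extreme scenarios


def load_dsa_bounds(source=None) -> list[tuple[DSATarget, float, float]]:
    """(target, lower, upper) triples from the bundled bounds table."""
    if source is None:
        source = resources.files("mouthwash_cea.data").joinpath("dsa_bounds.csv").open()
    frame = pd.read_csv(source)
    out = []
    for row in frame.itertuples():
        arm = None if (not isinstance(row.arm, str) or not row.arm) else row.arm
        out.append((DSATarget(row.kind, row.target, arm),
                    float(row.lower), float(row.upper)))
    return out


def _bound(bounds, kind, name, arm, which) -> float:
    for target, lo, hi in bounds:
        if (target.kind, target.name, target.arm) == (kind, name, arm):
            return lo if which == "lower" else hi
    raise ValidationError(name, f"no DSA bound for {kind}/{arm}/{name}")


def extreme_scenario(label: str, bounds=None) -> ExtremeScenario:
    """Build a named extreme scenario from the bounds fixture.

    ``no_mv`` zeroes every ventilation probability in both arms.  The
    best (worst) case moves the intervention-arm pneumonia, critical-care
    and ventilation probabilities and its pneumonia stay lengths to the
    lower (upper) bounds while the bed-day and pneumonia-episode costs go
    to the upper (lower) bounds.
    """
    if label == "no_mv":
        return ExtremeScenario("no_mv", tuple(
            (DSATarget("prob", node, arm), 0.0)
            for arm in (CONTROL, INTERVENTION) for node in ("pn_mv", "np_mv")
        ))
    if label not in ("best_case", "worst_case"):
        raise ValidationError("label", f"unknown extreme scenario {label!r}")
    bounds = load_dsa_bounds() if bounds is None else bounds
    favourable = label == "best_case"
    prob_side = "lower" if favourable else "upper"
    cost_side = "upper" if favourable else "lower"
    overrides = []
    for node in ("pneumonia", "pn_ccu", "pn_mv"):
        overrides.append((DSATarget("prob", node, INTERVENTION),
                          _bound(bounds, "prob", node, INTERVENTION, prob_side)))
    for cls in ("pneumonia_ward", "pneumonia_ccu_nomv", "pneumonia_ccu_mv"):
        overrides.append((DSATarget("los", cls, INTERVENTION),
                          _bound(bounds, "los", cls, INTERVENTION, prob_side)))
    for name in ("bed_day", "pneumonia_episode"):
        overrides.append((DSATarget("cost", name, None),
                          _bound(bounds, "cost", name, None, cost_side)))
    return ExtremeScenario(label, tuple(overrides))


def extreme(params: ParameterSet, label: str, rrr_context: float = 0.01,
            bounds=None) -> CEResult:
    """Evaluate one extreme scenario at the conservative RRR context."""
    scenario = extreme_scenario(label, bounds)
    p = derive_intervention_arm(params, rrr_context)
    for target, value in scenario.overrides:
        p = target.apply(p, value)
    return evaluate_comparison(p)


def full_dsa_table(params: ParameterSet,
                   rrr_values: Sequence[float] = (0.2, 0.1, 0.05, 0.01),
                   rrr_context: float = 0.01,
                   bounds=None,
                   zar_factor: float = 17.35) -> pd.DataFrame:
    """The complete DSA table: base, RRR sweep, one-way rows, extremes."""
    bounds = load_dsa_bounds() if bounds is None else bounds
    rows: list[DSARow] = []
    base_breakoff = breakoff_search(params, GEL_COST, rrr_context=params.rrr)
    rows.append(replace(_row(params, "base_case", None, zar_factor=zar_factor),
                        breakoff=base_breakoff.value))
    rows.extend(rrr_sweep(params, rrr_values, zar_factor=zar_factor))
    for target, lo, hi in bounds:
        for bound in (lo, hi):
            rows.append(one_way(params, target, bound, rrr_context, zar_factor))
    for label in ("no_mv", "best_case", "worst_case"):
        ce = extreme(params, label, rrr_context, bounds)
        rows.append(DSARow(
            parameter=f"extreme:{label}", tested_value=None,
            delta_cost=ce.delta_cost, delta_cost_zar=ce.delta_cost * zar_factor,
            incremental_benefit=ce.delta_effect,
            classification=ce.classification, icer=ce.icer_value,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
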