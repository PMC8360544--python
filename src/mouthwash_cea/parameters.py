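"""Model input parameters: branch probabilities, unit costs, lengths of stay.

The decision tree compares two strategies for adult abdominal-surgery
patients in South Africa: two doses of preoperative chlorhexidine
mouthwash versus no mouthwash.  All inputs are cohort-level summaries:

* branch probabilities, mostly as event/total counts from two prospective
  surgical cohorts (n = 931 for the pneumonia node) plus a few
  expert-opinion point values;
* unit or episode costs, already expressed in 2020 international dollars
  at the South African price level (see :mod:`mouthwash_cea.currency`
  for how such values are produced);
* mean length of stay (days) for each of six terminal pathway classes.

The intervention arm carries no trial data of its own.  Its
pneumonia-branch probabilities are derived from the control arm by a
relative risk reduction (RRR, default 0.3): ``p_int = p_ctrl * (1 - RRR)``
for the pneumonia probability and, among pneumonia patients, the critical
care admission, mechanical ventilation and critical-care mortality
probabilities.  Every no-pneumonia parameter, and general-ward mortality
among pneumonia patients, is identical across arms by assumption.

A pandemic overlay raises the control-arm pneumonia probability and adds
a per-patient cost to both arms before the RRR derivation is re-applied.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, NamedTuple

ARMS = ("no_mouthwash", "mouthwash")
CONTROL, INTERVENTION = ARMS

#: Probability nodes of the tree, in top-down order.  ``pn_`` prefixes are
#: conditional on pneumonia, ``np_`` on no pneumonia.
PROB_NODES = (
    "pneumonia",
    "pn_ccu",
    "pn_mv",
    "pn_died_mv",
    "pn_died_ccu_nomv",
    "pn_died_ward",
    "np_ccu",
    "np_mv",
    "np_died_mv",
    "np_died_ccu_nomv",
    "np_died_ward",
)

#: Control-arm nodes scaled by (1 - RRR) when deriving the intervention arm.
RRR_SCALED_NODES = frozenset(
    {"pneumonia", "pn_ccu", "pn_mv", "pn_died_mv", "pn_died_ccu_nomv"}
)

LOS_CLASSES = (
    "pneumonia_ccu_mv",
    "pneumonia_ccu_nomv",
    "pneumonia_ward",
    "nopneumonia_ccu_mv",
    "nopneumonia_ccu_nomv",
    "nopneumonia_ward",
)

REQUIRED_COSTS = (
    "pneumonia_episode",
    "bed_day",
    "icu_day",
    "chlorhexidine",
    "mv_episode",
    "procedure",
)

#: Items that may legitimately be costed per hospital day.
_PER_DAY_ITEMS = frozenset({"bed_day", "icu_day"})

#: Printed table values are 2-dp roundings of the underlying fractions.
PRINT_TOL = 0.005


class ValidationError(ValueError):
    """A model input failed validation; ``field`` names the offender."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


class BetaCounts(NamedTuple):
    """Beta distribution spec parameterized directly by cohort counts."""

    alpha: float
    beta: float
    degenerate: bool = False

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def sampling_params(self) -> tuple[float, float]:
        """(alpha, beta) actually used for draws.

        Degenerate all-or-nothing counts get a +0.5/+0.5 continuity
        correction so the distribution is proper.
        """
        if self.degenerate:
            return self.alpha + 0.5, self.beta + 0.5
        return self.alpha, self.beta


def beta_from_counts(events: int, total: int) -> BetaCounts:
    """Beta spec with ``alpha = events``, ``beta = total - events``.

    The mean then equals the observed proportion ``events/total``.  Zero
    or full event counts are flagged degenerate; :meth:`BetaCounts.sampling_params`
    applies a continuity correction for sampling.
    """
    if total <= 0:
        raise ValidationError("total", "must be a positive count")
    if events < 0 or events > total:
        raise ValidationError("events", f"must satisfy 0 <= events <= total, got {events}/{total}")
    return BetaCounts(float(events), float(total - events), degenerate=events in (0, total))


@dataclass(frozen=True)
class ProbabilityParam:
    """A branch probability, optionally backed by event/total counts.

    ``uncertainty`` is ``"beta_counts"`` for parameters drawn from a beta
    distribution in probabilistic analyses and ``"fixed"`` for point-mass
    values (expert opinion or RRR-derived quantities).  A beta parameter
    without counts needs an explicit effective sample size ``ess``.
    """

    name: str
    value: float
    events: int | None = None
    total: int | None = None
    uncertainty: str = "fixed"
    ess: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValidationError(self.name, f"probability {self.value} outside [0, 1]")
        if (self.events is None) != (self.total is None):
            raise ValidationError(self.name, "events and total must be given together")
        if self.events is not None:
            if self.events < 0 or self.total <= 0 or self.events > self.total:
                raise ValidationError(self.name, f"bad counts {self.events}/{self.total}")
            if abs(self.value - self.events / self.total) > PRINT_TOL:
                raise ValidationError(
                    self.name,
                    f"value {self.value} inconsistent with counts "
                    f"{self.events}/{self.total} beyond printed rounding",
                )
        if self.uncertainty not in ("beta_counts", "fixed"):
            raise ValidationError(self.name, f"unknown uncertainty tag {self.uncertainty!r}")
        if self.uncertainty == "beta_counts" and self.events is None and self.ess is None:
            raise ValidationError(
                self.name, "beta_counts requires counts or an effective sample size"
            )

    def beta_spec(self) -> BetaCounts:
        """Beta spec from counts, or from value x effective sample size."""
        if self.uncertainty != "beta_counts":
            raise ValidationError(self.name, "not a beta-distributed parameter")
        if self.events is not None:
            return beta_from_counts(self.events, self.total)
        alpha = self.value * self.ess
        return BetaCounts(alpha, self.ess - alpha, degenerate=alpha in (0.0, self.ess))


@dataclass(frozen=True)
class CostItem:
    """A unit/episode cost in 2020 international dollars.

    ``raw_value``/``source_currency``/``source_year`` record provenance in
    the source currency; the model itself consumes ``adjusted_2020_intl_usd``.
    """

    name: str
    adjusted_2020_intl_usd: float
    raw_value: float | None = None
    source_currency: str | None = None
    source_year: int | None = None
    setting: str | None = None
    unit: str = "per_patient"
    uncertainty: str = "gamma"

    def __post_init__(self):
        if self.adjusted_2020_intl_usd < 0:
            raise ValidationError(self.name, "cost must be nonnegative")
        if self.unit not in ("per_patient", "per_day", "per_episode"):
            raise ValidationError(self.name, f"unknown unit {self.unit!r}")
        if self.unit == "per_day" and self.name not in _PER_DAY_ITEMS:
            raise ValidationError(self.name, "only bed-day/critical-care-day items are per_day")
        if self.uncertainty not in ("gamma", "fixed"):
            raise ValidationError(self.name, f"unknown uncertainty tag {self.uncertainty!r}")


@dataclass(frozen=True)
class LoSItem:
    """Mean length of stay (days) for one terminal pathway class."""

    pathway_class: str
    mean_days: float

    def __post_init__(self):
        if self.pathway_class not in LOS_CLASSES:
            raise ValidationError(self.pathway_class, "unknown pathway class")
        if self.mean_days < 0:
            raise ValidationError(self.pathway_class, "mean_days must be nonnegative")


@dataclass(frozen=True)
class CovidOverlay:
    """Pandemic scenario modifier.

    ``pneumonia_increment`` is added to the *control* pneumonia
    probability before the RRR derivation; ``per_patient_cost`` accrues to
    every patient in both arms.  ``mode`` records whether the increment is
    the literal percentage-point figure (``absolute_pp``) or the smaller
    increment calibrated to the published pandemic-scenario proportions
    (``calibrated``).
    """

    pneumonia_increment: float
    per_patient_cost: float
    mode: str = "absolute_pp"

    DEFAULT_ABSOLUTE = 0.018
    DEFAULT_CALIBRATED = 0.0028
    DEFAULT_COST = 254.0

    def __post_init__(self):
        if not 0.0 <= self.pneumonia_increment <= 1.0:
            raise ValidationError("pneumonia_increment", "must lie in [0, 1]")
        if self.mode not in ("absolute_pp", "calibrated"):
            raise ValidationError("mode", f"unknown overlay mode {self.mode!r}")

    @classmethod
    def absolute(cls, increment: float = DEFAULT_ABSOLUTE, cost: float = DEFAULT_COST):
        return cls(increment, cost, "absolute_pp")

    @classmethod
    def calibrated(cls, increment: float = DEFAULT_CALIBRATED, cost: float = DEFAULT_COST):
        return cls(increment, cost, "calibrated")


@dataclass(frozen=True)
class ParameterSet:
    """Complete, validated model input set for both arms.

    ``probabilities`` is keyed by ``(arm, node)``; ``los`` is shared
    across arms at base case, with ``los_overrides`` allowing per-arm
    deviations during sensitivity analysis.  ``covid_cost_per_patient``
    is nonzero only after a pandemic overlay has been applied.
    """

    probabilities: Mapping[tuple[str, str], ProbabilityParam]
    costs: Mapping[str, CostItem]
    los: Mapping[str, LoSItem]
    rrr: float = 0.3
    covid_cost_per_patient: float = 0.0
    los_overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def prob(self, arm: str, node: str) -> float:
        return self.probabilities[(arm, node)].value

    def cost(self, name: str) -> float:
        return self.costs[name].adjusted_2020_intl_usd

    def los_days(self, arm: str, pathway_class: str) -> float:
        override = self.los_overrides.get((arm, pathway_class))
        if override is not None:
            return override
        return self.los[pathway_class].mean_days

    # -- copy-with helpers ----------------------------------------------
    def with_probability(self, arm: str, node: str, value: float) -> "ParameterSet":
        """Override one arm's probability, leaving the other arm alone."""
        if (arm, node) not in self.probabilities:
            raise ValidationError(f"{arm}/{node}", "unknown probability node")
        probs = dict(self.probabilities)
        probs[(arm, node)] = ProbabilityParam(node, value, uncertainty="fixed")
        return replace(self, probabilities=probs)

    def with_cost(self, name: str, value: float) -> "ParameterSet":
        if name not in self.costs:
            raise ValidationError(name, "unknown cost item")
        costs = dict(self.costs)
        costs[name] = replace(costs[name], adjusted_2020_intl_usd=value)
        return replace(self, costs=costs)

    def with_los(self, arm: str, pathway_class: str, days: float) -> "ParameterSet":
        if pathway_class not in self.los:
            raise ValidationError(pathway_class, "unknown pathway class")
        if days < 0:
            raise ValidationError(pathway_class, "mean_days must be nonnegative")
        overrides = dict(self.los_overrides)
        overrides[(arm, pathway_class)] = days
        return replace(self, los_overrides=overrides)

    # -- validation ------------------------------------------------------
    def validate(self) -> "ParameterSet":
        if not 0.0 <= self.rrr < 1.0:
            raise ValidationError("rrr", f"must lie in [0, 1), got {self.rrr}")
        for arm in ARMS:
            for node in PROB_NODES:
                if (arm, node) not in self.probabilities:
                    raise ValidationError(f"{arm}/{node}", "missing probability")
        for name in REQUIRED_COSTS:
            if name not in self.costs:
                raise ValidationError(name, "missing cost item")
        for cls in LOS_CLASSES:
            if cls not in self.los:
                raise ValidationError(cls, "missing length-of-stay class")
        return self

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "probabilities": [
                {"arm": arm, **dataclasses.asdict(p)}
                for (arm, _), p in sorted(self.probabilities.items())
            ],
            "costs": [dataclasses.asdict(c) for _, c in sorted(self.costs.items())],
            "los": [dataclasses.asdict(l) for _, l in sorted(self.los.items())],
            "rrr": self.rrr,
            "covid_cost_per_patient": self.covid_cost_per_patient,
            "los_overrides": [
                {"arm": arm, "pathway_class": cls, "mean_days": days}
                for (arm, cls), days in sorted(self.los_overrides.items())
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ParameterSet":
        probs = {}
        for row in payload["probabilities"]:
            row = dict(row)
            arm = row.pop("arm")
            probs[(arm, row["name"])] = ProbabilityParam(**row)
        costs = {row["name"]: CostItem(**row) for row in payload["costs"]}
        los = {row["pathway_class"]: LoSItem(**row) for row in payload["los"]}
        overrides = {
            (row["arm"], row["pathway_class"]): row["mean_days"]
            for row in payload.get("los_overrides", [])
        }
        return cls(
            probs,
            costs,
            los,
            rrr=payload.get("rrr", 0.3),
            covid_cost_per_patient=payload.get("covid_cost_per_patient", 0.0),
            los_overrides=overrides,
        ).validate()

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        return cls.from_dict(json.loads(text))


def derive_intervention_arm(params: ParameterSet, rrr: float) -> ParameterSet:
    """Re-derive the mouthwash arm from the control arm at a given RRR.

    Pneumonia incidence and, among pneumonia patients, critical-care
    admission, mechanical ventilation and both critical-care death
    probabilities are scaled by ``(1 - rrr)``.  All other probabilities
    (general-ward death among pneumonia patients; every no-pneumonia
    parameter) are copied from the control arm unchanged.
    """
    if not 0.0 <= rrr < 1.0:
        raise ValidationError("rrr", f"must lie in [0, 1), got {rrr}")
    probs = dict(params.probabilities)
    for node in PROB_NODES:
        control = probs[(CONTROL, node)]
        if node in RRR_SCALED_NODES:
            probs[(INTERVENTION, node)] = ProbabilityParam(
                node, control.value * (1.0 - rrr), uncertainty="fixed"
            )
        else:
            probs[(INTERVENTION, node)] = control
    return replace(params, probabilities=probs, rrr=rrr)


def apply_covid_overlay(params: ParameterSet, overlay: CovidOverlay) -> ParameterSet:
    """Apply the pandemic scenario before re-deriving the intervention arm.

    The increment raises the control pneumonia probability; pushing it
    outside [0, 1] is an error rather than a silent clamp.  The
    per-patient cost accrues to both arms (it cancels in cost
    differences except through the pneumonia-probability shift).
    """
    control = params.probabilities[(CONTROL, "pneumonia")]
    shifted = control.value + overlay.pneumonia_increment
    if shifted > 1.0:
        raise ValidationError("pneumonia", f"overlay pushes probability to {shifted} > 1")
    probs = dict(params.probabilities)
    probs[(CONTROL, "pneumonia")] = replace(
        control, value=shifted, events=None, total=None,
        ess=control.total if control.total is not None else control.ess,
    )
    out = replace(
        params,
        probabilities=probs,
        covid_cost_per_patient=params.covid_cost_per_patient + overlay.per_patient_cost,
    )
    return derive_intervention_arm(out, params.rrr)


# ---------------------------------------------------------------------------
# fixture loading


def _data_path(name: str):
    return resources.files("mouthwash_cea.data").joinpath(name)


def _read_csv_rows(source) -> list[dict]:
    if hasattr(source, "read"):
        return list(csv.DictReader(source))
    with open(source, newline="") as fh:
        return list(csv.DictReader(fh))


def load_parameter_set(
    probabilities=None,
    costs=None,
    los=None,
    rrr: float = 0.3,
    mv_effective_sample_size: float = 39.0,
) -> ParameterSet:
    """Load and validate a parameter set from delimited-table sources.

    With no arguments the bundled fixtures (the published probability,
    cost and length-of-stay tables) are used.  Control-arm probabilities
    are stored at full ``events/total`` precision; the intervention arm is
    derived at ``rrr`` and cross-checked against the printed
    intervention-arm values to within the 2-dp rounding tolerance.

    ``mv_effective_sample_size`` supplies the pseudo-count weight for the
    one control-arm beta parameter published without counts (mechanical
    ventilation among pneumonia patients; default 39, the size of the
    pneumonia cohort).
    """
    prob_rows = _read_csv_rows(probabilities if probabilities is not None
                               else _data_path("probabilities.csv").open())
    cost_rows = _read_csv_rows(costs if costs is not None
                               else _data_path("costs.csv").open())
    los_rows = _read_csv_rows(los if los is not None
                              else _data_path("los.csv").open())

    probs: dict[tuple[str, str], ProbabilityParam] = {}
    printed_intervention: dict[str, float] = {}
    for row in prob_rows:
        arm = row["arm"]
        if arm not in ARMS:
            raise ValidationError(row["name"], f"unknown arm {arm!r}")
        printed = float(row["printed_value"])
        events = int(row["events"]) if row.get("events") else None
        total = int(row["total"]) if row.get("total") else None
        if arm == INTERVENTION:
            printed_intervention[row["name"]] = printed
            continue
        dist = row["distribution"].strip().lower()
        uncertainty = "beta_counts" if dist == "beta" else "fixed"
        value = events / total if events is not None else printed
        probs[(arm, row["name"])] = ProbabilityParam(
            row["name"], value, events, total, uncertainty,
            ess=mv_effective_sample_size if (uncertainty == "beta_counts" and events is None) else None,
        )

    cost_map: dict[str, CostItem] = {}
    for row in cost_rows:
        cost_map[row["name"]] = CostItem(
            name=row["name"],
            adjusted_2020_intl_usd=float(row["adjusted_2020_intl_usd"]),
            raw_value=float(row["raw_value"]) if row.get("raw_value") else None,
            source_currency=row.get("source_currency") or None,
            source_year=int(row["source_year"]) if row.get("source_year") else None,
            setting=row.get("setting") or None,
            unit=row["unit"],
            uncertainty=row.get("distribution", "gamma"),
        )

    los_map = {row["pathway_class"]: LoSItem(row["pathway_class"], float(row["mean_days"]))
               for row in los_rows}

    # Seed the intervention slots (overwritten by the derivation) so the
    # completeness check below sees a fully keyed mapping.
    for node in PROB_NODES:
        if (CONTROL, node) not in probs:
            raise ValidationError(f"{CONTROL}/{node}", "missing probability")
        probs[(INTERVENTION, node)] = probs[(CONTROL, node)]

    ps = ParameterSet(probs, cost_map, los_map, rrr=rrr).validate()
    ps = derive_intervention_arm(ps, rrr)

    # Cross-check the derived arm against the printed intervention values,
    # but only when the loader is running at the RRR those values assume.
    if printed_intervention and abs(rrr - 0.3) < 1e-12:
        for node, printed in printed_intervention.items():
            derived = ps.prob(INTERVENTION, node)
            if abs(derived - printed) > PRINT_TOL + 1e-9:
                raise ValidationError(
                    node,
                    f"derived intervention value {derived:.4f} disagrees with "
                    f"printed {printed} beyond rounding",
                )
    return ps


def default_parameter_set(rrr: float = 0.3, **kwargs) -> ParameterSet:
    """The bundled base-case parameter set (published tables, given RRR)."""
    return load_parameter_set(rrr=rrr, **kwargs)
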