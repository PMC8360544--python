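"""Arm comparison: incremental cost/effect, dominance, NMB and CEAC.

The effect axis is the *reduction in the proportion of pneumonia
patients* (not QALYs): ``delta_effect = comparator pneumonia proportion -
intervention pneumonia proportion``, so a positive value means the
intervention prevents pneumonia.  Willingness to pay (WTP, lambda) is
priced per unit of that proportion, and net monetary benefit is

    NMB(lambda) = lambda * delta_effect - delta_cost.

The intervention *dominates* when it is strictly cheaper and strictly
more effective; the comparator dominates in the mirrored case; everywhere
else an incremental cost-effectiveness ratio (ICER) is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .parameters import ValidationError
from .tree import ArmResult

INTERVENTION_DOMINATES = "intervention_dominates"
COMPARATOR_DOMINATES = "comparator_dominates"
ICER = "icer"


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of intervention versus comparator.

    ``icer_value`` is present only for the ``icer`` classification; it is
    ``nan`` when both deltas are zero (indeterminate) and signed infinity
    when only the effect delta is zero.
    """

    delta_cost: float
    delta_effect: float
    classification: str
    icer_value: float | None = None

    @property
    def dominant(self) -> bool:
        return self.classification == INTERVENTION_DOMINATES


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability_cost_effective: float


def compare_arms(intervention: ArmResult, comparator: ArmResult) -> CEResult:
    """Incremental cost and pneumonia reduction, with dominance class."""
    dc = intervention.expected_cost - comparator.expected_cost
    de = comparator.pneumonia_proportion - intervention.pneumonia_proportion
    if dc < 0 and de > 0:
        return CEResult(dc, de, INTERVENTION_DOMINATES)
    if dc > 0 and de < 0:
        return CEResult(dc, de, COMPARATOR_DOMINATES)
    if de == 0:
        icer = math.nan if dc == 0 else math.copysign(math.inf, dc)
    else:
        icer = dc / de
    return CEResult(dc, de, ICER, icer)


def net_benefit(ce, wtp: float) -> float:
    """NMB at a willingness-to-pay threshold.

    ``ce`` may be a :class:`CEResult` or a bare ``(delta_cost,
    delta_effect)`` pair (e.g. one probabilistic draw).
    """
    if wtp < 0:
        raise ValidationError("wtp", "willingness to pay must be nonnegative")
    if isinstance(ce, CEResult):
        dc, de = ce.delta_cost, ce.delta_effect
    else:
        dc, de = ce
    return wtp * de - dc


def default_wtp_grid(start: float = 0.0, stop: float = 30_000.0,
                     step: float = 250.0) -> np.ndarray:
    """WTP grid spanning $0-$30,000 per unit pneumonia reduction."""
    return np.arange(start, stop + step / 2, step)


def ceac(draws: Sequence[tuple[float, float]] | np.ndarray,
         wtp_grid: Iterable[float] | None = None) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve from probabilistic draws.

    At each threshold the curve reports the fraction of draws with
    positive net benefit; draws exactly on the NMB = 0 boundary count
    one half.
    """
    arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise ValidationError("draws", "CEAC requires at least one draw")
    arr = arr.reshape(-1, 2)
    dc, de = arr[:, 0], arr[:, 1]
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(list(wtp_grid), float)
    points = []
    for wtp in grid:
        nmb = wtp * de - dc
        frac = (np.count_nonzero(nmb > 0) + 0.5 * np.count_nonzero(nmb == 0)) / len(nmb)
        points.append(CEACPoint(float(wtp), float(frac)))
    return points
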