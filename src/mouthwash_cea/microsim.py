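"""Patient-level microsimulation and synthetic cohort tables.

Two jobs, both in support of testing the cohort model rather than adding
modelling capability of their own:

* :func:`simulate_cohort` routes individual patients through the tree by
  independent Bernoulli draws at each node and prices them with the same
  pathway costing the analytic model uses.  Its Monte-Carlo mean is an
  independent estimate of the analytic expected cost/effect, converging
  at the usual 1/sqrt(n) rate - the brute-force oracle for
  :func:`mouthwash_cea.tree.evaluate_arm`.
* :func:`synthesize_cohort_tables` generates event/total count tables in
  the layout of the source cohort publications by hierarchical binomial
  sampling (downstream denominators are upstream event counts), for
  parameter-recovery and interval-coverage experiments.

Stay lengths default to the deterministic class means so the simulator
matches the cohort model exactly in expectation; an optional
gamma-distributed per-patient stay mode exists for stress testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import (CONTROL, ParameterSet, ProbabilityParam,
                         ValidationError, beta_from_counts)
from .tree import pathway_cost

#: (node, denominator description) layout of a synthetic count table.
COUNT_NODES = (
    "pneumonia",
    "pn_ccu", "pn_mv", "pn_died_mv", "pn_died_ccu_nomv", "pn_died_ward",
    "np_ccu", "np_mv", "np_died_mv", "np_died_ccu_nomv", "np_died_ward",
)


@dataclass(frozen=True)
class CohortSimulation:
    """Simulated patients plus Monte-Carlo estimates with standard errors."""

    arm: str
    records: pd.DataFrame
    mean_cost: float
    se_cost: float
    pneumonia_proportion: float
    se_proportion: float
    seed: int


def simulate_cohort(params: ParameterSet, arm: str, n: int, seed: int = 0,
                    los_mode: str = "fixed", los_cv: float = 0.5) -> CohortSimulation:
    """Monte-Carlo cohort of ``n`` patients routed through the tree.

    ``los_mode="gamma"`` replaces each patient's deterministic class-mean
    stay with a gamma draw of the same mean and coefficient of variation
    ``los_cv`` (stress-test mode; expectation unchanged).
    """
    if n < 1:
        raise ValidationError("n", "need at least one patient")
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, hash_arm(arm)]))
    p = lambda node: params.prob(arm, node)

    pneumonia = rng.random(n) < p("pneumonia")
    ccu = np.where(pneumonia, rng.random(n) < p("pn_ccu"),
                   rng.random(n) < p("np_ccu"))
    mv = ccu & np.where(pneumonia, rng.random(n) < p("pn_mv"),
                        rng.random(n) < p("np_mv"))
    death_p = np.select(
        [pneumonia & mv, pneumonia & ccu & ~mv, pneumonia & ~ccu,
         ~pneumonia & mv, ~pneumonia & ccu & ~mv],
        [p("pn_died_mv"), p("pn_died_ccu_nomv"), p("pn_died_ward"),
         p("np_died_mv"), p("np_died_ccu_nomv")],
        default=p("np_died_ward"),
    )
    died = rng.random(n) < death_p

    prefix = np.where(pneumonia, "pneumonia", "nopneumonia")
    suffix = np.where(ccu, np.where(mv, "_ccu_mv", "_ccu_nomv"), "_ward")
    los_class = np.char.add(prefix.astype("U11"), suffix.astype("U9"))
    los_days = np.array([params.los_days(arm, cls) for cls in los_class])
    if los_mode == "gamma":
        shape = 1.0 / los_cv**2
        positive = los_days > 0
        los_days = np.where(positive,
                            rng.gamma(shape, np.maximum(los_days, 1e-12) * los_cv**2 / 1.0),
                            los_days)
    elif los_mode != "fixed":
        raise ValidationError("los_mode", f"unknown mode {los_mode!r}")

    # Cost components priced identically to the analytic model, with the
    # per-day component re-scaled for individual stays.
    base_cost = np.empty(n)
    per_day = np.where(ccu, params.cost("icu_day"), params.cost("bed_day"))
    for pn in (True, False):
        for loc, mvi in (("ccu", True), ("ccu", False), ("ward", None)):
            mask = (pneumonia == pn) & ((ccu & (mv == bool(mvi))) if loc == "ccu" else ~ccu)
            if mvi is False:
                mask &= ~mv
            if not mask.any():
                continue
            fixed = pathway_cost(params, arm, pneumonia=pn, location=loc, mv=mvi)
            cls = f"{'pneumonia' if pn else 'nopneumonia'}_{'ccu_' + ('mv' if mvi else 'nomv') if loc == 'ccu' else 'ward'}"
            fixed -= params.los_days(arm, cls) * (params.cost("icu_day") if loc == "ccu"
                                                  else params.cost("bed_day"))
            base_cost[mask] = fixed
    cost = base_cost + los_days * per_day

    records = pd.DataFrame({
        "id": np.arange(n), "arm": arm, "pneumonia": pneumonia,
        "location": np.where(ccu, "ccu", "ward"), "mv": mv,
        "outcome": np.where(died, "died", "discharged"),
        "los_days": los_days, "cost": cost,
    })
    return CohortSimulation(
        arm=arm, records=records,
        mean_cost=float(cost.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        pneumonia_proportion=float(pneumonia.mean()),
        se_proportion=float(np.sqrt(pneumonia.mean() * (1 - pneumonia.mean()) / n)),
        seed=seed,
    )


def hash_arm(arm: str) -> int:
    import hashlib
    return int.from_bytes(hashlib.sha256(arm.encode()).digest()[:4], "big")


@dataclass(frozen=True)
class SyntheticCohortTable:
    """Event/total counts in the layout of the published probability table."""

    counts: Mapping[str, tuple[int, int]]  # node -> (events, total)
    n_patients: int
    seed: int
    low_information: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"name": k, "events": e, "total": t} for k, (e, t) in self.counts.items()]
        )


def synthesize_cohort_tables(params: ParameterSet, n_patients: int,
                             seed: int = 0, arm: str = CONTROL) -> SyntheticCohortTable:
    """Hierarchical binomial count table from a generating parameter set.

    Each node's denominator is the event count of its parent branch
    (pneumonia events feed the pneumonia critical-care node, and so on),
    matching how the source cohort tables are laid out.
    """
    if n_patients < 1:
        raise ValidationError("n_patients", "need at least one patient")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    p = lambda node: params.prob(arm, node)
    b = lambda n, q: int(rng.binomial(n, q)) if n > 0 else 0

    n_pn = b(n_patients, p("pneumonia"))
    n_np = n_patients - n_pn
    pn_ccu = b(n_pn, p("pn_ccu"))
    pn_mv = b(pn_ccu, p("pn_mv"))
    np_ccu = b(n_np, p("np_ccu"))
    np_mv = b(np_ccu, p("np_mv"))
    counts = {
        "pneumonia": (n_pn, n_patients),
        "pn_ccu": (pn_ccu, n_pn),
        "pn_mv": (pn_mv, pn_ccu),
        "pn_died_mv": (b(pn_mv, p("pn_died_mv")), pn_mv),
        "pn_died_ccu_nomv": (b(pn_ccu - pn_mv, p("pn_died_ccu_nomv")), pn_ccu - pn_mv),
        "pn_died_ward": (b(n_pn - pn_ccu, p("pn_died_ward")), n_pn - pn_ccu),
        "np_ccu": (np_ccu, n_np),
        "np_mv": (np_mv, np_ccu),
        "np_died_mv": (b(np_mv, p("np_died_mv")), np_mv),
        "np_died_ccu_nomv": (b(np_ccu - np_mv, p("np_died_ccu_nomv")), np_ccu - np_mv),
        "np_died_ward": (b(n_np - np_ccu, p("np_died_ward")), n_np - np_ccu),
    }
    low_info = any(t == 0 or e in (0, t) for e, t in counts.values())
    return SyntheticCohortTable(counts, n_patients, seed, low_information=low_info)


def recover_probabilities(table: SyntheticCohortTable) -> dict[str, ProbabilityParam]:
    """Point estimates (and beta specs) recovered from a count table.

    Nodes with an empty denominator recover to ``None``-like NaN values
    and are the reason a table may be flagged ``low_information``.
    """
    out = {}
    for node, (events, total) in table.counts.items():
        if total == 0:
            continue
        spec = beta_from_counts(events, total)
        out[node] = ProbabilityParam(node, events / total, events, total,
                                     uncertainty="beta_counts")
    return out


def credible_interval(events: int, total: int, level: float = 0.95) -> tuple[float, float]:
    """Central beta credible interval for a count-backed probability.

    Uses the count parameterization (``alpha = events``, ``beta = total -
    events``) with the continuity correction at degenerate counts.
    """
    a, b = beta_from_counts(events, total).sampling_params()
    tail = (1.0 - level) / 2.0
    return (float(stats.beta.ppf(tail, a, b)), float(stats.beta.ppf(1.0 - tail, a, b)))
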