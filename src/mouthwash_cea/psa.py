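"""Probabilistic sensitivity analysis (PSA).

Parameter uncertainty follows the published distribution assignments:
count-backed probabilities are beta with ``alpha = events`` and
``beta = total - events`` (so the draw mean is the observed proportion);
the one count-free beta probability (ventilation among control-arm
pneumonia patients) uses a configurable effective sample size; expert
point values are held fixed; costs are gamma.  The gamma distributions
carry no published variance, so a coefficient of variation (default 0.2)
parameterizes them mean-preservingly: ``shape = 1/cv^2``,
``scale = mean * cv^2``.  Because the published Monte-Carlo cost means
exceed the deterministic base case by ~28%, they imply unpublished
hyperparameters and are not reproduction targets; this module's contract
is the distributional properties, not those two numbers.

Each iteration draws all control-arm parameters independently, re-derives
the intervention arm from the drawn control values at the configured RRR
(so the two arms stay internally consistent draw by draw), evaluates both
arms, and records the incremental cost and incremental pneumonia
reduction.

Reproducibility: one root seed; every parameter owns a substream derived
from the root seed and a stable hash of its name, so adding or removing
one parameter never perturbs the draws of the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import (CONTROL, INTERVENTION, PROB_NODES, RRR_SCALED_NODES,
                         ParameterSet, ProbabilityParam, ValidationError,
                         beta_from_counts)
from .tree import expected_values_vectorized

DEFAULT_N_ITERATIONS = 10_000
DEFAULT_COST_CV = 0.2


@dataclass(frozen=True)
class UncertaintySpec:
    """Distribution assignment for one scalar parameter.

    ``dist`` is ``beta`` (args: alpha, beta), ``gamma`` (args: mean, cv)
    or ``fixed`` (args: value).
    """

    name: str
    dist: str
    args: tuple[float, ...]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "fixed":
            return np.full(n, self.args[0])
        if self.dist == "beta":
            alpha, beta = self.args
            if alpha <= 0 or beta <= 0:  # degenerate counts: continuity correction
                alpha, beta = alpha + 0.5, beta + 0.5
            return rng.beta(alpha, beta, size=n)
        if self.dist == "gamma":
            mean, cv = self.args
            if mean == 0 or cv == 0:
                return np.full(n, mean)
            shape = 1.0 / cv**2
            return rng.gamma(shape, mean * cv**2, size=n)
        raise ValidationError(self.name, f"unknown distribution {self.dist!r}")

    @property
    def mean(self) -> float:
        if self.dist == "fixed":
            return self.args[0]
        if self.dist == "beta":
            a, b = self.args
            if a <= 0 or b <= 0:
                a, b = a + 0.5, b + 0.5
            return a / (a + b)
        return self.args[0]


def build_specs(params: ParameterSet, cost_cv: float = DEFAULT_COST_CV,
                cost_cv_overrides: Mapping[str, float] | None = None,
                ) -> dict[str, UncertaintySpec]:
    """Uncertainty specs for every sampled scalar.

    Keys are ``prob:<node>`` for control-arm probabilities and
    ``cost:<name>`` for cost items.  Stay lengths have no published
    uncertainty and are left out (fixed).
    """
    overrides = dict(cost_cv_overrides or {})
    specs: dict[str, UncertaintySpec] = {}
    for node in PROB_NODES:
        p: ProbabilityParam = params.probabilities[(CONTROL, node)]
        key = f"prob:{node}"
        if p.uncertainty == "beta_counts":
            spec = p.beta_spec()
            a, b = spec.sampling_params()
            specs[key] = UncertaintySpec(key, "beta", (a, b))
        else:
            specs[key] = UncertaintySpec(key, "fixed", (p.value,))
    for name, item in params.costs.items():
        key = f"cost:{name}"
        if item.uncertainty == "gamma":
            cv = overrides.get(name, cost_cv)
            specs[key] = UncertaintySpec(key, "gamma",
                                         (item.adjusted_2020_intl_usd, cv))
        else:
            specs[key] = UncertaintySpec(key, "fixed", (item.adjusted_2020_intl_usd,))
    return specs


def degenerate_specs(params: ParameterSet) -> dict[str, UncertaintySpec]:
    """All-fixed specs: every draw reproduces the base case exactly."""
    specs = build_specs(params)
    return {k: UncertaintySpec(k, "fixed", (s.mean if s.dist != "gamma" else s.args[0],))
            for k, s in specs.items()}


def _substream(root_seed: int, name: str) -> np.random.Generator:
    # Stable per-parameter key: sha256, not Python's salted hash().
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([root_seed, key]))


def _draw_all(specs: Mapping[str, UncertaintySpec], n: int,
              seed: int) -> dict[str, np.ndarray]:
    return {name: spec.sample(_substream(seed, name), n)
            for name, spec in sorted(specs.items())}


def sample_parameter_set(specs: Mapping[str, UncertaintySpec],
                         base: ParameterSet, seed: int) -> ParameterSet:
    """One joint draw, returned as a full re-derived :class:`ParameterSet`."""
    draws = _draw_all(specs, 1, seed)
    out = base
    for node in PROB_NODES:
        out = out.with_probability(CONTROL, node, float(draws[f"prob:{node}"][0]))
    for name in base.costs:
        out = out.with_cost(name, float(draws[f"cost:{name}"][0]))
    from .parameters import derive_intervention_arm
    return derive_intervention_arm(out, base.rrr)


@dataclass(frozen=True)
class PSAOutput:
    """Per-iteration incremental results plus run metadata."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    seed: int
    n_iterations: int
    rrr: float
    metadata: dict = field(default_factory=dict)

    @property
    def draws(self) -> np.ndarray:
        """(n, 2) array of (delta_cost, delta_effect) pairs."""
        return np.column_stack([self.delta_cost, self.delta_effect])

    def summary(self) -> dict:
        dc, de = self.delta_cost, self.delta_effect
        quadrants = {
            "cheaper_more_effective": float(np.mean((dc < 0) & (de > 0))),
            "costlier_more_effective": float(np.mean((dc > 0) & (de > 0))),
            "cheaper_less_effective": float(np.mean((dc < 0) & (de < 0))),
            "costlier_less_effective": float(np.mean((dc > 0) & (de < 0))),
        }
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "rrr": self.rrr,
            "mean_delta_cost": float(dc.mean()),
            "mean_delta_effect": float(de.mean()),
            "delta_cost_p2.5": float(np.percentile(dc, 2.5)),
            "delta_cost_p97.5": float(np.percentile(dc, 97.5)),
            "delta_effect_p2.5": float(np.percentile(de, 2.5)),
            "delta_effect_p97.5": float(np.percentile(de, 97.5)),
            "quadrant_fractions": quadrants,
            **self.metadata,
        }

    def to_frame(self, wtps: tuple[float, ...] = (5_000.0, 15_000.0)) -> pd.DataFrame:
        frame = pd.DataFrame({
            "iteration": np.arange(self.n_iterations),
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
        })
        for wtp in wtps:
            frame[f"nmb_at_{int(wtp)}"] = wtp * self.delta_effect - self.delta_cost
        return frame


def run_psa(params: ParameterSet,
            specs: Mapping[str, UncertaintySpec] | None = None,
            n: int = DEFAULT_N_ITERATIONS,
            seed: int = 0,
            cost_cv: float = DEFAULT_COST_CV) -> PSAOutput:
    """Monte-Carlo PSA: n joint draws, both arms evaluated per draw."""
    if n < 1:
        raise ValidationError("n", "need at least one iteration")
    params.validate()
    if specs is None:
        specs = build_specs(params, cost_cv=cost_cv)
    draws = _draw_all(specs, n, seed)

    scale = 1.0 - params.rrr
    def prob_ctrl(node): return draws[f"prob:{node}"]
    def prob_int(node):
        d = draws[f"prob:{node}"]
        return d * scale if node in RRR_SCALED_NODES else d
    def cost_of(name): return draws[f"cost:{name}"]
    def los_ctrl(cls): return params.los_days(CONTROL, cls)
    def los_int(cls): return params.los_days(INTERVENTION, cls)

    covid = params.covid_cost_per_patient
    cost_c, pneu_c = expected_values_vectorized(prob_ctrl, cost_of, los_ctrl,
                                                CONTROL, covid)
    cost_i, pneu_i = expected_values_vectorized(prob_int, cost_of, los_int,
                                                INTERVENTION, covid)
    dc = np.asarray(cost_i - cost_c, dtype=float)
    de = np.asarray(pneu_c - pneu_i, dtype=float)
    if not (np.all(np.isfinite(dc)) and np.all(np.isfinite(de))):
        raise ValidationError("draws", "non-finite PSA draw encountered")
    meta = {"cost_cv": cost_cv,
            "mv_spec": specs.get("prob:pn_mv").dist if "prob:pn_mv" in specs else None}
    return PSAOutput(dc, de, seed=seed, n_iterations=n, rrr=params.rrr,
                     metadata=meta)
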