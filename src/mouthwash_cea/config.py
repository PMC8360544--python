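"""Run configuration: scenario selection and analysis settings.

A run is described by a small YAML document (bundled default:
``data/scenario.yaml``): the RRR, the pandemic-overlay mode and
magnitudes, the willingness-to-pay grid, PSA size/seed and the Rand
display factor.  Scenario 1 is the pandemic-free base case; scenario 2
applies the pandemic overlay before the intervention arm is re-derived.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .parameters import (CovidOverlay, ParameterSet, ValidationError,
                         apply_covid_overlay, load_parameter_set)


@dataclass(frozen=True)
class RunConfig:
    scenario: int = 1
    rrr: float = 0.3
    overlay_mode: str = "absolute_pp"
    pneumonia_increment: float = CovidOverlay.DEFAULT_ABSOLUTE
    calibrated_increment: float = CovidOverlay.DEFAULT_CALIBRATED
    covid_cost: float = CovidOverlay.DEFAULT_COST
    wtp_start: float = 0.0
    wtp_stop: float = 30_000.0
    wtp_step: float = 250.0
    psa_n: int = 10_000
    cost_cv: float = 0.2
    mv_effective_sample_size: float = 39.0
    dsa_rrr_values: tuple[float, ...] = (0.2, 0.1, 0.05, 0.01)
    dsa_rrr_context: float = 0.01
    zar_per_intl_usd: float = 17.35
    seed: int = 20210812

    def __post_init__(self):
        if self.scenario not in (1, 2):
            raise ValidationError("scenario", f"must be 1 or 2, got {self.scenario}")
        if not 0.0 <= self.rrr < 1.0:
            raise ValidationError("rrr", f"must lie in [0, 1), got {self.rrr}")
        if self.overlay_mode not in ("absolute_pp", "calibrated"):
            raise ValidationError("overlay_mode", f"unknown mode {self.overlay_mode!r}")
        if self.psa_n < 1:
            raise ValidationError("psa_n", "need at least one iteration")

    def overlay(self) -> CovidOverlay:
        if self.overlay_mode == "calibrated":
            return CovidOverlay.calibrated(self.calibrated_increment, self.covid_cost)
        return CovidOverlay.absolute(self.pneumonia_increment, self.covid_cost)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["dsa_rrr_values"] = list(self.dsa_rrr_values)
        return d

    def digest(self) -> str:
        """Stable config hash echoed into every output's metadata."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_run_config(source=None, **overrides) -> RunConfig:
    """Read the YAML run configuration (bundled default) with overrides."""
    if source is None:
        source = resources.files("mouthwash_cea.data").joinpath("scenario.yaml").open()
    cfg = yaml.safe_load(source.read() if hasattr(source, "read") else open(source).read())
    covid = cfg.get("covid", {})
    wtp = cfg.get("wtp_grid", {})
    psa = cfg.get("psa", {})
    dsa = cfg.get("dsa", {})
    kwargs = dict(
        rrr=cfg.get("rrr", 0.3),
        overlay_mode=covid.get("mode", "absolute_pp"),
        pneumonia_increment=covid.get("pneumonia_increment", CovidOverlay.DEFAULT_ABSOLUTE),
        calibrated_increment=covid.get("calibrated_increment", CovidOverlay.DEFAULT_CALIBRATED),
        covid_cost=covid.get("per_patient_cost", CovidOverlay.DEFAULT_COST),
        wtp_start=wtp.get("start", 0.0),
        wtp_stop=wtp.get("stop", 30_000.0),
        wtp_step=wtp.get("step", 250.0),
        psa_n=psa.get("n_iterations", 10_000),
        cost_cv=psa.get("cost_cv", 0.2),
        mv_effective_sample_size=psa.get("mv_effective_sample_size", 39.0),
        dsa_rrr_values=tuple(dsa.get("rrr_values", (0.2, 0.1, 0.05, 0.01))),
        dsa_rrr_context=dsa.get("rrr_context", 0.01),
        zar_per_intl_usd=cfg.get("display_zar_per_intl_usd", 17.35),
        seed=cfg.get("seed", 20210812),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def scenario_parameter_set(config: RunConfig,
                           base: ParameterSet | None = None) -> ParameterSet:
    """Parameter set for the configured scenario, overlay applied if any."""
    params = base if base is not None else load_parameter_set(
        rrr=config.rrr,
        mv_effective_sample_size=config.mv_effective_sample_size,
    )
    if config.scenario == 2:
        params = apply_covid_overlay(params, config.overlay())
    return params
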