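"""Configuration files: YAML/JSON schemas for schedules and cohorts.

A run config file looks like::

    experiment: exp1
    seed: 7
    n_subjects: 12
    strategy: internal_noise
    narrow_sigma: 1.0        # 1.3 is the alternative parameterization
    control_trials_per_likelihood: 100   # 0 disables the control task
    priors:                  # optional overrides
      narrow: {mu: 35.0, sigma: 1.0, color: white}
    likelihoods:
      low: {sigma: 0.6, n_dots: 8}
    observer:                # optional CohortParams overrides
      sigma_m_median: 0.5
      learn_rate: 0.003

Validation failures raise :class:`ConfigError` naming the offending field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import task
from .cohort import CohortParams

__all__ = ["ConfigError", "RunConfig", "load_run_config", "config_hash"]


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


class RunConfig:
    """Validated simulate-run configuration."""

    def __init__(self, raw: dict) -> None:
        self.raw = raw
        experiment = raw.get("experiment", "exp1")
        try:
            schedule = task.default_config(experiment, float(raw.get("narrow_sigma", 1.0)))
        except ValueError as exc:
            raise ConfigError(f"experiment: {exc}") from exc
        priors = dict(schedule.priors)
        for pid, spec in (raw.get("priors") or {}).items():
            try:
                priors[pid] = task.PriorSpec(
                    pid, float(spec["mu"]), float(spec["sigma"]), spec.get("color", "")
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"priors.{pid}: {exc}") from exc
        likelihoods = dict(schedule.likelihoods)
        for lid, spec in (raw.get("likelihoods") or {}).items():
            try:
                likelihoods[lid] = task.LikelihoodSpec(
                    lid, float(spec["sigma"]), int(spec.get("n_dots", 8))
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"likelihoods.{lid}: {exc}") from exc
        try:
            self.schedule = task.ScheduleConfig(
                experiment,
                priors,
                likelihoods,
                schedule.pairings_by_block,
                run_length=int(raw.get("run_length", 20)),
                prior_only_period=int(raw.get("prior_only_period", 9)),
                sd_mode=raw.get("sd_mode", "population"),
                pixel_grid=raw.get("pixel_grid"),
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        try:
            self.cohort = CohortParams(
                strategy=raw.get("strategy", "internal_noise"),
                **(raw.get("observer") or {}),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"observer: {exc}") from exc
        self.seed = int(raw.get("seed", 0))
        self.n_subjects = int(raw.get("n_subjects", 12))
        if self.n_subjects < 1:
            raise ConfigError("n_subjects: must be >= 1")
        self.control_trials = int(raw.get("control_trials_per_likelihood", 100))
        if self.control_trials < 0:
            raise ConfigError("control_trials_per_likelihood: must be >= 0")


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable config: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig(raw)


def config_hash(raw: dict) -> str:
    """Stable short hash of a config mapping (for run manifests)."""
    canon = json.dumps(raw, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
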