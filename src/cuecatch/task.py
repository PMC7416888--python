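"""Generative model of the localization task.

A hidden target is drawn from one of two Gaussian location priors on a
horizontal axis measured in percent of screen width (psw, range 0-100).
The sensory cue is a cloud of dots scattered about the target with a
condition-specific SD and rescaled so the displayed SD is exact on every
trial.  Schedules interleave prior x likelihood pairings in moment-balanced
runs, insert dot-free prior-only probe trials, and score responses with an
interval-overlap catch rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PriorSpec",
    "LikelihoodSpec",
    "ScheduleConfig",
    "Trial",
    "default_priors",
    "default_likelihoods",
    "default_config",
    "sample_run_targets",
    "generate_dot_cloud",
    "build_schedule",
    "catch_and_score",
    "schedule_to_frame",
]

EXPERIMENTS = ("exp1", "exp2", "exp3")

#: Net (response bar) width and feedback-dot diameter, psw.
NET_WIDTH = 1.0
DOT_DIAMETER = 0.5


@dataclass(frozen=True)
class PriorSpec:
    """One Gaussian location prior (mean and SD in psw)."""

    prior_id: str
    mu: float
    sigma: float
    color: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < 100.0):
            raise ValueError(f"prior mean must lie inside the screen, got {self.mu}")
        if self.sigma <= 0:
            raise ValueError(f"prior SD must be positive, got {self.sigma}")


@dataclass(frozen=True)
class LikelihoodSpec:
    """One cue-noise condition: dot-generation SD and dot count."""

    likelihood_id: str
    sigma: float
    n_dots: int = 8

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"likelihood SD must be positive, got {self.sigma}")
        if self.n_dots < 2 or self.n_dots % 2:
            raise ValueError(f"n_dots must be even and >= 2, got {self.n_dots}")


def default_priors(narrow_sigma: float = 1.0) -> dict[str, PriorSpec]:
    """Two priors: narrow at 35 psw (white target), wide at 70 psw (black).

    ``narrow_sigma`` defaults to 1.0 psw; 1.3 psw is an alternative
    parameterization kept available in configs (see docs/methods.md).
    """
    return {
        "narrow": PriorSpec("narrow", 35.0, narrow_sigma, "white"),
        "wide": PriorSpec("wide", 70.0, 2.5, "black"),
    }


def default_likelihoods(n_dots: int = 8) -> dict[str, LikelihoodSpec]:
    """Low/medium/high cue noise: 0.6, 3 and 6 psw SD, 8 dots."""
    return {
        "low": LikelihoodSpec("low", 0.6, n_dots),
        "medium": LikelihoodSpec("medium", 3.0, n_dots),
        "high": LikelihoodSpec("high", 6.0, n_dots),
    }


@dataclass(frozen=True)
class ScheduleConfig:
    """Block structure of one session.

    ``pairings_by_block`` maps 1-based block number to a dict
    ``{(prior_id, likelihood_id): n_trials}``.  ``sd_mode`` selects the SD
    convention ("population" = divide-by-n, "sample" = n-1) used both for
    dot-cloud rescaling and run-target moment matching.
    """

    experiment: str
    priors: dict[str, PriorSpec]
    likelihoods: dict[str, LikelihoodSpec]
    pairings_by_block: dict[int, dict[tuple[str, str], int]]
    run_length: int = 20
    prior_only_period: int = 9
    sd_mode: str = "population"
    pixel_grid: int | None = None  # optional rounding to an n-pixel screen

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.sd_mode not in ("population", "sample"):
            raise ValueError(f"sd_mode must be 'population' or 'sample', got {self.sd_mode!r}")
        if self.run_length < 2 or self.run_length % len(self.priors):
            raise ValueError("run_length must be a positive multiple of the number of priors")
        for block, pairings in self.pairings_by_block.items():
            for (p, l), cnt in pairings.items():
                if p not in self.priors:
                    raise ValueError(f"block {block}: unknown prior {p!r}")
                if l not in self.likelihoods:
                    raise ValueError(f"block {block}: unknown likelihood {l!r}")
                if cnt <= 0:
                    raise ValueError(f"block {block}: non-positive count for ({p}, {l})")

    @property
    def n_blocks(self) -> int:
        return len(self.pairings_by_block)

    def main_trials_in_block(self, block: int) -> int:
        return sum(self.pairings_by_block[block].values())

    @property
    def total_main_trials(self) -> int:
        return sum(self.main_trials_in_block(b) for b in self.pairings_by_block)


def default_config(experiment: str, narrow_sigma: float = 1.0) -> ScheduleConfig:
    """The study's parameterization for one of the three experiments.

    exp1/exp2 (identical schedules; they differ only in instructions given
    to subjects, which is an observer property, not a schedule property):
    blocks 1-3 hold the four low/medium pairings at 75 trials each, blocks
    4-5 introduce the high-noise cue (all six pairings at 50 each).  exp3
    holds all six pairings at 50 trials in every block.  Every block has
    300 main trials; five blocks give 1500.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}")
    priors = default_priors(narrow_sigma)
    liks = default_likelihoods()
    six = list(itertools.product(priors, liks))
    four = [(p, l) for p, l in six if l != "high"]
    if experiment in ("exp1", "exp2"):
        pairings = {b: {pl: 75 for pl in four} for b in (1, 2, 3)}
        pairings.update({b: {pl: 50 for pl in six} for b in (4, 5)})
    else:
        pairings = {b: {pl: 50 for pl in six} for b in range(1, 6)}
    return ScheduleConfig(experiment, priors, liks, pairings)


def _sd(x: np.ndarray, sd_mode: str) -> float:
    return float(np.std(x, ddof=0 if sd_mode == "population" else 1))


def sample_run_targets(
    prior: PriorSpec,
    n_targets: int,
    rng: np.random.Generator,
    sd_mode: str = "population",
) -> np.ndarray:
    """Gaussian target draws affinely corrected to exact first two moments.

    The returned sample has mean exactly ``prior.mu`` and SD exactly
    ``prior.sigma`` (x' = mu + (x - mean(x)) * sigma / sd(x)), so an ideal
    learner accumulating evidence over the run recovers the prior's
    parameters exactly.  Degenerate draws with zero sample SD are redrawn.
    """
    if n_targets < 2:
        raise ValueError(f"need at least 2 targets for moment matching, got {n_targets}")
    while True:
        x = rng.normal(prior.mu, prior.sigma, size=n_targets)
        s = _sd(x, sd_mode)
        if s > 0:
            return prior.mu + (x - x.mean()) * (prior.sigma / s)


def _dot_y_ladder(n_dots: int) -> np.ndarray:
    # symmetric about 0 with 1-psw spacing: +-0.5, +-1.5, ... for even n
    return np.arange(n_dots) - (n_dots - 1) / 2.0


def generate_dot_cloud(
    target_x: float,
    lik: LikelihoodSpec,
    rng: np.random.Generator,
    sd_mode: str = "population",
) -> tuple[np.ndarray, np.ndarray, float]:
    """One dot-cloud stimulus: iid Gaussian draws rescaled to exact SD.

    Returns ``(dot_xs, dot_ys, centroid)``.  The horizontal positions are
    rescaled about their sample mean so the displayed SD equals
    ``lik.sigma`` exactly while the centroid (the pre-rescaling sample
    mean, the ideal observer's cue statistic) is preserved.  Vertical
    offsets are the fixed symmetric ladder, assigned to dots in shuffled
    order.
    """
    while True:
        raw = rng.normal(target_x, lik.sigma, size=lik.n_dots)
        s = _sd(raw, sd_mode)
        if s > 0:
            break
    centroid = float(raw.mean())
    dot_xs = centroid + (raw - centroid) * (lik.sigma / s)
    dot_ys = _dot_y_ladder(lik.n_dots)
    rng.shuffle(dot_ys)
    return dot_xs, dot_ys, centroid


@dataclass
class Trial:
    """One scheduled stimulus (dots absent on prior-only probe trials)."""

    block: int
    index_in_block: int
    kind: str  # "main" | "prior_only"
    prior_id: str
    likelihood_id: str | None
    target_x: float
    dot_xs: np.ndarray | None = None
    dot_ys: np.ndarray | None = None
    centroid: float | None = None


def build_schedule(config: ScheduleConfig, rng: np.random.Generator) -> list[Trial]:
    """Full trial list for one session.

    Main trials are grouped into runs of ``run_length`` with equal per-prior
    counts; within each run every prior's targets are moment-corrected to
    (mu_p, sigma_p) exactly and pairings are interleaved by a seeded
    shuffle.  A short final run (when a block's count is not divisible by
    the run length) is moment-corrected at its own size.  One prior-only
    trial is inserted after every ``prior_only_period`` main trials
    (counted across the whole session), alternating prior identity; these
    probes do not count toward the per-block main-trial totals.
    """
    prior_ids = list(config.priors)
    per_prior_run = config.run_length // len(prior_ids)
    trials: list[Trial] = []
    main_count = 0
    probe_cycle = itertools.cycle(prior_ids)

    def make_main(block: int, idx: int, prior_id: str, lik_id: str, target: float) -> Trial:
        xs, ys, c = generate_dot_cloud(target, config.likelihoods[lik_id], rng, config.sd_mode)
        if config.pixel_grid:
            step = 100.0 / config.pixel_grid
            xs = np.round(xs / step) * step
            c = float(xs.mean())
        return Trial(block, idx, "main", prior_id, lik_id, target, xs, ys, c)

    def make_probe(block: int, idx: int) -> Trial:
        pid = next(probe_cycle)
        target = float(rng.normal(config.priors[pid].mu, config.priors[pid].sigma))
        return Trial(block, idx, "prior_only", pid, None, target)

    for block in sorted(config.pairings_by_block):
        pairings = config.pairings_by_block[block]
        # per-prior shuffled sequence of likelihood labels for this block
        lik_seq: dict[str, list[str]] = {}
        for pid in prior_ids:
            labels = [l for (p, l), cnt in pairings.items() if p == pid for _ in range(cnt)]
            rng.shuffle(labels)
            lik_seq[pid] = labels
        n_per_prior = {pid: len(lik_seq[pid]) for pid in prior_ids}
        if len(set(n_per_prior.values())) != 1:
            raise ValueError(f"block {block}: unequal per-prior trial counts {n_per_prior}")
        remaining = n_per_prior[prior_ids[0]]
        idx = len([t for t in trials if t.block == block])
        pos = 0
        while remaining > 0:
            k = min(per_prior_run, remaining)
            queue: dict[str, list[tuple[str, float]]] = {}
            for pid in prior_ids:
                labels = lik_seq[pid][pos : pos + k]
                if k >= 2:
                    targets = sample_run_targets(config.priors[pid], k, rng, config.sd_mode)
                else:
                    targets = np.array([config.priors[pid].mu])
                queue[pid] = list(zip(labels, targets))
            slots = [pid for pid in prior_ids for _ in range(k)]
            rng.shuffle(slots)
            for pid in slots:
                lik_id, target = queue[pid].pop(0)
                idx += 1
                trials.append(make_main(block, idx, pid, lik_id, float(target)))
                main_count += 1
                if main_count % config.prior_only_period == 0:
                    idx += 1
                    trials.append(make_probe(block, idx))
            pos += k
            remaining -= k
    return trials


def catch_and_score(
    response_x: float,
    target_x: float,
    net_width: float = NET_WIDTH,
    dot_diameter: float = DOT_DIAMETER,
) -> tuple[bool, int]:
    """Catch rule: net/target overlap of at least half the feedback dot.

    The net is the interval [response - w/2, response + w/2] and the
    feedback dot [target - d/2, target + d/2]; the target is caught iff
    their horizontal overlap is >= d/2 (with the defaults, iff
    |response - target| <= 0.5 psw).  Returns (caught, points).
    """
    overlap = min(response_x + net_width / 2, target_x + dot_diameter / 2) - max(
        response_x - net_width / 2, target_x - dot_diameter / 2
    )
    caught = overlap >= dot_diameter / 2
    return caught, int(caught)


def schedule_to_frame(trials: list[Trial], n_dots: int = 8) -> pd.DataFrame:
    """Flatten a schedule to one row per trial (dot_x_1..n columns)."""
    rows = []
    for t in trials:
        row = {
            "block": t.block,
            "trial_index": t.index_in_block,
            "kind": t.kind,
            "prior_id": t.prior_id,
            "likelihood_id": t.likelihood_id if t.likelihood_id else "",
            "target_x": t.target_x,
            "centroid": t.centroid if t.centroid is not None else np.nan,
        }
        for i in range(n_dots):
            row[f"dot_x_{i + 1}"] = t.dot_xs[i] if t.dot_xs is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
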