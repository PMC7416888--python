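"""Synthetic subject cohorts: full simulated sessions and control tasks.

The study's behavioral data are generated, not collected: each simulated
subject gets an independent schedule, per-subject noise parameters drawn
from cohort-level distributions, and a trial-by-trial simulated session.
Everything is deterministic given (configuration, seed); all per-subject
parameter draws are logged alongside the trial log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import task
from .observers import Observer, ObserverParams, STRATEGIES

__all__ = [
    "CohortParams",
    "generate_cohort",
    "generate_control_cohort",
    "generate_control_session",
    "write_log",
    "read_log",
]

LOG_SCHEMA_VERSION = "cuecatch-log-v1"

#: Median internal centroiding noise per cue condition (psw), increasing
#: with dot scatter: averaging a tight cloud is easier than a spread one.
DEFAULT_SIGMA_LI_MEDIAN = {"low": 0.6, "medium": 1.0, "high": 1.5}


@dataclass
class CohortParams:
    """Cohort-level distributions for per-subject parameters.

    sigma_li is drawn per subject and per likelihood condition from a
    log-normal centered on ``sigma_li_median`` with log-SD
    ``sigma_li_spread``; motor noise and the rote learner's rate constant
    likewise.  The transfer rule is shared across subjects.
    """

    strategy: str = "internal_noise"
    sigma_li_median: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_LI_MEDIAN)
    )
    sigma_li_spread: float = 0.3
    sigma_m_median: float = 0.5
    sigma_m_spread: float = 0.25
    learn_rate_median: float = 0.0005
    learn_rate_spread: float = 0.5
    fixed_w: float = 0.5
    transfer_rule: str = "optimal"
    lapse_rate: float = 0.0
    known_prior: bool = False
    prior_only_sampling: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")

    def draw_subject(self, rng: np.random.Generator) -> ObserverParams:
        sigma_li = {
            lik: float(med * np.exp(rng.normal(0.0, self.sigma_li_spread)))
            for lik, med in self.sigma_li_median.items()
        }
        sigma_m = float(self.sigma_m_median * np.exp(rng.normal(0.0, self.sigma_m_spread)))
        if self.sigma_m_median == 0:
            sigma_m = 0.0
        learn_rate = float(
            self.learn_rate_median * np.exp(rng.normal(0.0, self.learn_rate_spread))
        )
        return ObserverParams(
            strategy=self.strategy,
            sigma_li=sigma_li,
            sigma_m=sigma_m,
            learn_rate=learn_rate,
            fixed_w=self.fixed_w,
            transfer_rule=self.transfer_rule,
            lapse_rate=self.lapse_rate,
            known_prior=self.known_prior,
            prior_only_sampling=self.prior_only_sampling,
        )


def _session_rows(
    subject_id: str,
    experiment: str,
    trials: list[task.Trial],
    observer: Observer,
    rng: np.random.Generator,
    seed_tag: str,
    n_dots: int,
) -> list[dict]:
    rows = []
    for t in trials:
        response = observer.respond(t, rng)
        caught, _ = task.catch_and_score(response, t.target_x)
        observer.observe_feedback(t, response, t.target_x)
        row = {
            "subject_id": subject_id,
            "experiment": experiment,
            "block": t.block,
            "trial_index": t.index_in_block,
            "kind": t.kind,
            "prior_id": t.prior_id,
            "likelihood_id": t.likelihood_id if t.likelihood_id else "",
            "target_x": t.target_x,
            "centroid": t.centroid if t.centroid is not None else np.nan,
            "response_x": response,
            "error": response - t.target_x,
            "abs_error": abs(response - t.target_x),
            "caught": int(caught),
            "seed_tag": seed_tag,
        }
        for i in range(n_dots):
            row[f"dot_x_{i + 1}"] = t.dot_xs[i] if t.dot_xs is not None else np.nan
        rows.append(row)
    return rows


def generate_cohort(
    experiment: str = "exp1",
    n_subjects: int = 26,
    params: CohortParams | None = None,
    seed: int = 0,
    config: task.ScheduleConfig | None = None,
    strategy_mix: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trial_log, subject_table).

    Each subject receives a freshly seeded schedule and observer (spawned
    from ``seed``), so the whole cohort is reproducible from
    (configuration, seed).  The subject table logs every drawn parameter.
    ``strategy_mix`` maps strategy label -> proportion of subjects
    (largest-remainder apportionment, deterministic); without it every
    subject uses ``params.strategy``.  The default cohort sizes in the
    three experiments are 26, 12 and 12 subjects.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    params = params or CohortParams()
    if strategy_mix:
        bad = [s for s in strategy_mix if s not in STRATEGIES]
        if bad:
            raise ValueError(f"unknown strategies in mix: {bad}")
        total = sum(strategy_mix.values())
        quotas = {s: n_subjects * p / total for s, p in strategy_mix.items()}
        counts = {s: int(q) for s, q in quotas.items()}
        for s in sorted(quotas, key=lambda s: quotas[s] - counts[s], reverse=True):
            if sum(counts.values()) >= n_subjects:
                break
            counts[s] += 1
        strategy_seq = [s for s in strategy_mix for _ in range(counts[s])]
    else:
        strategy_seq = [params.strategy] * n_subjects
    config = config or task.default_config(experiment)
    n_dots = next(iter(config.likelihoods.values())).n_dots
    root = np.random.SeedSequence(seed)
    rows: list[dict] = []
    subject_rows: list[dict] = []
    for i, ss in enumerate(root.spawn(n_subjects)):
        sched_rng, obs_rng, draw_rng = (np.random.default_rng(s) for s in ss.spawn(3))
        sid = f"S{i + 1:03d}"
        subj_params = replace(params, strategy=strategy_seq[i]) if strategy_mix else params
        obs_params = subj_params.draw_subject(draw_rng)
        observer = Observer(obs_params, config.priors, config.likelihoods)
        trials = task.build_schedule(config, sched_rng)
        rows.extend(
            _session_rows(sid, config.experiment, trials, observer, obs_rng, f"seed{seed}", n_dots)
        )
        srow = {
            "subject_id": sid,
            "strategy": obs_params.strategy,
            "sigma_m": obs_params.sigma_m,
            "learn_rate": obs_params.learn_rate,
        }
        for lik, s in obs_params.sigma_li.items():
            srow[f"sigma_li_{lik}"] = s
        subject_rows.append(srow)
    return pd.DataFrame(rows), pd.DataFrame(subject_rows)


def generate_control_session(
    n_trials_per_likelihood: int,
    sigma_li: dict[str, float],
    sigma_m: float = 0.0,
    seed: int | np.random.Generator = 0,
    likelihoods: dict[str, task.LikelihoodSpec] | None = None,
    target_range: tuple[float, float] = (20.0, 80.0),
    subject_id: str = "S001",
) -> pd.DataFrame:
    """Prior-free centroiding task for one subject.

    Targets are scattered uniformly (no learnable prior), clouds are drawn
    per likelihood condition, and responses are centroid + internal noise
    + motor noise, so SD(centroid - response) estimates the subject's
    combined internal variability.
    """
    if n_trials_per_likelihood < 2:
        raise ValueError("need at least 2 trials per condition")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    likelihoods = likelihoods or task.default_likelihoods()
    rows = []
    idx = 0
    for lik_id, lik in likelihoods.items():
        for _ in range(n_trials_per_likelihood):
            idx += 1
            target = float(rng.uniform(*target_range))
            xs, _, centroid = task.generate_dot_cloud(target, lik, rng)
            resp = centroid + rng.normal(0.0, sigma_li.get(lik_id, 0.0)) + (
                rng.normal(0.0, sigma_m) if sigma_m > 0 else 0.0
            )
            row = {
                "subject_id": subject_id,
                "experiment": "control",
                "block": 1,
                "trial_index": idx,
                "kind": "main",
                "prior_id": "",
                "likelihood_id": lik_id,
                "target_x": target,
                "centroid": centroid,
                "response_x": resp,
                "error": resp - target,
                "abs_error": abs(resp - target),
                "caught": int(task.catch_and_score(resp, target)[0]),
                "seed_tag": "",
            }
            for i in range(lik.n_dots):
                row[f"dot_x_{i + 1}"] = xs[i]
            rows.append(row)
    return pd.DataFrame(rows)


def generate_control_cohort(
    subjects: pd.DataFrame,
    n_trials_per_likelihood: int = 100,
    seed: int = 0,
    likelihoods: dict[str, task.LikelihoodSpec] | None = None,
) -> pd.DataFrame:
    """Control sessions for every subject in a cohort's subject table,
    reusing each subject's logged sigma_li / sigma_m draws."""
    root = np.random.SeedSequence(seed)
    frames = []
    lik_cols = [c for c in subjects.columns if c.startswith("sigma_li_")]
    for (_, srow), ss in zip(subjects.iterrows(), root.spawn(len(subjects))):
        sigma_li = {c.removeprefix("sigma_li_"): srow[c] for c in lik_cols}
        frames.append(
            generate_control_session(
                n_trials_per_likelihood,
                sigma_li,
                sigma_m=srow.get("sigma_m", 0.0),
                seed=np.random.default_rng(ss),
                likelihoods=likelihoods,
                subject_id=srow["subject_id"],
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_log(log: pd.DataFrame, path) -> None:
    """Write a trial log as CSV with a schema-version header comment
    (gzip if the path ends in .gz)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", newline="") as fh:
        fh.write(f"# {LOG_SCHEMA_VERSION}\n")
        log.to_csv(fh, index=False)


def read_log(path) -> pd.DataFrame:
    """Read a trial log written by :func:`write_log` (plain or gzip)."""
    df = pd.read_csv(path, comment="#")
    for col in ("prior_id", "likelihood_id"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df
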