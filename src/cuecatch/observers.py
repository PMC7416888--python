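"""Observer models: closed-form cue weights and trial-by-trial simulation.

All observers respond with a reliability-weighted blend of the perceived
cue centroid and their current belief about the prior mean,

    response = w * (centroid + internal noise) + (1 - w) * mu_hat + motor noise,

and differ only in how the weight w on the sensory cue is set:

``ideal_bayes``
    w from the external-noise ideal formula with the true task parameters.
``bayes_transfer``
    w from the same formula, but using the prior SD the observer has
    learned from feedback and the cue SD read off the displayed cloud —
    so a freshly introduced noise level is down-weighted immediately,
    without any feedback on it (probabilistic transfer).
``internal_noise``
    w from the internal-variability-only formula sigma_p^2 / (sigma_li^2
    + sigma_p^2): the observer weights the cue by its own centroiding
    noise and ignores the external dot scatter.
``lookup_table``
    a per-condition weight learned by an error-driven delta rule, with no
    generalization: an unseen condition borrows the weight of the
    experienced condition with the nearest cue SD (rote learning).
``fixed_weight``
    a constant, configurable weight (useful for parameter recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .task import Trial

__all__ = [
    "optimal_weight",
    "internal_noise_weight",
    "overall_variability_weight",
    "posterior_weight_numeric",
    "centroid_estimators",
    "expected_catch_rate",
    "ObserverParams",
    "Observer",
    "STRATEGIES",
]

STRATEGIES = ("ideal_bayes", "bayes_transfer", "internal_noise", "lookup_table", "fixed_weight")


def optimal_weight(sigma_l: float, n: int, sigma_p: float) -> float:
    """Ideal weight on the cue: precision of the n-dot centroid vs the prior.

    w = (n / sigma_l^2) / (n / sigma_l^2 + 1 / sigma_p^2).
    """
    if sigma_l <= 0 or sigma_p <= 0:
        raise ValueError("SDs must be positive")
    if n < 1:
        raise ValueError("need at least one dot")
    prec_cue = n / sigma_l**2
    return prec_cue / (prec_cue + 1.0 / sigma_p**2)


def internal_noise_weight(sigma_li: float, sigma_p: float) -> float:
    """Weight when only internal centroiding noise counts against the cue:
    w = sigma_p^2 / (sigma_li^2 + sigma_p^2)."""
    if sigma_p <= 0:
        raise ValueError("prior SD must be positive")
    if sigma_li < 0:
        raise ValueError("internal noise SD must be non-negative")
    return sigma_p**2 / (sigma_li**2 + sigma_p**2)


def overall_variability_weight(sigma_l: float, n: int, sigma_li: float, sigma_p: float) -> float:
    """Weight from total cue variability sigma_lo^2 = sigma_l^2/n + sigma_li^2."""
    if sigma_l <= 0 or sigma_p <= 0:
        raise ValueError("SDs must be positive")
    if sigma_li < 0:
        raise ValueError("internal noise SD must be non-negative")
    var_lo = sigma_l**2 / n + sigma_li**2
    return (1.0 / var_lo) / (1.0 / var_lo + 1.0 / sigma_p**2)


def posterior_weight_numeric(
    cue_sigma: float,
    sigma_p: float,
    mu_p: float = 50.0,
    grid_halfwidth_sds: float = 12.0,
    n_grid: int = 40001,
) -> float:
    """Cue weight from an explicit grid posterior (numerical cross-check).

    Evaluates the Gaussian prior x Gaussian cue-likelihood posterior over a
    dense location grid for two displaced cue values and returns the slope
    of the posterior mean in the cue — the weight an ideal observer with
    this effective cue SD places on it.  Independent of the closed forms
    above; used to validate them.
    """
    if cue_sigma < 0 or sigma_p <= 0:
        raise ValueError("SDs must be positive")
    if cue_sigma == 0:
        return 1.0
    half = grid_halfwidth_sds * max(cue_sigma, sigma_p)
    x = np.linspace(mu_p - half, mu_p + half, n_grid)

    def post_mean(cue: float) -> float:
        logp = -0.5 * ((x - mu_p) / sigma_p) ** 2 - 0.5 * ((x - cue) / cue_sigma) ** 2
        w = np.exp(logp - logp.max())
        return float(np.trapezoid(w * x, x) / np.trapezoid(w, x))

    c0, c1 = mu_p - sigma_p, mu_p + sigma_p
    return (post_mean(c1) - post_mean(c0)) / (c1 - c0)


def _robust_average(xs: np.ndarray, n_sd: float = 2.0, max_iter: int = 50) -> float:
    """Iteratively trimmed mean: drop dots > n_sd sample SDs from the
    current mean and recompute until stable (an outlier-free cloud is left
    untrimmed, so this reduces to the mean)."""
    kept = np.asarray(xs, dtype=float)
    for _ in range(max_iter):
        m, s = kept.mean(), kept.std()
        if s == 0:
            break
        mask = np.abs(kept - m) <= n_sd * s
        if mask.all() or mask.sum() < 2:
            break
        kept = kept[mask]
    return float(kept.mean())


def centroid_estimators(dot_xs: np.ndarray) -> dict[str, float]:
    """The four candidate cue statistics: mean, robust average, median,
    mid-range."""
    xs = np.asarray(dot_xs, dtype=float)
    if xs.size < 2:
        raise ValueError("need at least two dots")
    return {
        "mean": float(xs.mean()),
        "robust_average": _robust_average(xs),
        "median": float(np.median(xs)),
        "midrange": float((xs.min() + xs.max()) / 2.0),
    }


def expected_catch_rate(
    w: float,
    sigma_l: float,
    n: int,
    sigma_p: float,
    sigma_m: float = 0.0,
    half_window: float = 0.5,
) -> float:
    """Expected catch probability for a constant-weight responder.

    The response error about the target is Gaussian with variance
    sigma_err^2 = w^2 sigma_l^2/n + (1-w)^2 sigma_p^2 + sigma_m^2 (cue
    scatter, prior scatter, motor noise), and a trial is caught when
    |error| <= half_window, so the rate is 2*Phi(half_window/sigma_err)-1.
    Maximized over w at the ideal weight when sigma_m does not depend on w
    — the quantity behind "how much reward does suboptimal weighting
    actually cost".
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight must lie in [0, 1], got {w}")
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    var_err = w**2 * sigma_l**2 / n + (1 - w) ** 2 * sigma_p**2 + sigma_m**2
    if var_err == 0:
        return 1.0
    return float(2 * stats.norm.cdf(half_window / np.sqrt(var_err)) - 1)


@dataclass
class ObserverParams:
    """Per-subject observer parameterization.

    sigma_li maps likelihood condition -> internal centroid-estimation
    noise SD (psw); sigma_m is motor noise SD (psw).  fixed_w is a scalar
    or a {(prior_id, likelihood_id): w} map for the fixed_weight strategy.
    transfer_rule selects whether bayes_transfer uses the external-noise
    ideal formula or the internal-noise formula with its learned prior SD.
    init_* seed the prior belief before any feedback (screen-center
    ignorance); lapse_rate is a hook for random-guess trials (default off).
    With ``known_prior`` the belief is clamped to the true prior
    parameters (no learning drift).  ``prior_only_sampling`` makes probe
    responses scatter with the believed prior SD (drawn from the believed
    prior) rather than sitting at its mean — the regime in which probe
    response SD tracks the learned prior's SD.
    """

    strategy: str
    sigma_li: dict[str, float] = field(default_factory=dict)
    sigma_m: float = 0.0
    learn_rate: float = 0.0005
    fixed_w: float | dict[tuple[str, str], float] = 0.5
    transfer_rule: str = "optimal"
    init_prior_mean: float = 50.0
    init_prior_sd: float = 10.0
    lapse_rate: float = 0.0
    known_prior: bool = False
    prior_only_sampling: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if any(s < 0 for s in self.sigma_li.values()) or self.sigma_m < 0:
            raise ValueError("noise SDs must be non-negative")
        ws = self.fixed_w.values() if isinstance(self.fixed_w, dict) else [self.fixed_w]
        if any(not 0 <= w <= 1 for w in ws):
            raise ValueError("fixed weights must lie in [0, 1]")
        if self.transfer_rule not in ("optimal", "internal"):
            raise ValueError("transfer_rule must be 'optimal' or 'internal'")

    def noise_sd(self, likelihood_id: str | None) -> float:
        if likelihood_id is None:
            return 0.0
        return self.sigma_li.get(likelihood_id, 0.0)


class _PriorBelief:
    """Running mean/SD of feedback locations for one prior (Welford)."""

    def __init__(self, init_mean: float, init_sd: float) -> None:
        self.init_mean = init_mean
        self.init_sd = init_sd
        self.n = 0
        self._mean = 0.0
        self._m2 = 0.0

    def update(self, x: float) -> None:
        self.n += 1
        d = x - self._mean
        self._mean += d / self.n
        self._m2 += d * (x - self._mean)

    @property
    def mean(self) -> float:
        return self._mean if self.n >= 1 else self.init_mean

    @property
    def sd(self) -> float:
        if self.n < 2:
            return self.init_sd
        s = np.sqrt(self._m2 / (self.n - 1))
        return float(s) if s > 0 else self.init_sd


class Observer:
    """Stateful trial-by-trial observer.

    Call :meth:`respond` for each scheduled trial, then
    :meth:`observe_feedback` with the revealed target so the prior belief
    (and, for lookup_table, the condition weights) can update.
    """

    def __init__(self, params: ObserverParams, priors, likelihoods) -> None:
        self.params = params
        self.priors = priors
        self.likelihoods = likelihoods
        if params.known_prior:
            self.beliefs = {
                pid: _PriorBelief(spec.mu, spec.sigma) for pid, spec in priors.items()
            }
        else:
            self.beliefs = {
                pid: _PriorBelief(params.init_prior_mean, params.init_prior_sd) for pid in priors
            }
        # lookup_table state: learned weight and update-scale per condition
        self.table: dict[tuple[str, str], float] = {}
        self._scale: dict[tuple[str, str], float] = {}
        self._last: tuple | None = None

    # -- weight selection ------------------------------------------------
    def _lookup_weight(self, prior_id: str, lik_id: str) -> float:
        key = (prior_id, lik_id)
        if key in self.table:
            return self.table[key]
        seen = [(p, l) for (p, l) in self.table if p == prior_id] or list(self.table)
        if not seen:
            return 1.0
        sigma = self.likelihoods[lik_id].sigma
        nearest = min(seen, key=lambda k: abs(self.likelihoods[k[1]].sigma - sigma))
        return self.table[nearest]

    def weight(self, trial: Trial, cloud_sd: float | None = None) -> float:
        """Weight on the cue the observer applies to this trial."""
        p = self.params
        prior = self.priors[trial.prior_id]
        lik = self.likelihoods[trial.likelihood_id]
        if p.strategy == "fixed_weight":
            if isinstance(p.fixed_w, dict):
                return p.fixed_w[(trial.prior_id, trial.likelihood_id)]
            return p.fixed_w
        if p.strategy == "ideal_bayes":
            return optimal_weight(lik.sigma, lik.n_dots, prior.sigma)
        if p.strategy == "internal_noise":
            return internal_noise_weight(
                p.noise_sd(trial.likelihood_id), self.beliefs[trial.prior_id].sd
            )
        if p.strategy == "bayes_transfer":
            sd_hat = cloud_sd if cloud_sd is not None else lik.sigma
            believed = self.beliefs[trial.prior_id].sd
            if p.transfer_rule == "internal":
                return internal_noise_weight(p.noise_sd(trial.likelihood_id), believed)
            return optimal_weight(sd_hat, lik.n_dots, believed)
        return self._lookup_weight(trial.prior_id, trial.likelihood_id)

    # -- simulation ------------------------------------------------------
    def respond(self, trial: Trial, rng: np.random.Generator) -> float:
        """Simulate the response to one trial (does not update beliefs)."""
        p = self.params
        mu_hat = self.beliefs[trial.prior_id].mean
        motor = rng.normal(0.0, p.sigma_m) if p.sigma_m > 0 else 0.0
        if trial.kind == "prior_only":
            self._last = (trial, None, None, mu_hat)
            if p.prior_only_sampling:
                return float(rng.normal(mu_hat, self.beliefs[trial.prior_id].sd)) + motor
            return mu_hat + motor
        if p.lapse_rate > 0 and rng.random() < p.lapse_rate:
            resp = rng.uniform(0.0, 100.0)
            self._last = (trial, None, None, mu_hat)
            return resp
        sigma_li = p.noise_sd(trial.likelihood_id)
        perceived = trial.centroid + (rng.normal(0.0, sigma_li) if sigma_li > 0 else 0.0)
        cloud_sd = float(np.std(trial.dot_xs)) if trial.dot_xs is not None else None
        w = self.weight(trial, cloud_sd)
        self._last = (trial, perceived, w, mu_hat)
        return w * perceived + (1 - w) * mu_hat + motor

    def observe_feedback(self, trial: Trial, response: float, target: float) -> None:
        """Update prior belief (all strategies) and, for lookup_table, the
        condition weight via a variance-normalized delta rule."""
        if self._last is not None and self.params.strategy == "lookup_table":
            last_trial, perceived, w, mu_hat = self._last
            if last_trial is trial and perceived is not None:
                key = (trial.prior_id, trial.likelihood_id)
                if key not in self.table:
                    self.table[key] = self._lookup_weight(*key)
                    # start the normalizer at the observable scale of
                    # (c - mu_hat): cloud variance / n plus believed
                    # prior variance (both computable on this trial)
                    lik = self.likelihoods[trial.likelihood_id]
                    cloud_var = (
                        float(np.var(trial.dot_xs)) if trial.dot_xs is not None else lik.sigma**2
                    )
                    believed_var = self.beliefs[trial.prior_id].sd ** 2
                    self._scale[key] = max(cloud_var / lik.n_dots + believed_var, 1.0)
                # running scale of (perceived - mu_hat)^2 normalizes the
                # gradient so learn_rate is a per-trial fractional step
                self._scale[key] += 0.1 * ((perceived - mu_hat) ** 2 - self._scale[key])
                grad = (response - target) * (perceived - mu_hat) / max(self._scale[key], 1e-6)
                self.table[key] = float(np.clip(self.table[key] - self.params.learn_rate * grad, 0.0, 1.0))
        if not self.params.known_prior:
            self.beliefs[trial.prior_id].update(target)
        self._last = None
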