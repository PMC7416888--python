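"""Analysis chain: from trial logs to cue weights, model fits and contrasts.

The chain mirrors how such localization data are analyzed: exclude
gross-error trials (top 1% of absolute errors per pairing), regress
responses on cue centroids to read off per-cell weights, compare candidate
cue statistics by R^2, summarize prior-only probe trials, estimate each
subject's internal centroiding noise from the control task, derive the
three candidate models' predicted weights, and compare them to the fitted
weights by mean squared error.  Transfer is quantified by the
medium-vs-high weight gap in the first block containing the high-noise cue
and by the change in the high-noise weight over the following block, both
with bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .observers import internal_noise_weight, optimal_weight, overall_variability_weight
from .task import PriorSpec, LikelihoodSpec, default_likelihoods, default_priors

__all__ = [
    "exclude_outliers",
    "fit_weights",
    "estimator_r2",
    "prior_only_summary",
    "estimate_internal_noise",
    "model_predictions",
    "model_mse",
    "transfer_contrast",
    "bootstrap_ci",
    "analyze_log",
]

MODELS = ("external", "internal", "overall")


def exclude_outliers(
    log: pd.DataFrame, percentile: float = 99.0
) -> tuple[pd.DataFrame, dict]:
    """Drop main trials whose |error| is strictly above the per-pairing
    99th percentile (pooled across blocks and subjects).

    Uses the linear-interpolation percentile; ties at the threshold are
    kept (strict inequality), so a degenerate all-equal pairing drops
    nothing.  Returns (filtered log, report) where the report carries
    per-pairing thresholds/counts and per-subject drop counts.
    """
    main = log[log["kind"] == "main"]
    drop_idx: list = []
    pairing_rows = []
    for (pid, lid), grp in main.groupby(["prior_id", "likelihood_id"]):
        if grp.empty:
            warnings.warn(f"empty pairing ({pid}, {lid}) skipped")
            continue
        thr = float(np.percentile(grp["abs_error"], percentile))
        bad = grp.index[grp["abs_error"] > thr]
        drop_idx.extend(bad)
        pairing_rows.append(
            {
                "prior_id": pid,
                "likelihood_id": lid,
                "threshold": thr,
                "n_trials": len(grp),
                "n_dropped": len(bad),
            }
        )
    dropped = log.loc[drop_idx]
    per_subject = (
        dropped.groupby(["subject_id", "prior_id", "likelihood_id"]).size().rename("n_dropped")
        if "subject_id" in log.columns and len(dropped)
        else pd.Series(dtype=int, name="n_dropped")
    )
    report = {
        "per_pairing": pd.DataFrame(pairing_rows),
        "per_subject": per_subject.reset_index() if len(per_subject) else pd.DataFrame(),
        "max_dropped_per_subject_pairing": int(per_subject.max()) if len(per_subject) else 0,
        "n_dropped_total": len(drop_idx),
    }
    return log.drop(index=drop_idx), report


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = slope*x + intercept, plus R^2."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return float(slope), float(intercept), r2


def fit_weights(
    log: pd.DataFrame,
    grain: str = "per_block",
    min_trials: int = 10,
) -> pd.DataFrame:
    """Per-cell weight on the cue: OLS slope of response on centroid.

    ``grain`` is "per_block" (subject x prior x likelihood x block, the
    default, matching block-resolved weight figures) or "pooled" (blocks
    collapsed).  Cells with fewer than ``min_trials`` trials or a constant
    centroid are flagged and not fitted; slopes outside [-0.2, 1.2] are
    fitted but flagged.
    """
    if grain not in ("per_block", "pooled"):
        raise ValueError("grain must be 'per_block' or 'pooled'")
    keys = ["subject_id", "prior_id", "likelihood_id"]
    if grain == "per_block":
        keys.append("block")
    main = log[(log["kind"] == "main") & log["centroid"].notna()]
    rows = []
    for key, grp in main.groupby(keys):
        rec = dict(zip(keys, key))
        rec["n_trials"] = len(grp)
        x = grp["centroid"].to_numpy(float)
        y = grp["response_x"].to_numpy(float)
        if len(grp) < min_trials or np.ptp(x) == 0:
            rec.update(slope=np.nan, intercept=np.nan, r2=np.nan, flagged=True)
        else:
            slope, intercept, r2 = _ols_line(x, y)
            rec.update(
                slope=slope,
                intercept=intercept,
                r2=r2,
                flagged=not (-0.2 <= slope <= 1.2),
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def estimator_r2(log: pd.DataFrame, n_dots: int = 8) -> tuple[dict[str, float], str]:
    """R^2 of responses against each candidate cue statistic.

    Pooled across subjects, blocks and trial types; the statistic with the
    highest R^2 is the one responders most plausibly extracted from the
    cloud.  Requires the dot_x_* columns.
    """
    from .observers import _robust_average

    dot_cols = [f"dot_x_{i + 1}" for i in range(n_dots)]
    missing = [c for c in dot_cols if c not in log.columns]
    if missing:
        raise ValueError(f"log lacks dot position columns: {missing}")
    main = log[(log["kind"] == "main") & log[dot_cols[0]].notna()]
    dots = main[dot_cols].to_numpy(float)
    y = main["response_x"].to_numpy(float)
    ests = {
        "mean": dots.mean(axis=1),
        "robust_average": np.array([_robust_average(row) for row in dots]),
        "median": np.median(dots, axis=1),
        "midrange": (dots.min(axis=1) + dots.max(axis=1)) / 2.0,
    }
    r2 = {name: _ols_line(x, y)[2] for name, x in ests.items()}
    best = max(r2, key=r2.get)
    return r2, best


def prior_only_summary(
    log: pd.DataFrame, priors: dict[str, PriorSpec] | None = None
) -> pd.DataFrame:
    """Prior-learning summary from the dot-free probe trials.

    Per prior: mean response bias (mean response minus true prior mean)
    across subjects with a one-sample t-test against zero, and the median
    across subjects of each subject's response SD, next to the true prior
    SD.  An unbiased learner yields bias near 0 and median SD near
    sigma_p.
    """
    priors = priors or default_priors()
    probes = log[log["kind"] == "prior_only"]
    rows = []
    for pid, grp in probes.groupby("prior_id"):
        if pid not in priors:
            warnings.warn(f"prior {pid!r} not in the prior table; skipped")
            continue
        per_subj = grp.groupby("subject_id")["response_x"].agg(["mean", "std"])
        biases = per_subj["mean"] - priors[pid].mu
        t, p = stats.ttest_1samp(biases, 0.0) if len(biases) > 1 else (np.nan, np.nan)
        rows.append(
            {
                "prior_id": pid,
                "n_subjects": len(per_subj),
                "mean_bias": float(biases.mean()),
                "t_vs_zero": float(t),
                "p_value": float(p),
                "median_response_sd": float(per_subj["std"].median()),
                "true_sigma_p": priors[pid].sigma,
            }
        )
    for pid in priors:
        if not (probes["prior_id"] == pid).any():
            warnings.warn(f"no prior-only trials for prior {pid!r}; omitted")
    return pd.DataFrame(rows)


def estimate_internal_noise(
    control_log: pd.DataFrame, per_condition: bool = True
) -> pd.DataFrame:
    """Internal variability per subject: SD of (centroid - response).

    Estimated from the prior-free control task; necessarily measures
    centroiding and motor noise combined.  With ``per_condition`` a
    separate SD is returned per likelihood condition, else pooled.
    """
    keys = ["subject_id"] + (["likelihood_id"] if per_condition else [])
    rows = []
    for key, grp in control_log.groupby(keys):
        if len(grp) < 3:
            raise ValueError(f"cell {key} has fewer than 3 control trials")
        err = grp["centroid"] - grp["response_x"]
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec["sigma_li_hat"] = float(err.std(ddof=1))
        rec["n_trials"] = len(grp)
        rows.append(rec)
    return pd.DataFrame(rows)


def model_predictions(
    sigma_li: pd.DataFrame | None = None,
    priors: dict[str, PriorSpec] | None = None,
    likelihoods: dict[str, LikelihoodSpec] | None = None,
    subjects: list[str] | None = None,
) -> pd.DataFrame:
    """Predicted cue weights per subject x condition for the three models.

    ``external`` ignores internal noise (ideal weight from the imposed dot
    scatter); ``internal`` uses only the subject's estimated internal
    variability; ``overall`` combines both.  ``sigma_li`` is the table
    from :func:`estimate_internal_noise`; without it only the external
    column is filled (with a warning).
    """
    priors = priors or default_priors()
    likelihoods = likelihoods or default_likelihoods()
    if sigma_li is None:
        warnings.warn("no internal-noise estimates: internal/overall columns empty")
        subjects = subjects or ["pooled"]
        lookup = {}
    else:
        subjects = subjects or sorted(sigma_li["subject_id"].unique())
        per_cond = "likelihood_id" in sigma_li.columns
        lookup = {
            (r["subject_id"], r.get("likelihood_id", None)): r["sigma_li_hat"]
            for _, r in sigma_li.iterrows()
        }
        if not per_cond:
            lookup = {(s, None): v for (s, _), v in lookup.items()}
    rows = []
    for sid in subjects:
        for pid, prior in priors.items():
            for lid, lik in likelihoods.items():
                s_li = lookup.get((sid, lid), lookup.get((sid, None), np.nan))
                rows.append(
                    {
                        "subject_id": sid,
                        "prior_id": pid,
                        "likelihood_id": lid,
                        "w_external": optimal_weight(lik.sigma, lik.n_dots, prior.sigma),
                        "w_internal": internal_noise_weight(s_li, prior.sigma)
                        if np.isfinite(s_li)
                        else np.nan,
                        "w_overall": overall_variability_weight(
                            lik.sigma, lik.n_dots, s_li, prior.sigma
                        )
                        if np.isfinite(s_li)
                        else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def model_mse(
    weights: pd.DataFrame,
    predictions: pd.DataFrame,
    block: int | str = "final",
) -> pd.DataFrame:
    """MSE of each model's predicted weights against fitted weights.

    By default uses the final-block fitted weights over all conditions.
    Returns one row per model, ranked ascending by MSE — the winning model
    is the best account of how responders set their cue weights.
    """
    w = weights[~weights["flagged"].astype(bool)] if "flagged" in weights else weights
    if "block" in w.columns and block is not None:
        b = int(w["block"].max()) if block == "final" else int(block)
        w = w[w["block"] == b]
    merged = w.merge(predictions, on=["subject_id", "prior_id", "likelihood_id"], how="inner")
    if merged.empty:
        raise ValueError("no overlapping (subject, condition) cells between weights and predictions")
    rows = []
    for model in MODELS:
        col = f"w_{model}"
        ok = merged[merged[col].notna()]
        rows.append(
            {
                "model": model,
                "mse": float(((ok["slope"] - ok[col]) ** 2).mean()) if len(ok) else np.nan,
                "n_cells": len(ok),
            }
        )
    out = pd.DataFrame(rows).sort_values("mse").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    ci: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for the mean of ``values``:
    (mean, lower, upper)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(values, float)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return float(values.mean()), float(lo), float(hi)


def transfer_contrast(
    weights: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Transfer test around the first block containing the high-noise cue.

    ``immediate_gap``: per-subject weight(medium) - weight(high) in that
    block (averaged over priors), with a bootstrap CI over subjects.  A
    gap reliably above zero is the signature of probabilistic transfer —
    the new noise level is down-weighted at once.  ``exposure_slope``:
    per-subject change in weight(high) from that block to the next; a
    reliable decrease is the rote-learning signature (the weight only
    falls with feedback exposure).
    """
    if "block" not in weights.columns:
        raise ValueError("transfer contrast needs per-block weights")
    high = weights[weights["likelihood_id"] == "high"].dropna(subset=["slope"])
    if high.empty:
        raise ValueError("no high-likelihood cells: transfer contrast not applicable")
    b0 = int(high["block"].min())
    rng = np.random.default_rng(seed)

    def per_subject_mean(df: pd.DataFrame) -> pd.Series:
        return df.groupby("subject_id")["slope"].mean()

    w_med = per_subject_mean(
        weights[(weights["likelihood_id"] == "medium") & (weights["block"] == b0)]
    )
    w_high = per_subject_mean(high[high["block"] == b0])
    gaps = (w_med - w_high).dropna()
    g_mean, g_lo, g_hi = bootstrap_ci(gaps.to_numpy(), n_boot, seed=rng)
    out = {
        "first_high_block": b0,
        "immediate_gap": g_mean,
        "immediate_gap_ci": (g_lo, g_hi),
        "n_subjects": len(gaps),
    }
    nxt = high[high["block"] == b0 + 1]
    if len(nxt):
        slopes = (per_subject_mean(nxt) - per_subject_mean(high[high["block"] == b0])).dropna()
        s_mean, s_lo, s_hi = bootstrap_ci(slopes.to_numpy(), n_boot, seed=rng)
        out.update(exposure_slope=s_mean, exposure_slope_ci=(s_lo, s_hi))
    else:
        out.update(exposure_slope=np.nan, exposure_slope_ci=(np.nan, np.nan))
    return out


def analyze_log(
    log: pd.DataFrame,
    control_log: pd.DataFrame | None = None,
    priors: dict[str, PriorSpec] | None = None,
    likelihoods: dict[str, LikelihoodSpec] | None = None,
    grain: str = "per_block",
    min_trials: int = 10,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Run the full chain on one trial log; returns a results dict.

    Keys: ``weights`` (per-cell table), ``exclusion`` (report),
    ``estimator_r2``, ``best_estimator``, ``prior_only``, and — when a
    control log is given — ``sigma_li``, ``predictions``, ``model_mse``.
    ``transfer`` is filled when high-likelihood cells exist, else marked
    not applicable.
    """
    priors = priors or default_priors()
    likelihoods = likelihoods or default_likelihoods()
    filtered, report = exclude_outliers(log)
    weights = fit_weights(filtered, grain=grain, min_trials=min_trials)
    n_dots = next(iter(likelihoods.values())).n_dots
    r2, best = estimator_r2(filtered, n_dots=n_dots)
    out = {
        "weights": weights,
        "exclusion": report,
        "estimator_r2": r2,
        "best_estimator": best,
        "prior_only": prior_only_summary(filtered, priors),
    }
    if control_log is not None:
        sigma_li = estimate_internal_noise(control_log)
        preds = model_predictions(sigma_li, priors, likelihoods)
        out["sigma_li"] = sigma_li
        out["predictions"] = preds
        out["model_mse"] = model_mse(weights, preds)
    if grain == "per_block" and (weights["likelihood_id"] == "high").any():
        try:
            out["transfer"] = {"applicable": True, **transfer_contrast(weights, n_boot=n_boot, seed=seed)}
        except ValueError as exc:
            out["transfer"] = {"applicable": False, "reason": str(exc)}
    else:
        out["transfer"] = {"applicable": False, "reason": "no high-likelihood per-block cells"}
    return out
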