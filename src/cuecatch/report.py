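"""Human-readable markdown reports from a run summary JSON."""

from __future__ import annotations

import pandas as pd

__all__ = ["render_report"]


def _weights_table(weights: pd.DataFrame, predictions: pd.DataFrame | None) -> str:
    """Mean fitted weight per (prior, likelihood, block) with the three
    model reference values alongside when available."""
    cell = (
        weights.dropna(subset=["slope"])
        .groupby(["prior_id", "likelihood_id", "block"])["slope"]
        .mean()
        .reset_index()
    )
    if cell.empty:
        return "_no cells_\n"
    pivot = cell.pivot_table(index=["prior_id", "likelihood_id"], columns="block", values="slope")
    lines = ["| prior | likelihood | " + " | ".join(f"block {b}" for b in pivot.columns) + " |"]
    lines.append("|" + "---|" * (2 + len(pivot.columns)))
    for (pid, lid), row in pivot.iterrows():
        vals = " | ".join("" if pd.isna(v) else f"{v:.3f}" for v in row)
        lines.append(f"| {pid} | {lid} | {vals} |")
    out = "\n".join(lines) + "\n"
    if predictions is not None and len(predictions):
        ref = (
            predictions.groupby(["prior_id", "likelihood_id"])[
                ["w_external", "w_internal", "w_overall"]
            ]
            .mean()
            .reset_index()
        )
        lines = [
            "\nModel reference weights (mean over subjects; the dashed/dotted-line analogues):\n",
            "| prior | likelihood | external (ideal) | internal-noise | overall |",
            "|---|---|---|---|---|",
        ]
        for _, r in ref.iterrows():
            lines.append(
                f"| {r.prior_id} | {r.likelihood_id} | {r.w_external:.3f} | "
                f"{r.w_internal:.3f} | {r.w_overall:.3f} |"
            )
        out += "\n".join(lines) + "\n"
    return out


def render_report(summary: dict) -> str:
    """Markdown report: weights by block, estimator R^2, prior-only
    summary, model MSE ranking and the transfer contrast."""
    parts = ["# Localization run report\n"]
    weights = summary.get("weights")
    if weights is None or not len(weights):
        return parts[0] + "\n_no cells_\n"
    parts.append("## Weight on the likelihood by condition and block\n")
    parts.append(_weights_table(weights, summary.get("predictions")))
    if "estimator_r2" in summary:
        parts.append("\n## Cue-statistic comparison (R^2 of responses)\n")
        for name, r2 in sorted(summary["estimator_r2"].items(), key=lambda kv: -kv[1]):
            parts.append(f"- {name}: {r2:.4f}")
        parts.append(f"\nBest statistic: **{summary['best_estimator']}**\n")
    po = summary.get("prior_only")
    if po is not None and len(po):
        parts.append("\n## Prior-only probe trials\n")
        parts.append("| prior | mean bias | t | p | median response SD | true sigma_p |")
        parts.append("|---|---|---|---|---|---|")
        for _, r in po.iterrows():
            parts.append(
                f"| {r.prior_id} | {r.mean_bias:.3f} | {r.t_vs_zero:.2f} | "
                f"{r.p_value:.3f} | {r.median_response_sd:.2f} | {r.true_sigma_p:.2f} |"
            )
    mse = summary.get("model_mse")
    if mse is not None and len(mse):
        parts.append("\n## Model comparison (MSE vs final-block weights)\n")
        parts.append("| rank | model | MSE | cells |")
        parts.append("|---|---|---|---|")
        for _, r in mse.iterrows():
            parts.append(f"| {int(r['rank'])} | {r.model} | {r.mse:.4f} | {int(r.n_cells)} |")
    tr = summary.get("transfer") or {}
    parts.append("\n## Transfer contrast\n")
    if tr.get("applicable", False):
        lo, hi = tr["immediate_gap_ci"]
        parts.append(
            f"- immediate medium-vs-high weight gap (block {tr['first_high_block']}): "
            f"{tr['immediate_gap']:.3f} (95% CI {lo:.3f}, {hi:.3f}; n={tr['n_subjects']})"
        )
        slo, shi = tr["exposure_slope_ci"]
        parts.append(
            f"- high-noise weight change with one more block of exposure: "
            f"{tr['exposure_slope']:.3f} (95% CI {slo:.3f}, {shi:.3f})"
        )
    else:
        parts.append(f"- not applicable: {tr.get('reason', 'no high-likelihood cells')}")
    return "\n".join(parts) + "\n"
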