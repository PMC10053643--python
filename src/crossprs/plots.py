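"""Figure outputs for the evaluation stage.

All functions take computed results and save static matplotlib figures
plus the plain-text data behind them (density export for case/control
score distributions, ROC points, calibration table), so figures can be
regenerated or restyled without re-running the pipeline.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats


def save_evaluation_plots(result, score: np.ndarray, y: np.ndarray,
                          out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _density_plot(score, y, out)
    _quartile_or_plot(result, out)
    _calibration_plot(result, out)
    _roc_plot(score, y, out)


def _density_plot(score, y, out: Path) -> None:
    y = np.asarray(y, dtype=bool)
    grid = np.linspace(np.min(score), np.max(score), 200)
    data = {"score": grid}
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, mask in (("control", ~y), ("case", y)):
        vals = np.asarray(score)[mask]
        if len(vals) > 1 and np.std(vals) > 0:
            dens = stats.gaussian_kde(vals)(grid)
        else:
            dens = np.zeros_like(grid)
        data[f"density_{label}"] = dens
        ax.plot(grid, dens, label=label)
    ax.set_xlabel("PRS")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "score_density.png", dpi=150)
    plt.close(fig)
    pd.DataFrame(data).to_csv(out / "score_density.tsv", sep="\t", index=False)


def _quartile_or_plot(result, out: Path) -> None:
    t = result.quartile_ors
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.errorbar(t["quartile"], t["or"],
                yerr=[t["or"] - t["ci_low"], t["ci_high"] - t["or"]],
                fmt="o", capsize=3)
    ax.set_xlabel("PRS quartile (vs Q1)")
    ax.set_ylabel("odds ratio")
    ax.set_xticks([2, 3, 4])
    fig.tight_layout()
    fig.savefig(out / "quartile_or.png", dpi=150)
    plt.close(fig)


def _calibration_plot(result, out: Path) -> None:
    t = result.calibration
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.plot(t["quartile"], t["observed_prevalence"], "o-", label="observed")
    ax.plot(t["quartile"], t["mean_fitted"], "s--", label="fitted")
    ax.set_xlabel("PRS quartile")
    ax.set_ylabel("disease probability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "calibration.png", dpi=150)
    plt.close(fig)
    t.to_csv(out / "calibration.tsv", sep="\t", index=False)


def _roc_plot(score, y, out: Path) -> None:
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(np.asarray(y, dtype=int), np.asarray(score))
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    fig.tight_layout()
    fig.savefig(out / "roc.png", dpi=150)
    plt.close(fig)
    pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
        out / "roc.tsv", sep="\t", index=False)


def save_forest_plot(resampling_result, out_dir,
                     label: str = "subsample") -> None:
    """Point estimate with empirical 95% interval against the comparator."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r = resampling_result
    med = float(np.median(r.r2_values))
    fig, ax = plt.subplots(figsize=(5, 2.2))
    ax.errorbar([med], [0], xerr=[[med - r.ci_low], [r.ci_high - med]],
                fmt="o", capsize=4, label=label)
    ax.axvline(r.comparator_r2, color="firebrick", ls="--",
               label="comparator")
    ax.set_yticks([])
    ax.set_xlabel("liability-adjusted R²")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "forest.png", dpi=150)
    plt.close(fig)
    pd.DataFrame([{"label": label, "median_r2": med, "ci_low": r.ci_low,
                   "ci_high": r.ci_high, "comparator_r2": r.comparator_r2,
                   "empirical_p": r.empirical_p}]).to_csv(
        out / "forest.tsv", sep="\t", index=False)
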