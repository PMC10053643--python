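"""Resampling comparison of PRS performance between unequal cohorts, and
the supporting power simulation.

A large cohort is repeatedly sub-sampled (without replacement within an
iteration) to the case/control counts of a smaller comparator cohort; each
sub-sample is evaluated with the same covariate-adjusted liability-R²
machinery as the main analysis, and the empirical p-value for the
hypothesis that the comparator's R² is lower is

    P = (N_below + 1) / (N_iter + 1)

where ``N_below`` counts iterations whose sub-sample R² fell below the
comparator value. The add-one smoothing means the p-value is never zero
and never below ``1/(N_iter+1)``.

The power simulation asks how detectable a shift in mean PRS between cases
and controls is at given case/control counts: scores are drawn
Normal(0, 1) for controls and Normal(delta, 1) for cases, case status is
regressed on the score by logistic regression, and power is the fraction
of iterations whose Wald p-value for the score coefficient is below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import ConfigurationError, InputError
from .evaluation import evaluate_prs, select_optimal


@dataclass
class ResamplingResult:
    """Sub-sampling comparison output."""

    n_iter: int
    r2_values: np.ndarray           # per-iteration liability-adjusted R²
    comparator_r2: float
    n_below: int
    empirical_p: float
    ci_low: float                   # empirical 2.5th percentile of R²
    ci_high: float                  # empirical 97.5th percentile
    n_cases: int
    n_controls: int
    degenerate_iterations: int = 0  # flagged fits, retained in the count

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["r2_values"] = np.asarray(self.r2_values).tolist()
        return d


def empirical_p_value(n_below: int, n_iter: int) -> float:
    """Add-one-smoothed empirical p: (N_below + 1)/(N_iter + 1)."""
    if n_iter < 1 or not (0 <= n_below <= n_iter):
        raise InputError("need 0 <= n_below <= n_iter, n_iter >= 1")
    return (n_below + 1) / (n_iter + 1)


def subsample_compare(scores: pd.DataFrame | pd.Series | np.ndarray,
                      phenotype: np.ndarray,
                      covariates: pd.DataFrame,
                      n_cases: int, n_controls: int,
                      comparator_r2: float,
                      n_iter: int = 1000, seed: int = 0,
                      K: float = 0.002,
                      reoptimize: bool = True) -> ResamplingResult:
    """Sub-sample the large cohort and compare its R² with a comparator.

    ``scores`` may be a single score vector or a DataFrame of candidate
    score vectors (e.g. one per p-value threshold at the fixed optimal
    clumping r²). With ``reoptimize`` (the default) the best-fitting
    candidate is re-selected inside every sub-sample by lowest model-fit
    p-value, mirroring optimal-score selection in the comparator cohort;
    otherwise the single given configuration is used as-is. Iterations
    with degenerate fits (quasi-separation) still yield an R² and are
    retained.
    """
    if isinstance(scores, (pd.Series, np.ndarray, list)):
        score_matrix = pd.DataFrame({"score": np.asarray(scores, dtype=float)})
    else:
        score_matrix = scores.astype(float)
    if not reoptimize and score_matrix.shape[1] != 1:
        raise ConfigurationError(
            "reoptimize=False requires a single score column")
    y = np.asarray(phenotype, dtype=int)
    n = len(y)
    if len(score_matrix) != n or len(covariates) != n:
        raise InputError("score/phenotype/covariate lengths differ")
    case_idx = np.flatnonzero(y == 1)
    control_idx = np.flatnonzero(y == 0)
    if len(case_idx) < n_cases or len(control_idx) < n_controls:
        raise InputError(
            f"cohort has {len(case_idx)} cases / {len(control_idx)} controls; "
            f"cannot draw {n_cases}/{n_controls}")

    rng = np.random.default_rng(seed)
    cov = covariates.reset_index(drop=True)
    values = score_matrix.to_numpy()
    r2s = np.empty(n_iter)
    degenerate = 0
    for it in range(n_iter):
        take = np.concatenate([
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(control_idx, size=n_controls, replace=False),
        ])
        y_sub = y[take]
        cov_sub = cov.iloc[take].reset_index(drop=True)
        candidates = [
            evaluate_prs(values[take, j], y_sub, cov_sub, K=K,
                         config_label=str(score_matrix.columns[j]),
                         minimal=True)
            for j in range(values.shape[1])
        ]
        best = select_optimal(candidates) if len(candidates) > 1 else candidates[0]
        r2s[it] = best.r2_liability_adjusted
        if best.separation:
            degenerate += 1

    n_below = int((r2s < comparator_r2).sum())
    lo, hi = np.percentile(r2s, [2.5, 97.5])
    return ResamplingResult(
        n_iter=n_iter, r2_values=r2s, comparator_r2=float(comparator_r2),
        n_below=n_below, empirical_p=empirical_p_value(n_below, n_iter),
        ci_low=float(lo), ci_high=float(hi),
        n_cases=n_cases, n_controls=n_controls,
        degenerate_iterations=degenerate,
    )


@dataclass
class PowerCurve:
    """Simulated power across a grid of standardized mean differences."""

    delta_grid: np.ndarray
    power: np.ndarray
    n_significant: np.ndarray
    n_cases: int
    n_controls: int
    n_iter: int
    alpha: float

    def to_dict(self) -> dict:
        return {
            "delta_grid": np.asarray(self.delta_grid).tolist(),
            "power": np.asarray(self.power).tolist(),
            "n_significant": np.asarray(self.n_significant).tolist(),
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "n_iter": self.n_iter, "alpha": self.alpha,
        }


def power_simulation(n_cases: int = 42, n_controls: int = 40_490,
                     delta_grid=(0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
                     n_iter: int = 1000, alpha: float = 0.05,
                     seed: int = 0) -> PowerCurve:
    """Power to detect a case/control shift in a normally distributed PRS.

    Fresh data are simulated for every iteration; significance is the Wald
    z-test of the score coefficient in a logistic regression of case
    status on score.
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    delta_grid = np.asarray(delta_grid, dtype=float)
    if (delta_grid < 0).any():
        raise ConfigurationError("deltas must be >= 0")
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n_controls), np.ones(n_cases)]
    n_sig = np.zeros(len(delta_grid), dtype=int)
    for d, delta in enumerate(delta_grid):
        for _ in range(n_iter):
            x = np.concatenate([
                rng.normal(0.0, 1.0, n_controls),
                rng.normal(delta, 1.0, n_cases),
            ])
            p = _wald_p_logistic(y, x)
            if p < alpha:
                n_sig[d] += 1
    return PowerCurve(delta_grid, n_sig / n_iter, n_sig,
                      n_cases, n_controls, n_iter, alpha)


def _wald_p_logistic(y: np.ndarray, x: np.ndarray) -> float:
    """Two-sided Wald p for the slope of logit(y) ~ 1 + x."""
    X = np.column_stack([np.ones(len(x)), x])
    try:
        res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
        return float(res.pvalues[1])
    except np.linalg.LinAlgError:
        return 1.0
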