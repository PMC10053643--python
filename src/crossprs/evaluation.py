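"""Covariate-adjusted evaluation of polygenic scores in a case/control cohort.

For each score the full logistic model (intercept + standardized PRS + age
+ sex + PCs 1-4) is compared with the covariate-only null model. The model
fit p-value is the 1-df likelihood-ratio test of the PRS term; variance
explained is Nagelkerke's pseudo-R² of the full model against the
covariate-only null (so it isolates the PRS increment) and is converted to
the liability scale with the standard ascertainment correction for
case/control sampling at population prevalence K:

    t = Phi^-1(1 - K),  z = phi(t),  m = z / K
    e = 1 - P^(2P) (1-P)^(2(1-P))
    C = K(1-K)/z² · K(1-K)/(P(1-P)) · e
    theta = m·(P-K)/(1-K) · (m·(P-K)/(1-K) - t)
    R²_liability = C·R² / (1 + C·theta·R²)

with P the sample case proportion (``e`` maps Nagelkerke's rescaled R²
back to the observed Cox-Snell scale before the liability conversion).
When the sample is unascertained (P = K) the correction reduces to C·R². Discrimination is summarized by
rank-based AUCs of the full-model and null-model fitted probabilities and
of the raw score, and by quartile odds ratios (Q2-Q4 versus Q1) from a
covariate-adjusted logistic fit with Wald 95% intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .containers import ConfigurationError, InputError
from .engine import PrsResult

COVARIATE_COLUMNS = ("age", "sex", "pc1", "pc2", "pc3", "pc4")


# ----------------------------------------------------------------------
# logistic regression
# ----------------------------------------------------------------------

@dataclass
class LogisticFit:
    loglik: float
    params: np.ndarray
    bse: np.ndarray
    fitted: np.ndarray
    converged: bool
    separation: bool
    n: int
    names: list


def fit_logistic(y: np.ndarray, X: np.ndarray,
                 names: list | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit (Newton / IRLS via statsmodels).

    Raises :class:`InputError` for a single-class response or a
    rank-deficient design (naming the dependent columns). Quasi-separated
    fits are flagged, not silently returned.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if len(np.unique(y)) < 2:
        raise InputError("response has a single class; cannot fit")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        dependent = _dependent_columns(X, names)
        raise InputError(f"design matrix is rank deficient; dependent "
                         f"columns: {dependent}")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100,
                                     tol=1e-8)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            # fall back to a damped solver; flag the fit
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=200)
            separation = True
    fitted = np.asarray(res.predict())
    if not separation:
        separation = bool(np.abs(res.params).max() > 30
                          or not res.mle_retvals.get("converged", True))
    return LogisticFit(
        loglik=float(res.llf), params=np.asarray(res.params),
        bse=np.asarray(res.bse), fitted=fitted,
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation, n=len(y), names=list(names),
    )


def _dependent_columns(X: np.ndarray, names: list) -> list:
    """Identify columns not independent of their predecessors (QR sweep)."""
    dependent = []
    kept = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        trial = np.hstack([kept, X[:, j:j + 1]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept = trial
        else:
            dependent.append(names[j])
    return dependent


# ----------------------------------------------------------------------
# pseudo-R² and liability adjustment
# ----------------------------------------------------------------------

def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's pseudo-R² of a full model against a nested null.

    ``R²_CS = 1 - exp(2(l0 - l1)/n)`` rescaled by its maximum
    ``R²_max = 1 - exp(2 l0 / n)``.
    """
    if n <= 0:
        raise InputError("n must be positive")
    if loglik_full < loglik_null - 1e-8:
        raise InputError("loglik_full must be >= loglik_null (nested models)")
    r2_cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    r2_max = 1.0 - np.exp(2.0 * loglik_null / n)
    if r2_max <= 0:
        return 0.0
    return float(max(r2_cs, 0.0) / r2_max)


@dataclass
class LiabilityParams:
    """Quantities of the liability-scale ascertainment correction.

    ``K``: population prevalence; ``P_case``: sample case proportion;
    derived terms (threshold ``t``, density ``z``, mean case liability
    ``m``, scaling ``C``, ascertainment term ``theta``) follow the standard
    case/control-to-liability conversion.
    """

    K: float
    P_case: float
    t: float = field(init=False)
    z: float = field(init=False)
    m: float = field(init=False)
    C: float = field(init=False)
    theta: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.K < 1.0):
            raise ConfigurationError(f"K must lie in (0, 1), got {self.K}")
        if not (0.0 < self.P_case < 1.0):
            raise ConfigurationError(
                f"P_case must lie in (0, 1), got {self.P_case}")
        K, P = self.K, self.P_case
        self.t = float(stats.norm.ppf(1.0 - K))
        self.z = float(stats.norm.pdf(self.t))
        self.m = self.z / K
        # e converts Nagelkerke's R2 back to the Cox-Snell (observed) scale:
        # it equals R2_max = 1 - exp(2 l0/n) of a null model with case
        # fraction P. Without it the conversion would treat the rescaled
        # Nagelkerke value as an observed-scale R2 and overstate liability
        # variance several-fold (it could exceed h2).
        e = 1.0 - P ** (2 * P) * (1 - P) ** (2 * (1 - P))
        self.C = (K * (1 - K) / self.z ** 2) \
            * (K * (1 - K) / (P * (1 - P))) * e
        d = self.m * (P - K) / (1 - K)
        self.theta = d * (d - self.t)


def liability_adjust(r2_observed: float, params: LiabilityParams) -> float:
    """Convert an observed-scale pseudo-R² to the liability scale under
    case ascertainment: ``C·R² / (1 + C·theta·R²)``."""
    if not (0.0 <= r2_observed < 1.0):
        raise InputError(f"r2_observed must lie in [0, 1), got {r2_observed}")
    C, theta = params.C, params.theta
    return float(C * r2_observed / (1.0 + C * theta * r2_observed))


# ----------------------------------------------------------------------
# AUC and quartiles
# ----------------------------------------------------------------------

def rank_auc(score: np.ndarray, y: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney with midranks for ties)."""
    y = np.asarray(y, dtype=bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise InputError("AUC needs both cases and controls")
    ranks = stats.rankdata(score)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def assign_quartiles(score: np.ndarray) -> np.ndarray:
    """Quartile labels 1-4 by score rank.

    Cut points fall at ranks n/4, 2n/4, 3n/4; tied scores keep their input
    order (stable sort), so quartile sizes are as equal as n allows.
    """
    n = len(score)
    order = np.argsort(score, kind="stable")
    q = np.empty(n, dtype=int)
    q[order] = np.arange(n) * 4 // n + 1
    return q


# ----------------------------------------------------------------------
# full evaluation
# ----------------------------------------------------------------------

@dataclass
class EvalResult:
    """Everything the evaluation stage reports for one score."""

    config_label: str
    n_snps_included: int
    r2_nagelkerke_observed: float
    r2_liability_adjusted: float
    fit_p: float
    auc_full: float
    auc_null: float
    auc_prs_only: float
    quartile_ors: pd.DataFrame          # quartile, or, ci_low, ci_high, defined
    calibration: pd.DataFrame           # quartile, n, cases, controls,
                                        # observed_prevalence, mean_fitted
    n_cases: int
    n_controls: int
    separation: bool = False
    order_index: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("quartile_ors", "calibration")}
        d["quartile_ors"] = self.quartile_ors.to_dict(orient="records")
        d["calibration"] = self.calibration.to_dict(orient="records")
        return d


def evaluate_prs(prs: PrsResult | np.ndarray, phenotype: np.ndarray,
                 covariates: pd.DataFrame, K: float = 0.002,
                 config_label: str | None = None, n_snps: int | None = None,
                 minimal: bool = False) -> EvalResult:
    """Fit full and null logistic models for one score and report model
    fit, liability-adjusted R², AUCs, quartile ORs and calibration.

    ``minimal=True`` computes only the model-fit quantities (fit_p and the
    two R² values) — used by resampling loops where AUC/quartile output
    would be discarded.
    """
    if isinstance(prs, PrsResult):
        raw = np.asarray(prs.scores, dtype=float)
        config_label = config_label or prs.config_label
        n_snps = prs.n_snps_included if n_snps is None else n_snps
    else:
        raw = np.asarray(prs, dtype=float)
        config_label = config_label or "score"
        n_snps = -1 if n_snps is None else n_snps
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if len(raw) != n or len(covariates) != n:
        raise InputError("score/phenotype/covariate lengths differ")
    cov_cols = [c for c in COVARIATE_COLUMNS if c in covariates.columns]
    C = covariates[cov_cols].to_numpy(dtype=float)
    n_cases = int(y.sum())
    n_controls = n - n_cases

    sd = raw.std()
    constant_score = sd == 0 or not np.isfinite(sd)
    prs_std = np.zeros(n) if constant_score else (raw - raw.mean()) / sd

    X_null = np.column_stack([np.ones(n), C])
    null_fit = fit_logistic(y, X_null, ["const", *cov_cols])
    if constant_score:
        full_fit = null_fit
        lrt = 0.0
        fit_p = 1.0
    else:
        X_full = np.column_stack([np.ones(n), prs_std, C])
        full_fit = fit_logistic(y, X_full, ["const", "prs", *cov_cols])
        lrt = max(2.0 * (full_fit.loglik - null_fit.loglik), 0.0)
        fit_p = float(stats.chi2.sf(lrt, df=1))

    r2_obs = nagelkerke_r2(full_fit.loglik, null_fit.loglik, n)
    params = LiabilityParams(K=K, P_case=y.mean())
    r2_liab = liability_adjust(min(r2_obs, 1 - 1e-12), params)

    if minimal:
        empty = pd.DataFrame()
        return EvalResult(config_label, n_snps, r2_obs, r2_liab, fit_p,
                          np.nan, np.nan, np.nan, empty, empty,
                          n_cases, n_controls,
                          separation=full_fit.separation or null_fit.separation)

    auc_full = rank_auc(full_fit.fitted, y)
    auc_null = rank_auc(null_fit.fitted, y)
    auc_prs = rank_auc(raw, y)

    quart = assign_quartiles(raw)
    quartile_ors = _quartile_odds_ratios(y, quart, C, cov_cols)
    calibration = _calibration_table(y, quart, full_fit.fitted)

    return EvalResult(
        config_label, n_snps, r2_obs, r2_liab, fit_p,
        auc_full, auc_null, auc_prs, quartile_ors, calibration,
        n_cases, n_controls,
        separation=full_fit.separation or null_fit.separation,
    )


def _quartile_odds_ratios(y, quart, C, cov_cols) -> pd.DataFrame:
    """Covariate-adjusted ORs of Q2-Q4 against Q1 with Wald 95% CIs.

    A contrast involving a quartile without cases (including the reference)
    is reported as undefined rather than as a diverging estimate.
    """
    case_by_q = {q: int(y[quart == q].sum()) for q in (1, 2, 3, 4)}
    ref_ok = case_by_q[1] > 0 and case_by_q[1] < int((quart == 1).sum())
    rows = []
    estimable = [q for q in (2, 3, 4)
                 if ref_ok and 0 < case_by_q[q] < int((quart == q).sum())]
    params = {}
    if estimable:
        indicators = np.column_stack([(quart == q).astype(float)
                                      for q in estimable])
        X = np.column_stack([np.ones(len(y)), indicators, C])
        names = ["const", *[f"q{q}" for q in estimable], *cov_cols]
        try:
            fit = fit_logistic(y, X, names)
            for i, q in enumerate(estimable):
                b, se = fit.params[1 + i], fit.bse[1 + i]
                params[q] = (np.exp(b), np.exp(b - 1.96 * se),
                             np.exp(b + 1.96 * se), not fit.separation)
        except InputError:
            pass
    for q in (2, 3, 4):
        if q in params:
            or_, lo, hi, ok = params[q]
            rows.append({"quartile": q, "or": or_, "ci_low": lo,
                         "ci_high": hi, "defined": ok})
        else:
            rows.append({"quartile": q, "or": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "defined": False})
    return pd.DataFrame(rows)


def _calibration_table(y, quart, fitted) -> pd.DataFrame:
    rows = []
    for q in (1, 2, 3, 4):
        mask = quart == q
        nq = int(mask.sum())
        cases = int(y[mask].sum())
        rows.append({
            "quartile": q,
            "n": nq,
            "cases": cases,
            "controls": nq - cases,
            "observed_prevalence": cases / nq if nq else np.nan,
            "mean_fitted": float(fitted[mask].mean()) if nq else np.nan,
        })
    return pd.DataFrame(rows)


def select_optimal(results: list) -> EvalResult:
    """The score with the lowest model-fit p-value.

    Ties break toward larger liability-adjusted R², then fewer variants,
    then input order; the winner's ``order_index`` records its position.
    """
    if not results:
        raise InputError("select_optimal needs a non-empty result list")
    for i, r in enumerate(results):
        r.order_index = i
    n_snps_key = lambda r: r.n_snps_included if r.n_snps_included >= 0 else np.inf
    return min(results, key=lambda r: (r.fit_p, -r.r2_liability_adjusted,
                                       n_snps_key(r), r.order_index))
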