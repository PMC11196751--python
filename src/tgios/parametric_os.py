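"""Parametric overall-survival pathway.

Kaplan–Meier estimation, univariate Cox screening (Breslow ties),
accelerated-failure-time (AFT) regression over a set of log-location-scale
families with AIC-based family selection, likelihood-ratio backward
stepwise elimination, and per-patient survival-curve prediction.

All AFT families are parameterized on log time:

    log T = beta0 + x.beta + sigma * eps

with eps standard normal (lognormal), minimum-Gumbel (weibull; sigma = 1
fixed gives exponential) or standard logistic (loglogistic).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "KaplanMeierCurve",
    "km_estimate",
    "ScreeningResult",
    "cox_univariate_screen",
    "ParametricOSModel",
    "fit_parametric_survival",
    "backward_eliminate",
    "predict_parametric_curves",
    "AFT_FAMILIES",
]

AFT_FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic")


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass
class KaplanMeierCurve:
    """Product-limit estimate: step function, right-continuous, S(0) = 1."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n: int = 0

    def evaluate(self, times) -> np.ndarray:
        """Step-function value of S at arbitrary times (vectorized)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    @property
    def last_event_time(self) -> float:
        return float(self.event_times[-1]) if self.event_times.size else 0.0


def km_estimate(times, events) -> KaplanMeierCurve:
    """Kaplan–Meier product-limit estimator under right censoring."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("times must be > 0")
    if not np.all(np.isin(e, (0, 1))):
        raise ValueError("events must be 0/1")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for u in uniq:
        r = int(np.sum(t >= u))
        d = int(np.sum((t == u) & (e == 1)))
        s *= 1.0 - d / r
        surv.append(s)
        at_risk.append(r)
        n_ev.append(d)
    return KaplanMeierCurve(
        event_times=uniq,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
        n=t.size,
    )


# ---------------------------------------------------------------------------
# Univariate Cox screening


@dataclass
class ScreeningResult:
    covariate: str
    hazard_ratio: float
    coef: float
    se: float
    p_value: float
    n: int
    degenerate: bool = False


def _cox_breslow_loglik(beta: float, x: np.ndarray, t: np.ndarray, e: np.ndarray):
    """Breslow partial log-likelihood, gradient and information (1 covariate).

    Arrays must be sorted by descending time so risk sets are prefix sums.
    """
    w = np.exp(beta * x)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x)
    s2 = np.cumsum(w * x * x)
    # Breslow ties: every event at time u uses the full risk set {t >= u};
    # with descending sort, the risk-set prefix ends at the LAST index of u.
    last_of_time = np.r_[t[:-1] != t[1:], True]
    idx_last = np.minimum.accumulate(
        np.where(last_of_time, np.arange(t.size), t.size)[::-1]
    )[::-1]
    ev = e == 1
    j = idx_last[ev]
    ll = float(np.sum(beta * x[ev] - np.log(s0[j])))
    grad = float(np.sum(x[ev] - s1[j] / s0[j]))
    info = float(np.sum(s2[j] / s0[j] - (s1[j] / s0[j]) ** 2))
    return ll, grad, info


def _cox_fit_single(x: np.ndarray, t: np.ndarray, e: np.ndarray):
    order = np.argsort(-t, kind="stable")
    x, t, e = x[order], t[order], e[order]
    xc = x - x.mean()  # center for numerical stability
    beta = 0.0
    for _ in range(50):
        ll, grad, info = _cox_breslow_loglik(beta, xc, t, e)
        if info <= 0:
            break
        step = grad / info
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        if abs(step) < 1e-10:
            break
    _, _, info = _cox_breslow_loglik(beta, xc, t, e)
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    return beta, se


def cox_univariate_screen(
    features: pd.DataFrame, survival: pd.DataFrame
) -> list[ScreeningResult]:
    """One single-covariate proportional-hazards fit per feature column.

    Rows with a missing value in the screened column are dropped (the
    per-feature ``n`` reports what remained). Constant features are flagged
    degenerate with p = 1 by convention. Wald p-values.
    """
    surv = survival.set_index("patient_id")
    feats = features.set_index("patient_id") if "patient_id" in features else features
    results = []
    for col in feats.columns:
        joined = pd.concat(
            [feats[col], surv[["time_days", "event"]]], axis=1, join="inner"
        ).dropna()
        x = joined[col].to_numpy(dtype=float)
        t = joined["time_days"].to_numpy(dtype=float)
        e = joined["event"].to_numpy(dtype=int)
        if x.size == 0 or np.ptp(x) == 0 or e.sum() == 0:
            results.append(
                ScreeningResult(col, 1.0, 0.0, float("inf"), 1.0, int(x.size), True)
            )
            continue
        beta, se = _cox_fit_single(x, t, e)
        p = float(2 * stats.norm.sf(abs(beta) / se)) if np.isfinite(se) else 1.0
        results.append(
            ScreeningResult(col, math.exp(beta), beta, se, p, int(x.size), False)
        )
    return results


# ---------------------------------------------------------------------------
# Parametric AFT regression


def _eps_logpdf_logsf(family: str, z: np.ndarray):
    if family == "lognormal":
        return stats.norm.logpdf(z), stats.norm.logsf(z)
    if family == "loglogistic":
        return stats.logistic.logpdf(z), stats.logistic.logsf(z)
    # weibull / exponential: minimum-Gumbel error, S(z) = exp(-exp(z))
    zc = np.clip(z, -700, 700)
    return zc - np.exp(zc), -np.exp(zc)


def _aft_negloglik(params, X, logt, event, family, fixed_scale):
    k = X.shape[1]
    beta = params[:k]
    sigma = fixed_scale if fixed_scale is not None else math.exp(params[k])
    z = (logt - X @ beta) / sigma
    lp, ls = _eps_logpdf_logsf(family, z)
    # density of T: f_eps(z) / (sigma * t)
    ll = np.sum(np.where(event == 1, lp - math.log(sigma) - logt, ls))
    return -float(ll)


@dataclass
class ParametricOSModel:
    """Fitted AFT model: family, coefficients (location scale), dispersion."""

    family: str
    coefficients: pd.Series  # includes "intercept"
    scale: float
    log_likelihood: float
    aic: float
    covariates: list
    n: int
    n_events: int
    cov_matrix: np.ndarray | None = None
    elimination_trace: list = field(default_factory=list)

    def standard_errors(self) -> pd.Series:
        if self.cov_matrix is None:
            raise ValueError("covariance unavailable")
        k = len(self.coefficients)
        return pd.Series(
            np.sqrt(np.diag(self.cov_matrix)[:k]), index=self.coefficients.index
        )

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariates if c not in covariates.columns]
        if missing:
            raise KeyError(f"missing retained feature(s): {missing}")
        eta = np.full(len(covariates), self.coefficients["intercept"])
        for c in self.covariates:
            eta = eta + self.coefficients[c] * covariates[c].to_numpy(dtype=float)
        return eta

    def survival_function(self, covariates: pd.DataFrame, times) -> np.ndarray:
        """S(t | x) matrix of shape (n_patients, n_times)."""
        t = np.asarray(times, dtype=float)
        eta = self.linear_predictor(covariates)
        with np.errstate(divide="ignore"):
            logt = np.where(t > 0, np.log(np.maximum(t, 1e-300)), -np.inf)
        z = (logt[None, :] - eta[:, None]) / self.scale
        _, ls = _eps_logpdf_logsf(self.family, z)
        s = np.exp(ls)
        s[:, t <= 0] = 1.0
        return s

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": self.coefficients.to_dict(),
            "scale": self.scale,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "covariates": list(self.covariates),
            "n": self.n,
            "n_events": self.n_events,
        }


def _fit_one_family(
    X: np.ndarray, logt: np.ndarray, event: np.ndarray, family: str, names: list
) -> ParametricOSModel | None:
    fixed_scale = 1.0 if family == "exponential" else None
    err_family = "weibull" if family == "exponential" else family
    k = X.shape[1]
    x0 = np.zeros(k + (0 if fixed_scale else 1))
    x0[0] = float(np.mean(logt))
    if fixed_scale is None:
        ev_sd = float(np.std(logt[event == 1])) if event.sum() > 1 else 1.0
        x0[k] = math.log(max(ev_sd, 0.1))
    res = minimize(
        _aft_negloglik,
        x0,
        args=(X, logt, event, err_family, fixed_scale),
        method="BFGS",
        options={"maxiter": 500, "gtol": 1e-7},
    )
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        return None
    n_par = res.x.size
    ll = -float(res.fun)
    try:
        H = approx_hess(res.x, _aft_negloglik, args=(X, logt, event, err_family, fixed_scale))
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    sigma = fixed_scale if fixed_scale is not None else math.exp(res.x[k])
    return ParametricOSModel(
        family=family,
        coefficients=pd.Series(res.x[:k], index=names),
        scale=float(sigma),
        log_likelihood=ll,
        aic=2 * n_par - 2 * ll,
        covariates=[c for c in names if c != "intercept"],
        n=X.shape[0],
        n_events=int(event.sum()),
        cov_matrix=cov,
    )


def _design(features: pd.DataFrame, survival: pd.DataFrame, covariates: list):
    feats = features.set_index("patient_id") if "patient_id" in features else features
    surv = survival.set_index("patient_id")
    joined = pd.concat(
        [feats[covariates], surv[["time_days", "event"]]], axis=1, join="inner"
    ).dropna()
    if len(joined) == 0:
        raise ValueError("no complete-case rows")
    X = np.column_stack(
        [np.ones(len(joined))] + [joined[c].to_numpy(dtype=float) for c in covariates]
    )
    logt = np.log(joined["time_days"].to_numpy(dtype=float))
    event = joined["event"].to_numpy(dtype=int)
    return X, logt, event, ["intercept"] + list(covariates)


def fit_parametric_survival(
    features: pd.DataFrame,
    survival: pd.DataFrame,
    covariates: list | None = None,
    families=AFT_FAMILIES,
) -> ParametricOSModel:
    """Fit each requested AFT family by ML; return the lowest-AIC fit.

    Complete-case on the requested covariates. Ties in AIC are broken by
    the order of ``AFT_FAMILIES``; a family that fails to converge is
    skipped with a warning.
    """
    if not families:
        raise ValueError("at least one family required")
    unknown = set(families) - set(AFT_FAMILIES)
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}")
    if covariates is None:
        covariates = [
            c for c in features.columns if c not in ("patient_id",)
        ]
    X, logt, event, names = _design(features, survival, covariates)
    fits = []
    for fam in AFT_FAMILIES:
        if fam not in families:
            continue
        m = _fit_one_family(X, logt, event, fam, names)
        if m is None:
            warnings.warn(f"AFT family {fam!r} failed to converge; skipped")
            continue
        fits.append(m)
    if not fits:
        raise RuntimeError("all requested AFT families failed to converge")
    return min(fits, key=lambda m: m.aic)


def backward_eliminate(
    features: pd.DataFrame,
    survival: pd.DataFrame,
    covariates: list,
    alpha: float = 0.01,
    families=AFT_FAMILIES,
) -> ParametricOSModel:
    """Backward stepwise elimination with likelihood-ratio tests.

    The family is selected once on the full model and held fixed so the
    per-round models stay nested. Each round drops the covariate with the
    largest LRT p-value >= ``alpha`` (ties broken alphabetically) and
    refits, until every retained covariate is significant. Deterministic
    and independent of input column order.
    """
    full = fit_parametric_survival(features, survival, covariates, families)
    family = full.family
    current = full
    retained = sorted(covariates)
    trace = []
    while retained:
        X, logt, event, names = _design(features, survival, retained)
        pvals = {}
        for c in sorted(retained):
            reduced_cov = [r for r in retained if r != c]
            Xr, logtr, eventr, namesr = _design(features, survival, reduced_cov)
            reduced = _fit_one_family(Xr, logtr, eventr, family, namesr)
            if reduced is None:
                pvals[c] = 0.0  # cannot drop what cannot be refit without
                continue
            lr = 2 * (current.log_likelihood - reduced.log_likelihood)
            pvals[c] = float(stats.chi2.sf(max(lr, 0.0), df=1))
        worst = max(sorted(pvals), key=lambda c: pvals[c])
        if pvals[worst] < alpha:
            break
        retained = [r for r in retained if r != worst]
        trace.append({"removed": worst, "p_value": pvals[worst]})
        Xr, logtr, eventr, namesr = _design(features, survival, retained)
        current = _fit_one_family(Xr, logtr, eventr, family, namesr)
        if current is None:
            raise RuntimeError("refit after elimination failed")
    current.elimination_trace = trace
    return current


def predict_parametric_curves(
    model: ParametricOSModel, covariates: pd.DataFrame, grid
) -> pd.DataFrame:
    """Per-patient survival curves S(t | x) on a time grid.

    Index is the patient id (taken from a ``patient_id`` column or the
    frame's index); columns are the grid times.
    """
    cov = covariates.set_index("patient_id") if "patient_id" in covariates else covariates
    t = np.asarray(grid, dtype=float)
    s = model.survival_function(cov, t)
    return pd.DataFrame(s, index=cov.index, columns=t)
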