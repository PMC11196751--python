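"""Biexponential tumor-growth-inhibition (TGI) model.

The tumor-size trajectory is

    SLD(t) = SLD0 * (exp(-KS * t) + exp(KG * t) - 1)

with shrinkage rate KS and regrowth rate KG (both 1/day). Its minimizer,
time-to-tumor-growth, has the closed form TTG = ln(KS/KG) / (KS + KG),
clamped at 0 when KS <= KG (a never-shrinking tumor regrows immediately).

Fitting is an empirical-Bayes scheme: penalized least-squares MAP fits per
patient (log-parameterized for positivity) alternating with moment-based
population updates — a deterministic, self-contained stand-in for a full
nonlinear mixed-effects marginal-likelihood fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "biexp_sld",
    "ttg",
    "evaluability_filter",
    "TGIIndividual",
    "TGIPopulation",
    "GroupPrior",
    "fit_individual",
    "fit_population",
    "goodness_of_fit",
    "individuals_to_frame",
]

_LOG_KG_FLOOR = math.log(1e-6)  # lower bound for log(KG), 1/day
_LOG_KS_FLOOR = math.log(1e-6)
_PARAM_NAMES = ("log_sld0", "log_ks", "log_kg")

# Columns of the exported per-patient TGI metrics table.
TGI_METRICS_COLUMNS = [
    "patient_id",
    "SLD0",
    "KS",
    "KG",
    "TTG",
    "logKS",
    "logKG",
    "converged",
]


def _check_positive(**kwargs: float) -> None:
    for name, val in kwargs.items():
        if not np.all(np.isfinite(val)) or np.any(np.asarray(val) <= 0):
            raise ValueError(f"{name} must be finite and > 0")


def biexp_sld(t, sld0: float, ks: float, kg: float):
    """Tumor size (mm) at time ``t`` days; vectorized over ``t``.

    Equals ``sld0`` at t=0, decays at rate ``ks`` and regrows at rate ``kg``.
    """
    _check_positive(sld0=sld0, ks=ks, kg=kg)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = sld0 * (np.exp(-ks * t) + np.exp(kg * t) - 1.0)
    return out if out.ndim else float(out)


def ttg(ks: float, kg: float) -> float:
    """Time-to-tumor-growth (days): the minimizer of the trajectory.

    Closed form ``ln(ks/kg) / (ks + kg)``, clamped at 0 for ks <= kg.
    """
    _check_positive(ks=ks, kg=kg)
    return max(0.0, math.log(ks / kg) / (ks + kg))


def evaluability_filter(table: pd.DataFrame) -> tuple[set, set]:
    """Partition patients into (evaluable, excluded) id sets.

    A patient is evaluable iff they have a baseline (time-0) record and at
    least one record at time > 0.
    """
    evaluable: set = set()
    excluded: set = set()
    if len(table) == 0:
        return evaluable, excluded
    for pid, grp in table.groupby("patient_id", sort=False):
        t = grp["time_days"].to_numpy(dtype=float)
        if np.any(t == 0) and np.any(t > 0):
            evaluable.add(pid)
        else:
            excluded.add(pid)
    return evaluable, excluded


@dataclass
class TGIIndividual:
    """Per-patient TGI parameter estimates on the natural scale."""

    patient_id: object
    sld0_mm: float
    ks_per_day: float
    kg_per_day: float
    ttg_days: float
    fit_sse: float
    converged: bool
    at_bounds: bool = False

    @property
    def log_params(self) -> np.ndarray:
        return np.log([self.sld0_mm, self.ks_per_day, self.kg_per_day])


@dataclass
class GroupPrior:
    """Log-scale population prior for one group: means, variances, residual SD."""

    mu: np.ndarray  # (log_sld0, log_ks, log_kg)
    omega2: np.ndarray  # same order; floored when used as penalty weights
    sigma_mm: float


@dataclass
class TGIPopulation:
    """Population-level estimates: per-group log-means and IIV variances."""

    mu: dict  # label -> ndarray(3) of (log_sld0, log_ks, log_kg) means
    omega2: dict  # label -> ndarray(3); NaN when a group has < 2 patients
    sigma_mm: float
    log_likelihood: float = float("nan")
    n_iterations: int = 0
    converged: bool = False
    param_names: tuple = field(default=_PARAM_NAMES)

    def prior_for(self, label: str) -> GroupPrior:
        om = self.omega2.get(label)
        if om is None or np.any(~np.isfinite(om)):
            finite = [v for v in self.omega2.values() if np.all(np.isfinite(v))]
            om = np.mean(finite, axis=0) if finite else np.full(3, 0.25)
        return GroupPrior(mu=self.mu[label], omega2=om, sigma_mm=self.sigma_mm)


def _objective(theta, t, y, prior: GroupPrior | None, sigma: float):
    """Penalized SSE on log parameters, with analytic gradient."""
    sld0, ks, kg = np.exp(theta)
    decay = np.exp(-ks * t)
    # cap the growth exponent so extreme iterates stay finite; the gradient
    # of a capped term is zeroed to stay consistent
    g_exp = kg * t
    capped = g_exp > 50.0
    grow = np.exp(np.minimum(g_exp, 50.0))
    model = sld0 * (decay + grow - 1.0)
    resid = model - y
    inv_s2 = 1.0 / (sigma * sigma)
    val = 0.5 * inv_s2 * float(resid @ resid)
    # d(model)/d(log params)
    d0 = model
    d1 = sld0 * (-ks * t) * decay
    d2 = sld0 * np.where(capped, 0.0, g_exp) * grow
    grad = inv_s2 * np.array([resid @ d0, resid @ d1, resid @ d2])
    if prior is not None:
        om = np.maximum(prior.omega2, 1e-4)
        dev = theta - prior.mu
        val += 0.5 * float(np.sum(dev * dev / om))
        grad += dev / om
    return val, grad


def _posterior_var(t, y, theta, omega2, sigma) -> np.ndarray:
    """Gauss-Newton approximation to the posterior variance of the log
    parameters at the MAP estimate (used in the EM variance update)."""
    sld0, ks, kg = np.exp(theta)
    decay = np.exp(-ks * t)
    grow = np.exp(np.minimum(kg * t, 50.0))
    model = sld0 * (decay + grow - 1.0)
    D = np.vstack([model, sld0 * (-ks * t) * decay, sld0 * (kg * t) * grow])
    H = D @ D.T / (sigma * sigma) + np.diag(1.0 / np.maximum(omega2, 1e-4))
    try:
        return np.diag(np.linalg.inv(H)).copy()
    except np.linalg.LinAlgError:
        return np.zeros(3)


def fit_individual(
    times: Sequence[float],
    sld: Sequence[float],
    patient_id: object = None,
    init: TGIIndividual | None = None,
    prior: GroupPrior | None = None,
) -> TGIIndividual:
    """MAP fit of one patient's trajectory.

    Minimizes the residual sum of squares on the log-parameter scale; when a
    ``prior`` is given a quadratic penalty ``(theta - mu)^2 / omega2``
    (scaled against ``sigma_mm``) shrinks the fit toward the population
    means. Without a prior, at least 3 measurements are required (the model
    has 3 parameters). Uses three deterministic jittered starts; optimizer
    failure yields ``converged=False`` with the best iterate, never an
    exception.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(sld, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and sld must be 1-d and of equal length")
    if prior is None and t.size < 3:
        raise ValueError(
            f"{t.size} measurements under-determine the 3-parameter model; "
            "supply a population prior"
        )
    if t.size == 0:
        raise ValueError("no measurements")
    sigma = prior.sigma_mm if prior is not None else 1.0
    sigma = max(sigma, 1e-3)

    y0 = max(float(y[np.argmin(t)]), 1.0)
    if init is not None:
        start = init.log_params.copy()
    elif prior is not None:
        start = prior.mu.copy()
    else:
        start = np.array([math.log(y0), math.log(0.05), math.log(0.005)])
    # Deterministic multi-start: base point plus two fixed jitters.
    jitters = [
        np.zeros(3),
        np.array([0.0, 1.0, 1.0]),
        np.array([0.0, -1.0, -1.0]),
    ]
    bounds = [(math.log(1e-2), math.log(1e4)), (_LOG_KS_FLOOR, math.log(10.0)),
              (_LOG_KG_FLOOR, math.log(10.0))]
    best = None
    for jit in jitters:
        res = minimize(
            _objective,
            start + jit,
            args=(t, y, prior, sigma),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    sld0, ks, kg = np.exp(theta)
    model = biexp_sld(t, sld0, ks, kg)
    sse = float(np.sum((model - y) ** 2))
    at_bounds = bool(
        np.any(np.isclose(theta, [b[0] for b in bounds], atol=1e-8))
        or np.any(np.isclose(theta, [b[1] for b in bounds], atol=1e-8))
    )
    return TGIIndividual(
        patient_id=patient_id,
        sld0_mm=float(sld0),
        ks_per_day=float(ks),
        kg_per_day=float(kg),
        ttg_days=ttg(ks, kg),
        fit_sse=sse,
        converged=bool(best.success),
        at_bounds=at_bounds,
    )


def fit_population(
    table: pd.DataFrame,
    baseline: pd.DataFrame,
    *,
    max_iter: int = 50,
    tol: float = 1e-4,
    init_sigma_mm: float = 5.0,
    init_omega2: float = 0.25,
) -> tuple[TGIPopulation, list[TGIIndividual]]:
    """Empirical-Bayes population fit over all evaluable patients.

    Alternates MAP individual fits (given current population parameters)
    with moment updates: group log-means and variances from the individual
    log-parameters, residual SD pooled across all observations. Stops when
    the relative change in population parameters drops below ``tol``.
    Groups with fewer than 2 evaluable patients get NaN variances (the
    pooled variance of the remaining groups is used as their penalty).
    """
    evaluable, _ = evaluability_filter(table)
    groups = baseline.set_index("patient_id")["tumor_type"]
    data = {
        pid: (
            grp["time_days"].to_numpy(dtype=float),
            grp["sld_mm"].to_numpy(dtype=float),
        )
        for pid, grp in table.groupby("patient_id", sort=False)
        if pid in evaluable
    }
    pids = sorted(data)
    if not pids:
        raise ValueError("no evaluable patients")
    labels = {pid: groups.get(pid, "ALL") for pid in pids}
    by_group: dict[str, list] = {}
    for pid in pids:
        by_group.setdefault(labels[pid], []).append(pid)
    for lab, members in by_group.items():
        if len(members) < 2:
            warnings.warn(f"group {lab!r} has < 2 evaluable patients; its IIV "
                          "variance will be reported as missing")

    # Initialize group means from baseline sizes and generic rate guesses.
    mu = {}
    for lab, members in by_group.items():
        base_slds = [max(float(data[p][1][np.argmin(data[p][0])]), 1.0) for p in members]
        mu[lab] = np.array(
            [float(np.mean(np.log(base_slds))), math.log(0.05), math.log(0.005)]
        )
    omega2 = {lab: np.full(3, init_omega2) for lab in by_group}
    sigma = init_sigma_mm
    pop = TGIPopulation(mu=mu, omega2=omega2, sigma_mm=sigma)

    fits: dict[str, TGIIndividual] = {}
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        for pid in pids:
            t, y = data[pid]
            fits[pid] = fit_individual(
                t,
                y,
                patient_id=pid,
                init=fits.get(pid),  # warm start after the first sweep
                prior=pop.prior_for(labels[pid]),
            )
        new_mu, new_om = {}, {}
        for lab, members in by_group.items():
            logs = np.array([fits[p].log_params for p in members])
            new_mu[lab] = logs.mean(axis=0)
            if len(members) >= 2:
                # EM-style update: spread of the MAP estimates understates
                # the IIV, so add the mean posterior variance back in
                pr = pop.prior_for(lab)
                pv = np.mean(
                    [
                        _posterior_var(
                            data[p][0], data[p][1], fits[p].log_params,
                            pr.omega2, pop.sigma_mm,
                        )
                        for p in members
                    ],
                    axis=0,
                )
                new_om[lab] = logs.var(axis=0, ddof=1) + pv
            else:
                new_om[lab] = np.full(3, np.nan)
        sq, n_obs = 0.0, 0
        for pid in pids:
            t, y = data[pid]
            f = fits[pid]
            sq += float(np.sum((biexp_sld(t, f.sld0_mm, f.ks_per_day, f.kg_per_day) - y) ** 2))
            n_obs += t.size
        new_sigma = max(math.sqrt(sq / n_obs), 1e-3)

        old_vec = np.concatenate([pop.mu[lab] for lab in sorted(by_group)] + [[pop.sigma_mm]])
        new_vec = np.concatenate([new_mu[lab] for lab in sorted(by_group)] + [[new_sigma]])
        rel = float(np.max(np.abs(new_vec - old_vec) / np.maximum(np.abs(old_vec), 1e-8)))
        pop = TGIPopulation(mu=new_mu, omega2=new_om, sigma_mm=new_sigma)
        if rel < tol:
            converged = True
            break

    # Penalized log-likelihood at the final estimates.
    ll = 0.0
    for pid in pids:
        t, y = data[pid]
        f = fits[pid]
        resid = biexp_sld(t, f.sld0_mm, f.ks_per_day, f.kg_per_day) - y
        ll += float(
            -0.5 * np.sum(resid**2) / pop.sigma_mm**2
            - t.size * math.log(pop.sigma_mm * math.sqrt(2 * math.pi))
        )
        pr = pop.prior_for(labels[pid])
        om = np.maximum(pr.omega2, 1e-4)
        dev = f.log_params - pr.mu
        ll += float(-0.5 * np.sum(dev**2 / om) - 0.5 * np.sum(np.log(2 * math.pi * om)))
    pop.log_likelihood = ll
    pop.n_iterations = n_iter
    pop.converged = converged
    return pop, [fits[p] for p in pids]


def goodness_of_fit(
    fits: Iterable[TGIIndividual], table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient fit summaries and observed-vs-predicted pairs.

    Returns ``(summary, pairs)``: summary has one row per fitted patient
    (n_obs, r2, resid_sd); pairs holds every (patient, time, observed,
    predicted, residual) record for plotting.
    """
    rows, pair_rows = [], []
    grouped = dict(tuple(table.groupby("patient_id", sort=False))) if len(table) else {}
    for f in fits:
        grp = grouped.get(f.patient_id)
        if grp is None:
            continue
        t = grp["time_days"].to_numpy(dtype=float)
        y = grp["sld_mm"].to_numpy(dtype=float)
        pred = np.asarray(biexp_sld(t, f.sld0_mm, f.ks_per_day, f.kg_per_day))
        resid = y - pred
        tss = float(np.sum((y - y.mean()) ** 2))
        sse = float(resid @ resid)
        r2 = 1.0 - sse / tss if tss > 0 else (1.0 if sse < 1e-12 else 0.0)
        rows.append(
            {
                "patient_id": f.patient_id,
                "n_obs": t.size,
                "r2": r2,
                "resid_sd": float(np.sqrt(sse / t.size)),
            }
        )
        for ti, yi, pi in zip(t, y, pred):
            pair_rows.append(
                {
                    "patient_id": f.patient_id,
                    "time_days": ti,
                    "observed": yi,
                    "predicted": pi,
                    "residual": yi - pi,
                }
            )
    cols_s = ["patient_id", "n_obs", "r2", "resid_sd"]
    cols_p = ["patient_id", "time_days", "observed", "predicted", "residual"]
    return (
        pd.DataFrame(rows, columns=cols_s),
        pd.DataFrame(pair_rows, columns=cols_p),
    )


def individuals_to_frame(fits: Iterable[TGIIndividual]) -> pd.DataFrame:
    """Export individual fits as the per-patient TGI metrics table."""
    rows = [
        {
            "patient_id": f.patient_id,
            "SLD0": f.sld0_mm,
            "KS": f.ks_per_day,
            "KG": f.kg_per_day,
            "TTG": f.ttg_days,
            "logKS": math.log(f.ks_per_day),
            "logKG": math.log(f.kg_per_day),
            "converged": f.converged,
        }
        for f in fits
    ]
    return pd.DataFrame(rows, columns=TGI_METRICS_COLUMNS)
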