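"""Seeded multi-tumor-type trial cohort simulator.

Generates three linked tables — longitudinal tumor size, baseline
covariates, survival outcomes — with the statistical structure the
downstream models assume: biexponential SLD trajectories with log-normal
inter-individual variability and additive normal residual error, and
survival times from an accelerated-failure-time (AFT) family whose linear
predictor depends on the true log tumor-regrowth rate and baseline
covariates.

Time unit is days throughout; shrinkage/regrowth rates are per day.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tgi_dynamics import biexp_sld

__all__ = [
    "GroupSpec",
    "CohortConfig",
    "SurvivalGenConfig",
    "DEFAULT_COVARIATE_PARAMS",
    "simulate_cohort",
    "write_cohort",
]

#: Columns of the longitudinal table.
LONGITUDINAL_COLUMNS = ["patient_id", "time_days", "sld_mm"]
#: Columns of the survival table.
SURVIVAL_COLUMNS = ["patient_id", "time_days", "event"]
#: Columns of the baseline table (``true_log_ks``/``true_log_kg`` carry the
#: generating individual parameters for evaluation against ground truth).
BASELINE_COLUMNS = [
    "patient_id",
    "tumor_type",
    "ecog",
    "hgb",
    "albu",
    "nlr",
    "liver_met",
    "n_tumor_sites",
    "neu",
    "ysd",
    "sld0_true_mm",
    "race_asian",
    "sex",
    "true_log_ks",
    "true_log_kg",
]

#: Baseline covariate generator defaults (plausible oncology-trial values;
#: all marginals independent by design).
DEFAULT_COVARIATE_PARAMS: dict[str, object] = {
    "ecog_probs": (0.35, 0.55, 0.10),
    "hgb_mean": 12.5,
    "hgb_sd": 1.5,
    "albu_mean": 4.0,
    "albu_sd": 0.45,
    "nlr_log_mean": math.log(3.5),
    "nlr_log_sd": 0.5,
    "liver_met_prob": 0.3,
    "n_tumor_sites_poisson_mean": 1.5,
    "neu_log_mean": math.log(4.5),
    "neu_log_sd": 0.35,
    "ysd_mean": 2.0,
    "race_asian_prob": 0.4,
    "sex_prob": 0.5,
}


@dataclass(frozen=True)
class GroupSpec:
    """One tumor-type arm: label, size and log-scale trajectory means."""

    label: str
    n_patients: int
    mu_log_ks: float
    mu_log_kg: float
    mu_log_sld0: float


@dataclass
class CohortConfig:
    """Cohort-level simulation settings.

    ``omega2_*`` are inter-individual variances on the log scale;
    ``sigma_sld_mm`` is the additive residual SD of observed SLD.
    """

    groups: Sequence[GroupSpec]
    omega2_log_ks: float = 0.25
    omega2_log_kg: float = 0.25
    omega2_log_sld0: float = 0.1
    sigma_sld_mm: float = 5.0
    visit_schedule_days: Sequence[float] = (0, 42, 84, 126, 168, 252, 336, 420)
    dropout_prob_per_visit: float = 0.0
    seed: int = 0
    covariate_params: Mapping[str, object] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        for g in self.groups:
            if g.n_patients < 1:
                raise ValueError(f"group {g.label!r}: n_patients must be >= 1")
            for v in (g.mu_log_ks, g.mu_log_kg, g.mu_log_sld0):
                if not np.isfinite(v):
                    raise ValueError(f"group {g.label!r}: non-finite mean")
        for name in ("omega2_log_ks", "omega2_log_kg", "omega2_log_sld0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not np.isfinite(self.sigma_sld_mm) or self.sigma_sld_mm < 0:
            raise ValueError("sigma_sld_mm must be finite and >= 0")
        sched = np.asarray(self.visit_schedule_days, dtype=float)
        if sched.size == 0:
            raise ValueError("visit_schedule_days must not be empty")
        if sched[0] != 0:
            raise ValueError("visit_schedule_days must start at 0")
        if sched.size > 1 and not np.all(np.diff(sched) > 0):
            raise ValueError("visit_schedule_days must be strictly increasing")
        if not 0 <= self.dropout_prob_per_visit <= 1:
            raise ValueError("dropout_prob_per_visit must be in [0, 1]")


@dataclass
class SurvivalGenConfig:
    """AFT survival generator: log T = intercept + beta.x + scale * eps.

    ``family`` selects the error law: ``lognormal`` (standard normal eps,
    median survival exp(intercept + beta.x)) or ``weibull`` (minimum-Gumbel
    eps). ``beta`` maps feature names — ``log_kg`` or any baseline column —
    to coefficients. Random censoring is exponential with rate
    ``random_censor_rate`` per day; administrative censoring truncates at
    ``admin_censor_day``.
    """

    family: str = "lognormal"
    intercept: float = math.log(500.0)
    beta: Mapping[str, float] = field(default_factory=dict)
    scale: float = 0.8
    admin_censor_day: float = 2000.0
    random_censor_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.family not in ("lognormal", "weibull"):
            raise ValueError(f"unknown AFT family {self.family!r}")
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError("scale must be finite and > 0")
        if not np.isfinite(self.admin_censor_day) or self.admin_censor_day <= 0:
            raise ValueError("admin_censor_day must be finite and > 0")
        if not np.isfinite(self.random_censor_rate) or self.random_censor_rate < 0:
            raise ValueError("random_censor_rate must be finite and >= 0")
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        for k, v in self.beta.items():
            if not np.isfinite(v):
                raise ValueError(f"beta[{k!r}] must be finite")


def _draw_baseline(rng: np.random.Generator, n: int, params: Mapping[str, object]) -> dict:
    p = dict(DEFAULT_COVARIATE_PARAMS)
    p.update(params)
    ecog_probs = np.asarray(p["ecog_probs"], dtype=float)
    ecog_probs = ecog_probs / ecog_probs.sum()
    return {
        "ecog": rng.choice(np.arange(len(ecog_probs)), size=n, p=ecog_probs),
        "hgb": np.maximum(rng.normal(p["hgb_mean"], p["hgb_sd"], n), 0.1),
        "albu": np.maximum(rng.normal(p["albu_mean"], p["albu_sd"], n), 0.1),
        "nlr": rng.lognormal(p["nlr_log_mean"], p["nlr_log_sd"], n),
        "liver_met": rng.binomial(1, p["liver_met_prob"], n),
        "n_tumor_sites": 1 + rng.poisson(p["n_tumor_sites_poisson_mean"], n),
        "neu": rng.lognormal(p["neu_log_mean"], p["neu_log_sd"], n),
        "ysd": rng.exponential(p["ysd_mean"], n),
        "race_asian": rng.binomial(1, p["race_asian_prob"], n),
        "sex": rng.binomial(1, p["sex_prob"], n),
    }


def simulate_cohort(
    config: CohortConfig, surv_config: SurvivalGenConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns (longitudinal, baseline, survival) tables.

    Trajectory noise/dropout and survival generation use separate seeds
    (``config.seed`` and ``surv_config.seed``) so either can be held fixed.
    Identical configs produce bit-identical tables.
    """
    config.validate()
    surv_config.validate()
    rng_traj = np.random.default_rng(config.seed)
    rng_surv = np.random.default_rng(surv_config.seed)
    sched = np.asarray(config.visit_schedule_days, dtype=float)

    base_rows: list[pd.DataFrame] = []
    pid_offset = 0
    for g in config.groups:
        n = g.n_patients
        log_sld0 = rng_traj.normal(g.mu_log_sld0, math.sqrt(config.omega2_log_sld0), n)
        log_ks = rng_traj.normal(g.mu_log_ks, math.sqrt(config.omega2_log_ks), n)
        log_kg = rng_traj.normal(g.mu_log_kg, math.sqrt(config.omega2_log_kg), n)
        cov = _draw_baseline(rng_traj, n, config.covariate_params)
        ids = [f"P{pid_offset + i + 1:05d}" for i in range(n)]
        pid_offset += n
        base_rows.append(
            pd.DataFrame(
                {
                    "patient_id": ids,
                    "tumor_type": g.label,
                    **cov,
                    "sld0_true_mm": np.exp(log_sld0),
                    "race_asian": cov["race_asian"],
                    "sex": cov["sex"],
                    "true_log_ks": log_ks,
                    "true_log_kg": log_kg,
                }
            )
        )
    baseline = pd.concat(base_rows, ignore_index=True)[BASELINE_COLUMNS]

    # Longitudinal trajectories with additive noise and monotone dropout.
    long_pid, long_t, long_sld = [], [], []
    for row in baseline.itertuples(index=False):
        sld0 = row.sld0_true_mm
        ks = math.exp(row.true_log_ks)
        kg = math.exp(row.true_log_kg)
        true_vals = biexp_sld(sched, sld0, ks, kg)
        noise = (
            rng_traj.normal(0.0, config.sigma_sld_mm, sched.size)
            if config.sigma_sld_mm > 0
            else np.zeros(sched.size)
        )
        # Dropout applies to post-baseline visits; once a visit is missed,
        # all later visits are missed too (trial discontinuation).
        n_keep = sched.size
        if config.dropout_prob_per_visit > 0:
            drops = rng_traj.random(sched.size) < config.dropout_prob_per_visit
            drops[0] = False  # the day-0 record always exists
            missed = np.flatnonzero(drops)
            if missed.size:
                n_keep = int(missed[0])
        obs = np.maximum(true_vals + noise, 0.0)[:n_keep]
        long_pid.extend([row.patient_id] * n_keep)
        long_t.extend(sched[:n_keep])
        long_sld.extend(obs)
    longitudinal = pd.DataFrame(
        {"patient_id": long_pid, "time_days": long_t, "sld_mm": long_sld}
    )

    # Survival: AFT event times from the true linear predictor.
    eta = np.full(len(baseline), surv_config.intercept, dtype=float)
    for name, coef in surv_config.beta.items():
        if name == "log_kg":
            x = baseline["true_log_kg"].to_numpy(dtype=float)
        elif name == "log_ks":
            x = baseline["true_log_ks"].to_numpy(dtype=float)
        elif name in baseline.columns:
            x = baseline[name].to_numpy(dtype=float)
        else:
            raise ValueError(f"beta refers to unknown feature {name!r}")
        eta = eta + coef * x
    n_total = len(baseline)
    if surv_config.family == "lognormal":
        eps = rng_surv.standard_normal(n_total)
    else:  # weibull: minimum-Gumbel error
        eps = np.log(rng_surv.exponential(1.0, n_total))
    t_event = np.exp(eta + surv_config.scale * eps)
    if surv_config.random_censor_rate > 0:
        t_cens = rng_surv.exponential(1.0 / surv_config.random_censor_rate, n_total)
    else:
        t_cens = np.full(n_total, np.inf)
    t_cens = np.minimum(t_cens, surv_config.admin_censor_day)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame(
        {"patient_id": baseline["patient_id"], "time_days": time, "event": event}
    )
    return longitudinal, baseline, survival


def write_cohort(
    out_dir: str | Path,
    longitudinal: pd.DataFrame,
    baseline: pd.DataFrame,
    survival: pd.DataFrame,
    *,
    seed: int | None = None,
) -> dict:
    """Write the three cohort CSVs plus a manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "longitudinal": "longitudinal.csv",
        "baseline": "baseline.csv",
        "survival": "survival.csv",
    }
    longitudinal.to_csv(out / files["longitudinal"], index=False)
    baseline.to_csv(out / files["baseline"], index=False)
    survival.to_csv(out / files["survival"], index=False)
    manifest = {
        "files": files,
        "seed": seed,
        "n_patients": int(len(baseline)),
        "n_measurements": int(len(longitudinal)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
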