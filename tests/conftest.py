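import math

import numpy as np
import pandas as pd
import pytest

from tgios.synthetic_trial import CohortConfig, GroupSpec, SurvivalGenConfig, simulate_cohort
from tgios.tgi_dynamics import ttg


def two_group_cohort_config(
    n_per_group=150,
    seed=11,
    sigma=4.0,
    dropout=0.0,
    visit_schedule=(0, 21, 42, 63, 105, 168, 252, 365),
):
    return CohortConfig(
        groups=[
            GroupSpec("TYPEA", n_per_group, math.log(0.02), math.log(0.004), math.log(55)),
            GroupSpec("TYPEB", n_per_group, math.log(0.025), math.log(0.002), math.log(45)),
        ],
        visit_schedule_days=visit_schedule,
        sigma_sld_mm=sigma,
        dropout_prob_per_visit=dropout,
        seed=seed,
    )


def kg_driven_survival_config(beta_logkg=-0.9, scale=0.6, seed=12, censor_rate=0.0):
    """Lognormal AFT whose hazard is driven by log(KG); the intercept centers
    the median survival near 300 days for the cohort above."""
    return SurvivalGenConfig(
        family="lognormal",
        intercept=math.log(300.0) - beta_logkg * math.log(0.003),
        beta={"log_kg": beta_logkg},
        scale=scale,
        admin_censor_day=2000.0,
        random_censor_rate=censor_rate,
        seed=seed,
    )


def true_metrics_frame(baseline: pd.DataFrame) -> pd.DataFrame:
    """TGI metrics table built from the generating truth (bypasses fitting)."""
    ks = np.exp(baseline["true_log_ks"].to_numpy())
    kg = np.exp(baseline["true_log_kg"].to_numpy())
    return pd.DataFrame(
        {
            "patient_id": baseline["patient_id"],
            "SLD0": baseline["sld0_true_mm"],
            "KS": ks,
            "KG": kg,
            "TTG": [ttg(a, b) for a, b in zip(ks, kg)],
            "logKS": np.log(ks),
            "logKG": np.log(kg),
            "converged": True,
        }
    )


@pytest.fixture(scope="session")
def kg_cohort():
    """Two-type cohort whose survival depends strongly on log(KG)."""
    cfg = two_group_cohort_config()
    scfg = kg_driven_survival_config()
    return simulate_cohort(cfg, scfg)


@pytest.fixture(scope="session")
def kg_cohort_features(kg_cohort):
    from tgios.ml_os import build_feature_matrix

    _, baseline, survival = kg_cohort
    return build_feature_matrix(true_metrics_frame(baseline), baseline), survival


@pytest.fixture
def toy_long_table():
    """Evaluability fixture: A (0,42,84), B (0), C (0,56), D (42)."""
    rows = [
        ("A", 0, 50.0), ("A", 42, 45.0), ("A", 84, 47.0),
        ("B", 0, 60.0),
        ("C", 0, 30.0), ("C", 56, 25.0),
        ("D", 42, 40.0),
    ]
    return pd.DataFrame(rows, columns=["patient_id", "time_days", "sld_mm"])
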