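"""Tumor-type-agnostic machine-learning survival path.

Assembles the fixed 11-column feature matrix (3 TGI metrics + 8 baseline
covariates; tumor type deliberately excluded), trains a gradient-boosted
AFT tree ensemble, and converts it to per-patient survival curves by
Kaplan–Meier over each patient's nearest neighbors in terminal-leaf
co-occurrence space. Bootstrap refits yield pointwise 95% prediction
intervals for pooled subgroup survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._boosting import AFTGradientBooster
from .parametric_os import km_estimate

__all__ = [
    "FEATURE_COLUMNS",
    "TimeGrid",
    "MLHyperparams",
    "MLSurvivalModel",
    "PredictionBand",
    "build_feature_matrix",
    "train_ml_survival",
    "predict_curves",
    "bootstrap_prediction_band",
]

logger = logging.getLogger(__name__)

#: The fixed, ordered feature set: three TGI metrics plus eight baseline
#: covariates. Tumor type (and sex/race) are never feature columns here.
FEATURE_COLUMNS = (
    "KS",
    "KG",
    "TTG",
    "ECOG",
    "HGB",
    "ALBU",
    "NLR",
    "liver_met",
    "n_tumor_sites",
    "NEU",
    "YSD",
)

_BASELINE_TO_FEATURE = {
    "ecog": "ECOG",
    "hgb": "HGB",
    "albu": "ALBU",
    "nlr": "NLR",
    "liver_met": "liver_met",
    "n_tumor_sites": "n_tumor_sites",
    "neu": "NEU",
    "ysd": "YSD",
}


@dataclass(frozen=True)
class TimeGrid:
    """Evaluation grid in days. The default is 0..2000 in steps of 5."""

    days: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.days, dtype=float)
        if d.size == 0 or d[0] != 0:
            raise ValueError("grid must start at 0")
        if d.size > 1 and not np.all(np.diff(d) > 0):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "days", d)

    def __len__(self) -> int:
        return int(self.days.size)

    @classmethod
    def default(cls) -> "TimeGrid":
        return cls(days=np.arange(0.0, 2000.0 + 1e-9, 5.0))

    @classmethod
    def from_spec(cls, start: float = 0, stop: float = 2000, step: float = 5) -> "TimeGrid":
        return cls(days=np.arange(start, stop + step / 2, step))


@dataclass
class MLHyperparams:
    """Boosting + neighbor-KM knobs with documented defaults."""

    n_rounds: int = 200
    learning_rate: float = 0.1
    max_depth: int = 3
    # leaf-size floor keeps the leaf co-occurrence neighborhoods from
    # memorizing realized event times, which biases pooled curves downward
    min_samples_leaf: int = 30
    aft_sigma: float = 1.0
    k_neighbors: int = 30

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class MLSurvivalModel:
    """Fitted ensemble plus everything needed to build neighbor KM curves."""

    booster: AFTGradientBooster
    feature_columns: tuple
    grid: TimeGrid
    hyperparams: MLHyperparams
    X_train: np.ndarray
    leaves_train: np.ndarray
    time_train: np.ndarray
    event_train: np.ndarray
    train_index: pd.Index
    seed: int = 0
    clip_violations_: int = field(default=0)

    def risk_scores(self, features: pd.DataFrame) -> pd.Series:
        X = _as_matrix(features, self.feature_columns)
        return pd.Series(self.booster.risk_score(X), index=features.index)


def build_feature_matrix(
    tgi_metrics: pd.DataFrame | None, baseline: pd.DataFrame
) -> pd.DataFrame:
    """Left-join TGI metrics onto the baseline table.

    Every baseline patient gets a row; patients absent from the metrics
    table (TGI non-evaluable) carry NaN in the KS/KG/TTG columns, which the
    tree learner routes natively — no imputation. Output columns are
    exactly ``FEATURE_COLUMNS`` (tumor type, sex and race are dropped),
    indexed by patient id.
    """
    if baseline["patient_id"].duplicated().any():
        dup = baseline.loc[baseline["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient id in baseline table: {dup!r}")
    out = baseline.set_index("patient_id")[list(_BASELINE_TO_FEATURE)].rename(
        columns=_BASELINE_TO_FEATURE
    )
    if tgi_metrics is not None and len(tgi_metrics):
        if tgi_metrics["patient_id"].duplicated().any():
            dup = tgi_metrics.loc[
                tgi_metrics["patient_id"].duplicated(), "patient_id"
            ].iloc[0]
            raise ValueError(f"duplicate patient id in TGI metrics table: {dup!r}")
        tgi = tgi_metrics.set_index("patient_id")[["KS", "KG", "TTG"]]
        out = out.join(tgi, how="left")
    else:
        out[["KS", "KG", "TTG"]] = np.nan
    return out[list(FEATURE_COLUMNS)].astype(float)


def _as_matrix(features: pd.DataFrame, columns) -> np.ndarray:
    got = list(features.columns)
    want = list(columns)
    if got != want:
        missing = [c for c in want if c not in got]
        extra = [c for c in got if c not in want]
        raise ValueError(
            f"feature columns do not match training columns; "
            f"missing={missing}, unexpected={extra}"
        )
    return features.to_numpy(dtype=float)


def train_ml_survival(
    features: pd.DataFrame,
    survival: pd.DataFrame,
    hyperparams: MLHyperparams | None = None,
    grid: TimeGrid | None = None,
    seed: int = 0,
) -> MLSurvivalModel:
    """Train the boosted ensemble on aligned feature/survival tables.

    ``features`` is the output of :func:`build_feature_matrix` (indexed by
    patient id); ``survival`` holds patient_id/time_days/event. Requires at
    least 20 patients and at least one event. Deterministic given ``seed``.
    """
    hp = hyperparams or MLHyperparams()
    grid = grid or TimeGrid.default()
    surv = survival.set_index("patient_id").loc[features.index]
    time = surv["time_days"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    if len(features) < 20:
        raise ValueError("need at least 20 patients to train")
    if event.sum() == 0:
        raise ValueError("no events in training data")
    X = _as_matrix(features, FEATURE_COLUMNS)
    booster = AFTGradientBooster(
        n_rounds=hp.n_rounds,
        learning_rate=hp.learning_rate,
        max_depth=hp.max_depth,
        min_samples_leaf=hp.min_samples_leaf,
        aft_sigma=hp.aft_sigma,
        random_state=seed,
    ).fit(X, time, event)
    return MLSurvivalModel(
        booster=booster,
        feature_columns=FEATURE_COLUMNS,
        grid=grid,
        hyperparams=hp,
        X_train=X,
        leaves_train=booster.apply(X),
        time_train=time,
        event_train=event,
        train_index=features.index,
        seed=seed,
    )


def _leaf_similarity(leaves_query: np.ndarray, leaves_train: np.ndarray) -> np.ndarray:
    """Count of trees in which query and training samples share a leaf.

    Returns an (n_query, n_train) integer matrix.
    """
    nq, nt = leaves_query.shape[0], leaves_train.shape[0]
    sim = np.zeros((nq, nt), dtype=np.int32)
    for m in range(leaves_query.shape[1]):
        sim += leaves_query[:, m][:, None] == leaves_train[:, m][None, :]
    return sim


def predict_curves(model: MLSurvivalModel, features: pd.DataFrame) -> pd.DataFrame:
    """Per-patient survival curves on the model grid.

    For each patient, the k training patients with the highest terminal-leaf
    co-occurrence form the neighbor set; the curve is their Kaplan–Meier
    estimate evaluated on the grid. Rows are monotone non-increasing in
    [0, 1] by construction; a final clip guards the contract anyway.
    """
    X = _as_matrix(features, model.feature_columns)
    leaves_q = model.booster.apply(X)
    sim = _leaf_similarity(leaves_q, model.leaves_train)
    k = min(model.hyperparams.k_neighbors, model.leaves_train.shape[0])
    days = model.grid.days
    curves = np.empty((X.shape[0], days.size))
    # neighborhood = everyone at least as similar as the k-th neighbor;
    # including all ties keeps the rule deterministic without biasing the
    # neighbor set toward any training-order-correlated subgroup
    kth = -np.partition(-sim, k - 1, axis=1)[:, k - 1]
    for i in range(X.shape[0]):
        nb = np.flatnonzero(sim[i] >= kth[i])
        kmc = km_estimate(model.time_train[nb], model.event_train[nb])
        curves[i] = kmc.evaluate(days)
    raw = curves.copy()
    curves = np.clip(np.minimum.accumulate(curves, axis=1), 0.0, 1.0)
    n_viol = int(np.sum(~np.isclose(raw, curves)))
    if n_viol:
        logger.info("monotonicity clipping adjusted %d curve values", n_viol)
        model.clip_violations_ += n_viol
    return pd.DataFrame(curves, index=features.index, columns=days)


@dataclass
class PredictionBand:
    """Pointwise bootstrap band for a pooled subgroup survival curve."""

    grid: TimeGrid
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray
    n_bootstrap: int
    subgroup_size: int = 0

    def __post_init__(self):
        for name in ("lower", "median", "upper"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != self.grid.days.shape:
                raise ValueError(f"{name} does not match the grid")
            setattr(self, name, v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.grid.days,
                "lower": self.lower,
                "median": self.median,
                "upper": self.upper,
            }
        )


def bootstrap_prediction_band(
    features: pd.DataFrame,
    survival: pd.DataFrame,
    subgroup_mask: np.ndarray | pd.Series,
    n_bootstrap: int = 1000,
    grid: TimeGrid | None = None,
    hyperparams: MLHyperparams | None = None,
    seed: int = 0,
    resample_indices: list | None = None,
) -> PredictionBand:
    """95% prediction interval for a subgroup's pooled survival curve.

    Each bootstrap replicate resamples the training patients with
    replacement, refits the full model, predicts every subgroup patient's
    curve and pools them by the mean; the band is the pointwise 2.5th /
    97.5th percentile (median = 50th) across replicates.
    ``resample_indices`` overrides the resampling (one index array per
    replicate) for deterministic testing.
    """
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    mask = np.asarray(subgroup_mask, dtype=bool)
    if mask.shape[0] != len(features):
        raise ValueError("subgroup mask length does not match features")
    if not mask.any():
        raise ValueError("subgroup is empty")
    grid = grid or TimeGrid.default()
    hp = hyperparams or MLHyperparams()
    sub_features = features.loc[mask]
    rng = np.random.default_rng(seed)
    n = len(features)
    if resample_indices is not None and len(resample_indices) != n_bootstrap:
        raise ValueError("resample_indices must supply one array per replicate")
    pooled = np.empty((n_bootstrap, grid.days.size))
    for b in range(n_bootstrap):
        idx = (
            np.asarray(resample_indices[b])
            if resample_indices is not None
            else rng.integers(0, n, n)
        )
        boot_feats = features.iloc[idx]
        boot_feats = boot_feats.set_axis(pd.RangeIndex(len(idx)))
        boot_surv = survival.set_index("patient_id").loc[features.index].iloc[idx]
        boot_surv = pd.DataFrame(
            {
                "patient_id": pd.RangeIndex(len(idx)),
                "time_days": boot_surv["time_days"].to_numpy(),
                "event": boot_surv["event"].to_numpy(),
            }
        )
        model_b = train_ml_survival(boot_feats, boot_surv, hp, grid, seed=seed)
        curves = predict_curves(model_b, sub_features)
        pooled[b] = curves.to_numpy().mean(axis=0)
    lower, median, upper = np.percentile(pooled, [2.5, 50.0, 97.5], axis=0)
    return PredictionBand(
        grid=grid,
        lower=lower,
        median=median,
        upper=upper,
        n_bootstrap=n_bootstrap,
        subgroup_size=int(mask.sum()),
    )
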