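"""Shapley-value explanations for the boosted survival ensemble.

Exact, path-dependent tree Shapley values computed on the boosting margin
(the risk scale), not on the neighbor-KM curves. For each tree the
conditional expectation v(S) — traverse when the split feature is in S,
cover-weighted average of both children otherwise — is evaluated for every
subset of the features the tree actually uses (a depth-d tree uses at most
2^d - 1 distinct features, so enumeration is exact and cheap for shallow
trees), then combined with Shapley weights. Features absent from a tree
are dummy players and receive exactly zero from it; local accuracy
(base value + row sum = margin) holds to floating-point precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ml_os import MLSurvivalModel, _as_matrix

__all__ = ["AttributionMatrix", "compute_attributions", "rank_features", "summary_plot"]

_MAX_TREE_FEATURES = 16  # 2^16 subsets; guard against deep trees


@dataclass
class AttributionMatrix:
    """Signed per-patient, per-feature contributions on the margin scale."""

    values: pd.DataFrame  # rows = patients, columns = features
    base_value: float
    margins: pd.Series  # the model margin each row decomposes

    def local_accuracy_error(self) -> pd.Series:
        """|base + row sum - margin| per patient."""
        return (self.base_value + self.values.sum(axis=1) - self.margins).abs()


def _subset_values(tree, X: np.ndarray, used: np.ndarray) -> np.ndarray:
    """v(S) for every subset of ``used`` features: shape (2^u, n_samples).

    Subset bitmask bit j corresponds to ``used[j]``. Missing feature values
    (NaN) follow the tree's trained default direction.
    """
    t = tree.tree_
    feature = t.feature
    threshold = t.threshold
    left, right = t.children_left, t.children_right
    value = t.value[:, 0, 0]
    weight = t.weighted_n_node_samples
    missing_left = t.missing_go_to_left.astype(bool)
    pos = {f: j for j, f in enumerate(used)}
    n = X.shape[0]
    n_subsets = 1 << used.size
    out = np.empty((n_subsets, n))

    def walk(node: int, mask: int) -> np.ndarray:
        if left[node] == -1:
            return np.full(n, value[node])
        f = feature[node]
        if mask >> pos[f] & 1:
            x = X[:, f]
            go_left = np.where(np.isnan(x), missing_left[node], x <= threshold[node])
            return np.where(go_left, walk(left[node], mask), walk(right[node], mask))
        wl = weight[left[node]] / weight[node]
        return wl * walk(left[node], mask) + (1 - wl) * walk(right[node], mask)

    for mask in range(n_subsets):
        out[mask] = walk(0, mask)
    return out


def _tree_shapley(tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact Shapley values for one tree: (phi of shape (n, n_features), v_empty)."""
    t = tree.tree_
    used = np.unique(t.feature[t.feature >= 0])
    n, p = X.shape
    if used.size == 0:  # single-leaf tree: pure base value
        return np.zeros((n, p)), float(t.value[0, 0, 0])
    if used.size > _MAX_TREE_FEATURES:
        raise ValueError(
            f"tree uses {used.size} features; exact subset enumeration is "
            f"capped at {_MAX_TREE_FEATURES} — use shallower trees"
        )
    u = used.size
    v = _subset_values(tree, X, used)
    fact = [math.factorial(i) for i in range(u + 1)]
    phi = np.zeros((n, p))
    for j, f in enumerate(used):
        bit = 1 << j
        for mask in range(1 << u):
            if mask & bit:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[u - s - 1] / fact[u]
            phi[:, f] += w * (v[mask | bit] - v[mask])
    return phi, float(v[0, 0]) if np.ptp(v[0]) == 0 else float(v[0].mean())


def compute_attributions(
    model: MLSurvivalModel, features: pd.DataFrame
) -> AttributionMatrix:
    """Shapley attributions of the ensemble risk margin for every patient.

    Sign convention: the decomposed quantity is the risk score (negated
    predicted log time), so a positive attribution means the feature pushed
    the prediction toward higher hazard.
    """
    X = _as_matrix(features, model.feature_columns)
    booster = model.booster
    n, p = X.shape
    phi = np.zeros((n, p))
    base = booster.base_margin_
    for tree in booster.trees_:
        tp, v0 = _tree_shapley(tree, X)
        phi += booster.learning_rate * tp
        base += booster.learning_rate * v0
    phi, base = -phi, -base
    margins = booster.risk_score(X)
    return AttributionMatrix(
        values=pd.DataFrame(phi, index=features.index, columns=model.feature_columns),
        base_value=float(base),
        margins=pd.Series(margins, index=features.index),
    )


def rank_features(
    attr: AttributionMatrix, subgroup_mask: np.ndarray | pd.Series | None = None
) -> pd.DataFrame:
    """Features ordered by decreasing mean |attribution| within a subgroup.

    Ties are broken alphabetically. Returns columns (feature, mean_abs_attribution).
    """
    vals = attr.values
    if subgroup_mask is not None:
        mask = np.asarray(subgroup_mask, dtype=bool)
        if not mask.any():
            raise ValueError("subgroup is empty")
        vals = vals.loc[mask]
    scores = vals.abs().mean(axis=0)
    ordered = sorted(scores.index, key=lambda f: (-scores[f], f))
    return pd.DataFrame(
        {"feature": ordered, "mean_abs_attribution": [scores[f] for f in ordered]}
    )


def summary_plot(
    attr: AttributionMatrix,
    features: pd.DataFrame,
    path,
    subgroup_mask: np.ndarray | pd.Series | None = None,
    title: str | None = None,
    seed: int = 0,
):
    """Beeswarm-style summary: one jittered row per feature, most influential
    on top, points colored by the feature's value (red high, blue low)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = attr.values
    feats = features
    if subgroup_mask is not None:
        mask = np.asarray(subgroup_mask, dtype=bool)
        if not mask.any():
            raise ValueError("subgroup is empty")
        vals, feats = vals.loc[mask], feats.loc[mask]
    ranking = rank_features(attr, subgroup_mask)["feature"].tolist()
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(ranking) + 1.5))
    for row, feature in enumerate(reversed(ranking)):
        x = vals[feature].to_numpy()
        fv = feats[feature].to_numpy(dtype=float)
        finite = np.isfinite(fv)
        color = np.full(x.size, 0.5)
        if finite.sum() > 1 and np.ptp(fv[finite]) > 0:
            ranks = pd.Series(fv).rank(pct=True).to_numpy()
            color[finite] = ranks[finite]
        y = row + rng.uniform(-0.25, 0.25, x.size)
        ax.scatter(x, y, c=color, cmap="coolwarm", s=12, vmin=0, vmax=1, alpha=0.8)
    ax.axvline(0.0, color="gray", lw=0.8)
    ax.set_yticks(range(len(ranking)))
    ax.set_yticklabels(list(reversed(ranking)))
    ax.set_xlabel("attribution to risk margin")
    if title:
        ax.set_title(title)
    sm = plt.cm.ScalarMappable(cmap="coolwarm")
    cb = fig.colorbar(sm, ax=ax, ticks=[0, 1])
    cb.ax.set_yticklabels(["low", "high"])
    cb.set_label("feature value")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
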