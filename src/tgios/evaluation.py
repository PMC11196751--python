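"""Result-generating comparisons: stratified Kaplan–Meier curves,
pairwise tumor-type tests on TGI metrics, band-vs-observed coverage, and
Harrell's concordance index."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ml_os import PredictionBand
from .parametric_os import KaplanMeierCurve, km_estimate

__all__ = [
    "StratifiedKM",
    "stratify_quartiles",
    "stratify_by_label",
    "pairwise_metric_tests",
    "band_overlay_report",
    "concordance_index",
]


@dataclass
class StratifiedKM:
    """Per-group Kaplan–Meier curves plus the stratification bookkeeping."""

    curves: dict  # label -> KaplanMeierCurve
    variable: str
    cut_points: np.ndarray
    assignments: pd.Series  # patient_id -> group label

    def median_survival(self) -> dict:
        """Per-group median survival time (inf when S never reaches 0.5)."""
        out = {}
        for label, c in self.curves.items():
            below = np.flatnonzero(c.survival <= 0.5)
            out[label] = float(c.event_times[below[0]]) if below.size else float("inf")
        return out


def stratify_quartiles(values: pd.Series, survival: pd.DataFrame) -> StratifiedKM:
    """Split patients at the 25/50/75 percentiles of ``values`` (ties go to
    the lower group) and estimate a KM curve per quartile, Q1 = lowest."""
    v = values.dropna()
    if len(v) < 4:
        raise ValueError("need at least 4 patients for quartiles")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    cuts = np.quantile(v.to_numpy(dtype=float), [0.25, 0.5, 0.75])
    group_idx = (v.to_numpy()[:, None] > cuts[None, :]).sum(axis=1)
    labels = pd.Series(
        [f"Q{i + 1}" for i in group_idx], index=v.index, name="quartile"
    )
    surv = survival.set_index("patient_id")
    curves = {}
    for q in ("Q1", "Q2", "Q3", "Q4"):
        members = labels.index[labels == q]
        sub = surv.loc[surv.index.intersection(members)]
        if len(sub):
            curves[q] = km_estimate(sub["time_days"], sub["event"])
    return StratifiedKM(
        curves=curves, variable=values.name or "value", cut_points=cuts,
        assignments=labels,
    )


def stratify_by_label(labels: pd.Series, survival: pd.DataFrame) -> StratifiedKM:
    """KM curve per categorical label (e.g. tumor type)."""
    surv = survival.set_index("patient_id")
    curves = {}
    for lab in sorted(labels.dropna().unique()):
        members = labels.index[labels == lab]
        sub = surv.loc[surv.index.intersection(members)]
        if len(sub):
            curves[lab] = km_estimate(sub["time_days"], sub["event"])
    return StratifiedKM(
        curves=curves, variable=labels.name or "label",
        cut_points=np.array([]), assignments=labels,
    )


def pairwise_metric_tests(
    metrics: pd.DataFrame, group_col: str = "tumor_type", metric_cols=None
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests for every group pair per metric.

    Holm adjustment is applied across the pairs within each metric. Groups
    with fewer than 2 values for a metric are skipped with a warning.
    Returns columns (metric, group_a, group_b, statistic, p_raw, p_adj).
    """
    if metric_cols is None:
        metric_cols = [c for c in metrics.columns if c != group_col]
    groups = sorted(metrics[group_col].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for metric in metric_cols:
        pair_rows = []
        for a, b in combinations(groups, 2):
            xa = metrics.loc[metrics[group_col] == a, metric].dropna().to_numpy()
            xb = metrics.loc[metrics[group_col] == b, metric].dropna().to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(
                    f"metric {metric!r}: group pair ({a}, {b}) skipped "
                    "(fewer than 2 values)"
                )
                continue
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
            pair_rows.append(
                {
                    "metric": metric,
                    "group_a": a,
                    "group_b": b,
                    "statistic": float(res.statistic),
                    "p_raw": min(float(res.pvalue), 1.0),
                }
            )
        if pair_rows:
            praw = [r["p_raw"] for r in pair_rows]
            _, padj, _, _ = multipletests(praw, method="holm")
            for r, p in zip(pair_rows, padj):
                r["p_adj"] = float(p)
            rows.extend(pair_rows)
    return pd.DataFrame(
        rows, columns=["metric", "group_a", "group_b", "statistic", "p_raw", "p_adj"]
    )


def band_overlay_report(
    bands: dict,
    observed: dict,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Coverage of observed KM curves by prediction bands, per subgroup.

    ``bands`` maps subgroup label -> :class:`PredictionBand`; ``observed``
    maps the same labels -> (times, events) arrays or a KaplanMeierCurve.
    Coverage counts grid points up to the subgroup's last observed event
    where the KM value lies inside [lower, upper]. When ``out_dir`` is
    given, one overlay figure per subgroup is written (band shaded, dashed
    median, solid observed KM).
    """
    if set(bands) != set(observed):
        raise ValueError(
            f"subgroup mismatch: bands={sorted(bands)}, observed={sorted(observed)}"
        )
    rows = []
    for label in sorted(bands):
        band: PredictionBand = bands[label]
        obs = observed[label]
        kmc = obs if isinstance(obs, KaplanMeierCurve) else km_estimate(*obs)
        days = band.grid.days
        usable = days <= kmc.last_event_time
        if not usable.any():
            rows.append({"subgroup": label, "n_grid_points": 0, "coverage": np.nan})
            continue
        km_vals = kmc.evaluate(days[usable])
        inside = (km_vals >= band.lower[usable] - 1e-12) & (
            km_vals <= band.upper[usable] + 1e-12
        )
        rows.append(
            {
                "subgroup": label,
                "n_grid_points": int(usable.sum()),
                "coverage": float(inside.mean()),
            }
        )
        if out_dir is not None:
            _plot_overlay(label, band, kmc, Path(out_dir))
    return pd.DataFrame(rows, columns=["subgroup", "n_grid_points", "coverage"])


def _plot_overlay(label: str, band: PredictionBand, kmc: KaplanMeierCurve, out_dir: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    days = band.grid.days
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(days, band.lower, band.upper, alpha=0.3, label="95% PI")
    ax.plot(days, band.median, "--", label="median predicted")
    ax.step(days, kmc.evaluate(days), where="post", color="black", label="observed KM")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(label)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / f"band_overlay_{label}.png", dpi=100)
    plt.close(fig)


def concordance_index(scores, times, events) -> float:
    """Harrell's C over comparable pairs, higher score = higher risk.

    A pair (i, j) is comparable when i has an observed event and
    t_i < t_j; it is concordant when score_i > score_j, and score ties
    count one half. Constant scores therefore give 0.5. Raises when no
    pair is comparable.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    num = den = 0.0
    for i in np.flatnonzero(e == 1):
        comparable = t > t[i]
        den += comparable.sum()
        num += np.sum(s[i] > s[comparable]) + 0.5 * np.sum(s[i] == s[comparable])
    if den == 0:
        raise ValueError("no comparable pairs")
    return float(num / den)
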