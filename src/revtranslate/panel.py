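"""Control-anchored biomarker panel classifier and differential correlation.

A sample is "detected" for a marker when its relative expression falls
strictly below a fraction (default 50%) of the arithmetic mean of the
control samples; a marker combination is detected when every member
marker is (AND rule).  Sensitivity is the detected fraction of cases,
specificity the non-detected fraction of controls, both in percent.

Case/control Spearman correlation matrices are compared pairwise to
classify each marker pair as maintained (both), lost (control only),
gained (case only) or absent (neither).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "marker_threshold",
    "classify_samples",
    "PanelResult",
    "spearman_correlation",
    "differential_correlation_matrix",
]


def marker_threshold(control_values, fraction: float = 0.5) -> float:
    """Detection threshold: fraction x arithmetic mean of control values."""
    values = pd.Series(control_values, dtype=float).dropna()
    if values.empty:
        raise ValueError("no non-missing control values")
    return float(fraction * values.mean())


@dataclass
class PanelResult:
    """Per-sample calls, confusion counts and accuracy per marker/combination."""

    thresholds: dict[str, float]
    calls: pd.DataFrame  # samples x (markers + "combination"), boolean (NA allowed)
    summary: pd.DataFrame  # per marker/combination: TP FP TN FN sensitivity specificity
    fraction: float


def _confusion(calls: pd.Series, labels: pd.Series) -> dict[str, float]:
    mask = calls.notna()
    c, l = calls[mask].astype(bool), labels[mask]
    tp = int((c & (l == "case")).sum())
    fn = int((~c & (l == "case")).sum())
    fp = int((c & (l == "control")).sum())
    tn = int((~c & (l == "control")).sum())
    return {
        "TP": tp,
        "FP": fp,
        "TN": tn,
        "FN": fn,
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
    }


def classify_samples(
    expr: pd.DataFrame,
    labels: pd.Series,
    markers,
    fraction: float = 0.5,
) -> PanelResult:
    """Threshold each marker against its control mean; combine by AND.

    Samples missing any member marker are excluded from the combination
    denominator (logged).  Controls enter both the threshold estimate and
    the specificity denominator, mirroring a control-anchored rule.
    """
    markers = list(markers)
    missing_cols = set(markers) - set(expr.columns)
    if missing_cols:
        raise ValueError(f"markers absent from table: {sorted(missing_cols)}")
    labels = labels.loc[expr.index]
    for g in ("control", "case"):
        if (labels == g).sum() == 0:
            raise ValueError(f"empty group {g!r}")

    thresholds = {}
    calls = pd.DataFrame(index=expr.index)
    for marker in markers:
        thr = marker_threshold(expr.loc[labels == "control", marker], fraction)
        thresholds[marker] = thr
        col = expr[marker]
        calls[marker] = pd.array(
            [pd.NA if pd.isna(v) else bool(v < thr) for v in col], dtype="boolean"
        )

    member = calls[markers]
    combo = member.all(axis=1)
    combo[member.isna().any(axis=1)] = pd.NA
    n_excluded = int(member.isna().any(axis=1).sum())
    if n_excluded:
        logger.info("%d samples missing a member marker; excluded from combination", n_excluded)
    calls["combination"] = combo

    summary = pd.DataFrame(
        {name: _confusion(calls[name], labels) for name in markers + ["combination"]}
    ).T
    return PanelResult(
        thresholds=thresholds, calls=calls, summary=summary, fraction=fraction
    )


def spearman_correlation(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho with Student-t approximate p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need >= 3 paired non-missing values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def differential_correlation_matrix(
    expr: pd.DataFrame, labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Classify marker pairs by within-group Spearman significance.

    A correlation "appears" in a group when its p-value is below
    ``alpha``; categories: both / control_only (lost in cases) /
    case_only (gained) / neither.  Pairs with fewer than 3 complete
    observations in a group fall back to "neither" with missing stats.
    """
    labels = labels.loc[expr.index]
    markers = list(expr.columns)
    rows = []
    for i, a in enumerate(markers):
        for b in markers[i + 1 :]:
            stats_per_group: dict[str, tuple[float, float]] = {}
            for g in ("control", "case"):
                sub = expr.loc[labels == g, [a, b]].dropna()
                if len(sub) < 3:
                    logger.info("pair (%s,%s) group %s: <3 complete pairs", a, b, g)
                    stats_per_group[g] = (np.nan, np.nan)
                    continue
                try:
                    stats_per_group[g] = spearman_correlation(sub[a], sub[b])
                except ValueError:
                    stats_per_group[g] = (np.nan, np.nan)
            (rho_c, p_c), (rho_s, p_s) = (
                stats_per_group["control"],
                stats_per_group["case"],
            )
            in_control = bool(p_c < alpha) if np.isfinite(p_c) else False
            in_case = bool(p_s < alpha) if np.isfinite(p_s) else False
            category = {
                (True, True): "both",
                (True, False): "control_only",
                (False, True): "case_only",
                (False, False): "neither",
            }[(in_control, in_case)]
            rows.append(
                {
                    "marker_a": a,
                    "marker_b": b,
                    "rho_control": rho_c,
                    "p_control": p_c,
                    "sign_control": np.sign(rho_c) if np.isfinite(rho_c) else np.nan,
                    "rho_case": rho_s,
                    "p_case": p_s,
                    "sign_case": np.sign(rho_s) if np.isfinite(rho_s) else np.nan,
                    "category": category,
                }
            )
    return pd.DataFrame(rows)
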