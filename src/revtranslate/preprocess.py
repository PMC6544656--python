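"""Gene-level preprocessing: background filter, quantile normalization,
median baseline transformation.

The pipeline starts from a gene-level log2 intensity matrix (genes x
samples).  Probe-level summarization is out of scope.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "validate_expression_matrix",
    "validate_traits",
    "background_filter",
    "quantile_normalize",
    "baseline_transform",
    "drop_zero_variance",
]


def validate_expression_matrix(m: pd.DataFrame) -> None:
    """Check the basic expression-matrix invariants (unique ids, finite values)."""
    if m.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if m.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")
    if not np.isfinite(m.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")


def validate_traits(m: pd.DataFrame, traits: pd.DataFrame) -> None:
    """Every matrix sample must have a trait row and both groups be non-empty."""
    missing = set(m.columns) - set(traits.index)
    if missing:
        raise ValueError(f"samples without trait rows: {sorted(missing)}")
    groups = traits.loc[list(m.columns), "group"]
    for g in ("control", "case"):
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g!r} has no samples")


def background_filter(
    raw: pd.DataFrame, traits: pd.DataFrame, lower_pct: float = 20.0
) -> list[str]:
    """Genes expressed above array background in all replicates of >=1 group.

    A gene passes on a given array when its signal is at or above the
    ``lower_pct`` percentile of that array's full value distribution
    (linear interpolation between order statistics).  The gene is kept
    when it passes on every array of at least one of the two groups.

    Parameters
    ----------
    raw : genes x samples matrix of non-negative raw signals.
    traits : per-sample table with a ``group`` column (control/case).
    lower_pct : lower percentile bound of the expressed window (default 20).

    Returns the list of retained gene ids, in matrix order.
    """
    validate_expression_matrix(raw)
    validate_traits(raw, traits)
    if (raw.to_numpy() < 0).any():
        raise ValueError("raw signal matrix must be non-negative")

    values = raw.to_numpy(dtype=float)
    thresholds = np.percentile(values, lower_pct, axis=0)  # per array, over genes
    passes = values >= thresholds[None, :]

    groups = traits.loc[list(raw.columns), "group"].to_numpy()
    keep = np.zeros(raw.shape[0], dtype=bool)
    for g in ("control", "case"):
        cols = groups == g
        keep |= passes[:, cols].all(axis=1)
    return list(raw.index[keep])


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common quantile (row-rank mean) distribution.

    After normalization each column holds the same sorted multiset — the
    vector of across-sample means of the order statistics — while
    within-column ranks are preserved.  Tied values receive the average of
    the reference values over their tied ranks.
    """
    validate_expression_matrix(m)
    if m.shape[1] < 2:
        warnings.warn("quantile_normalize with a single sample is the identity")
        return m.copy()

    values = m.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        out[order, j] = reference
        if len(np.unique(col)) < n:  # average the reference over tied ranks
            out[:, j] = (
                pd.Series(out[:, j]).groupby(pd.Series(col)).transform("mean").to_numpy()
            )
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def baseline_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's across-sample median (log2-scale baseline shift)."""
    validate_expression_matrix(m)
    medians = m.median(axis=1)
    return m.sub(medians, axis=0)


def drop_zero_variance(m: pd.DataFrame, tol: float = 0.0) -> pd.DataFrame:
    """Drop genes with no across-sample variance (correlation undefined)."""
    sd = m.to_numpy(dtype=float).std(axis=1)
    mask = sd > tol
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance genes", n_dropped)
    return m.loc[mask]
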