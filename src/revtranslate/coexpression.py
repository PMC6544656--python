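"""Unsigned weighted gene coexpression network analysis.

Builds an adjacency matrix |cor|^beta from pairwise Pearson correlations,
its topological overlap matrix (TOM), detects modules by average-linkage
hierarchical clustering on 1-TOM with a static tree cut and eigengene
merging, and relates module eigengenes to the binary sample trait.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_matrix",
    "pick_soft_threshold",
    "adjacency",
    "topological_overlap",
    "module_eigengene",
    "detect_modules",
    "cor_pvalue_student",
    "module_trait_table",
    "ModuleDetectionResult",
]

DEFAULT_BETA = 6  # pipeline operating soft-threshold exponent
DEFAULT_BETA_CANDIDATES = tuple(range(1, 11)) + (12, 14, 16, 18, 20)


def correlation_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between gene rows across samples."""
    if m.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlations")
    values = m.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = list(m.index[sd == 0])
        raise ValueError(f"zero-variance genes: {bad[:5]}")
    cor = np.corrcoef(values)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(np.clip(cor, -1.0, 1.0), index=m.index, columns=m.index)


def adjacency(cor: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_mn = |cor_mn|^beta, diagonal 1."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    values = np.abs(cor.to_numpy(dtype=float))
    if values.max() > 1 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    a = np.minimum(values, 1.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index of a connectivity vector.

    Bins log10(k) into equal-width bins, regresses log10(bin frequency)
    on log10(mean k per bin) and returns (signed R^2, slope); the R^2 is
    negated when the slope is positive.
    """
    k = k[k > 0]
    if k.size == 0:
        raise ValueError("all connectivities zero")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    which = np.digitize(logk, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    r2 = r * r
    return (-r2 if slope > 0 else r2), slope


def pick_soft_threshold(
    m: pd.DataFrame,
    candidates=DEFAULT_BETA_CANDIDATES,
    r2_target: float = 0.8,
) -> tuple[float, pd.DataFrame]:
    """Pick the soft-threshold exponent by the scale-free topology criterion.

    Returns the smallest candidate whose signed fit index reaches
    ``r2_target``; when none does, the candidate maximizing the fit index
    is returned with a warning.  The full fit table (beta, fit, slope,
    mean/median/max connectivity) accompanies the choice.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    cor = correlation_matrix(m)
    rows = []
    for beta in candidates:
        a = adjacency(cor, beta).to_numpy()
        k = a.sum(axis=0) - 1.0
        fit, slope = _scale_free_fit(k)
        rows.append(
            {
                "beta": beta,
                "fit": fit,
                "slope": slope,
                "mean_k": k.mean(),
                "median_k": float(np.median(k)),
                "max_k": k.max(),
            }
        )
    table = pd.DataFrame(rows)
    reaching = table[table["fit"] >= r2_target]
    if len(reaching):
        beta = float(reaching.iloc[0]["beta"])
    else:
        beta = float(table.loc[table["fit"].idxmax(), "beta"])
        warnings.warn(
            f"no candidate reached fit {r2_target}; falling back to argmax beta={beta}"
        )
    return beta, table


def topological_overlap(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij sums shared-neighbor adjacency products, k_i the connectivity of
    node i (excluding itself); the diagonal is 1 by convention.
    """
    av = a.to_numpy(dtype=float)
    if not np.allclose(av, av.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    k = av.sum(axis=0) - 1.0
    # l_ij = sum_{u != i,j} a_iu a_uj = (A @ A)_ij - 2 a_ij   (diag(A)=1)
    l = av @ av - 2.0 * av
    denom = np.minimum.outer(k, k) + 1.0 - av
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + av) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=a.index, columns=a.columns)


def module_eigengene(expr_sub: pd.DataFrame) -> pd.Series:
    """First principal component score (per sample) of a module.

    Genes are standardized to zero mean / unit variance across samples;
    the eigengene is the unit-norm leading left-singular direction of the
    samples x genes matrix, sign-oriented so that the mean correlation
    with the module's genes is non-negative.  It has zero mean across
    samples by construction.
    """
    x = expr_sub.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    me = u[:, 0]
    cors = np.array(
        [np.corrcoef(me, x[:, j])[0, 1] for j in range(x.shape[1]) if x[:, j].std() > 0]
    )
    if cors.size and cors.mean() < 0:
        me = -me
    return pd.Series(me, index=expr_sub.columns, name="eigengene")


@dataclass
class ModuleDetectionResult:
    """Module labels (0 = unassigned), eigengenes, and the dendrogram."""

    labels: pd.Series
    eigengenes: pd.DataFrame  # samples x modules
    linkage: np.ndarray = field(repr=False, default=None)


def _eigengene_frame(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    modules = sorted(set(labels) - {0})
    data = {
        m: module_eigengene(expr.loc[labels.index[labels == m]]) for m in modules
    }
    return pd.DataFrame(data, index=expr.columns)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel modules contiguously 1..K by decreasing size (0 stays 0)."""
    out = np.zeros_like(labels)
    sizes = pd.Series(labels[labels > 0]).value_counts()
    for new, old in enumerate(sizes.index, start=1):
        out[labels == old] = new
    return out


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 20,
    cut_height: float = 0.99,
    merge_cut_height: float = 0.25,
    expr: pd.DataFrame | None = None,
) -> ModuleDetectionResult:
    """Average-linkage clustering on 1-TOM with static cut and ME merging.

    Clusters from a static cut of the dendrogram at ``cut_height`` that
    fall below ``min_module_size`` are left unassigned (label 0).  Module
    pairs whose eigengene dissimilarity 1 - cor(ME_a, ME_b) falls below
    ``merge_cut_height`` are merged iteratively (closest pair first) and
    eigengenes recomputed.  ``expr`` supplies the expression matrix for
    eigengene computation.
    """
    if not (0 < cut_height < 1) or not (0 < merge_cut_height < 1):
        raise ValueError("cut heights must lie in (0,1)")
    if expr is None:
        raise ValueError("expr matrix required for eigengene computation")

    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    if np.allclose(dissim, dissim.flat[1]):
        warnings.warn("degenerate TOM: all dissimilarities equal")
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    labels = raw.copy()
    for lab, size in pd.Series(raw).value_counts().items():
        if size < min_module_size:
            labels[raw == lab] = 0
    labels = _relabel(labels)
    label_series = pd.Series(labels, index=tom.index, name="module")

    # iterative eigengene merging
    while True:
        modules = sorted(set(label_series) - {0})
        if len(modules) < 2:
            break
        me = _eigengene_frame(expr, label_series)
        cor = np.corrcoef(me.to_numpy().T)
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut_height:
            break
        a, b = modules[i], modules[j]
        label_series[label_series == b] = a
        label_series = pd.Series(
            _relabel(label_series.to_numpy()), index=label_series.index, name="module"
        )
        logger.info("merged modules %s and %s (dissim %.3f)", a, b, diss[i, j])

    eigengenes = _eigengene_frame(expr, label_series)
    return ModuleDetectionResult(labels=label_series, eigengenes=eigengenes, linkage=z)


def cor_pvalue_student(r: float, n: int) -> float:
    """Two-sided Student-t p-value of a Pearson correlation.

    t = r * sqrt(n-2) / sqrt(1-r^2) with n-2 df; |r| = 1 returns exactly 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def module_trait_table(
    me: pd.DataFrame, traits: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, int | None]:
    """Eigengene-trait Pearson correlations with Student-t significance.

    The trait is the binary case indicator (case=1, control=0).  The top
    module is the significant module with the largest |r| (ties broken by
    lower p); None when no module reaches ``alpha``.
    """
    groups = traits.loc[list(me.index), "group"]
    indicator = (groups == "case").astype(float).to_numpy()
    if indicator.std() == 0:
        raise ValueError("trait is constant")
    n = len(indicator)
    rows = []
    for module in me.columns:
        r = float(np.corrcoef(me[module].to_numpy(), indicator)[0, 1])
        p = cor_pvalue_student(r, n)
        rows.append({"module": module, "r": r, "p": p, "significant": p < alpha})
    table = pd.DataFrame(rows).set_index("module")
    sig = table[table["significant"]]
    top = None
    if len(sig):
        best = sig.assign(abs_r=sig["r"].abs()).sort_values(
            ["abs_r", "p"], ascending=[False, True]
        )
        top = best.index[0]
    return table, top
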