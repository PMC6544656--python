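"""Seeded synthetic data generators for the reverse-translation pipeline.

Three generators mirror the three data sources the analysis consumes:

* :func:`simulate_expression` — a small case/control microarray-like
  expression matrix (log2 intensities) with planted coexpressed modules
  driven by latent factors, at least one of which can be shifted in the
  case group.
* :func:`simulate_qpcr_cohort` — a two-group human cohort of marker
  relative-expression values in which a planted fraction of cases has a
  subset of markers reduced to a fixed multiple of the control level.
* :func:`simulate_clinical_table` — per-subject demographic/clinical
  covariates (normal continuous, multinomial categorical) per group.

All generators are deterministic given their config's integer seed; no
global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExprSimConfig",
    "ModuleTruth",
    "CohortSimConfig",
    "ClinicalSimConfig",
    "simulate_expression",
    "simulate_qpcr_cohort",
    "simulate_clinical_table",
    "table4_clinical_config",
]


@dataclass(frozen=True)
class ExprSimConfig:
    """Configuration for the planted-module expression simulator.

    Defaults reproduce the study design the pipeline targets: 7 control
    ("LM") and 5 case ("TG") arrays, two 50-gene modules with gene-factor
    loadings drawn from (0.7, 0.95), the first module down-shifted by 1.5
    within-group SD of its latent factor in cases, and independent
    background genes filling the matrix up to ``n_genes``.
    """

    n_genes: int = 2000
    n_control: int = 7
    n_case: int = 5
    module_sizes: tuple[int, ...] = (50, 50)
    module_gene_loading_range: tuple[float, float] = (0.7, 0.95)
    case_shift_per_module: tuple[float, ...] = (-1.5, 0.0)
    background_sd: float = 1.0
    gene_baseline_sd: float = 2.0
    intensity_offset: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        lo, hi = self.module_gene_loading_range
        if not (0.0 < lo <= hi < 1.0 or (lo == hi == 1.0)):
            raise ValueError("loadings must lie in (0,1) (or the degenerate 1.0)")
        if self.n_control + self.n_case < 4:
            raise ValueError("need at least 4 samples")
        if len(self.case_shift_per_module) != len(self.module_sizes):
            raise ValueError("one case shift per module required")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if self.gene_baseline_sd < 0:
            raise ValueError("gene_baseline_sd must be >= 0")


@dataclass(frozen=True)
class ModuleTruth:
    """Ground truth of a simulated expression matrix.

    ``gene_module`` maps every gene id to its planted module label
    (0 = independent background); ``module_shift`` maps module label to
    the planted case shift of its latent factor.
    """

    gene_module: pd.Series
    module_shift: dict[int, float]


def simulate_expression(
    config: ExprSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, ModuleTruth]:
    """Simulate a genes x samples log2 expression matrix with planted modules.

    Each planted module m has a per-sample latent factor e_m ~ N(0,1),
    shifted by ``case_shift_per_module[m]`` in case samples.  A gene g of
    module m with loading rho_g (uniform over the loading range) is
    ``rho_g * e_m + sqrt(1 - rho_g^2) * noise``; background genes are pure
    noise.  All genes are scaled by ``background_sd``, offset by
    ``intensity_offset`` plus a per-gene baseline drawn N(0,
    gene_baseline_sd) — microarray genes differ widely in basal intensity,
    which is what makes a per-array background-percentile filter
    meaningful — so values sit on a log2 scale around the offset.

    Returns
    -------
    (expr, traits, truth)
        ``expr``: DataFrame genes x samples; ``traits``: DataFrame indexed
        by sample id with a ``group`` column (control/case); ``truth``:
        :class:`ModuleTruth`.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_control + config.n_case
    sample_ids = [f"LM{i+1}" for i in range(config.n_control)] + [
        f"TG{i+1}" for i in range(config.n_case)
    ]
    group = ["control"] * config.n_control + ["case"] * config.n_case
    case_mask = np.asarray([g == "case" for g in group], dtype=float)

    gene_ids = [f"g{i+1:05d}" for i in range(config.n_genes)]
    values = np.empty((config.n_genes, n_samples))
    labels = np.zeros(config.n_genes, dtype=int)
    lo, hi = config.module_gene_loading_range

    row = 0
    for m, (size, shift) in enumerate(
        zip(config.module_sizes, config.case_shift_per_module), start=1
    ):
        latent = rng.standard_normal(n_samples) + shift * case_mask
        loadings = rng.uniform(lo, hi, size=size) if lo < hi else np.full(size, lo)
        noise = rng.standard_normal((size, n_samples))
        values[row : row + size] = (
            loadings[:, None] * latent[None, :]
            + np.sqrt(1.0 - loadings[:, None] ** 2) * noise
        )
        labels[row : row + size] = m
        row += size
    n_bg = config.n_genes - row
    if n_bg:
        values[row:] = rng.standard_normal((n_bg, n_samples))

    baselines = config.gene_baseline_sd * rng.standard_normal(config.n_genes)
    values = config.background_sd * values + config.intensity_offset + baselines[:, None]
    values = np.maximum(values, 0.0)  # log2 intensities floor at 0

    expr = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    traits = pd.DataFrame({"group": group}, index=pd.Index(sample_ids, name="sample_id"))
    truth = ModuleTruth(
        gene_module=pd.Series(labels, index=gene_ids, name="module"),
        module_shift={
            m: s for m, s in enumerate(config.case_shift_per_module, start=1)
        },
    )
    return expr, traits, truth


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration for the two-group marker-expression cohort simulator.

    Defaults emulate the larger validation cohort: 45 controls, 54
    patients, with 27% of patients forming a planted subset whose RGS1 and
    CCL4 relative expression is multiplied by 0.3 (i.e. reduced below the
    half-of-control-mean detection threshold with high probability).
    ``log_cv`` is the coefficient of variation of the log-normal marker
    distribution on the natural scale.
    """

    n_control: int = 45
    n_case: int = 54
    markers: tuple[str, ...] = ("RGS1", "CCL4")
    subset_fraction: float = 0.27
    subset_markers: tuple[str, ...] = ("RGS1", "CCL4")
    subset_multiplier: float = 0.3
    log_cv: float = 0.2
    marker_correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.subset_markers) <= set(self.markers):
            raise ValueError("subset_markers must be a subset of markers")
        if not (0.0 <= self.subset_fraction <= 1.0):
            raise ValueError("subset_fraction must lie in [0,1]")
        if not (0.0 < self.subset_multiplier < 1.0):
            raise ValueError("subset_multiplier must lie in (0,1)")
        if self.log_cv <= 0:
            raise ValueError("log_cv must be positive")
        if self.marker_correlation is not None:
            c = np.asarray(self.marker_correlation, dtype=float)
            k = len(self.markers)
            if c.shape != (k, k) or not np.allclose(c, c.T):
                raise ValueError("marker_correlation must be a symmetric k x k matrix")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError("marker_correlation diagonal must be 1")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("marker_correlation must be positive semidefinite")


def simulate_qpcr_cohort(
    config: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Simulate per-sample marker relative expression for a case/control cohort.

    Control expression is log-normal with geometric mean 1 and a Gaussian
    copula across markers given by ``marker_correlation`` (identity when
    None).  A fixed, randomly chosen ``round(subset_fraction * n_case)``
    cases have every marker in ``subset_markers`` multiplied by
    ``subset_multiplier``.

    Returns (expression table samples x markers, group labels, subset truth).
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.markers)
    corr = (
        np.eye(k)
        if config.marker_correlation is None
        else np.asarray(config.marker_correlation, dtype=float)
    )
    sigma = np.sqrt(np.log1p(config.log_cv**2))  # log-scale SD from natural-scale CV

    n = config.n_control + config.n_case
    sample_ids = [f"CTRL{i+1:03d}" for i in range(config.n_control)] + [
        f"SCZ{i+1:03d}" for i in range(config.n_case)
    ]
    labels = pd.Series(
        ["control"] * config.n_control + ["case"] * config.n_case,
        index=sample_ids,
        name="group",
    )

    # Gaussian copula: correlated standard normals, then log-normal marginals.
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    z = rng.standard_normal((n, k)) @ chol.T
    expr = np.exp(sigma * z)

    subset = np.zeros(n, dtype=bool)
    n_subset = int(round(config.subset_fraction * config.n_case))
    case_idx = np.arange(config.n_control, n)
    chosen = rng.choice(case_idx, size=n_subset, replace=False)
    subset[chosen] = True
    for j, marker in enumerate(config.markers):
        if marker in config.subset_markers:
            expr[subset, j] *= config.subset_multiplier

    table = pd.DataFrame(expr, index=sample_ids, columns=list(config.markers))
    subset_truth = pd.Series(subset, index=sample_ids, name="planted_subset")
    return table, labels, subset_truth


@dataclass(frozen=True)
class ClinicalSimConfig:
    """Per-group distributions for a synthetic clinical covariate table.

    ``continuous`` maps covariate -> {group: (mean, sd)}; ``categorical``
    maps covariate -> {group: {level: probability}}.
    """

    group_sizes: dict[str, int] = field(default_factory=dict)
    continuous: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    categorical: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group_sizes or any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be positive")
        for cov, per_group in self.categorical.items():
            for g, probs in per_group.items():
                if abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ValueError(
                        f"probabilities for {cov!r} in group {g!r} must sum to 1"
                    )
        for cov, per_group in self.continuous.items():
            for g, (_, sd) in per_group.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {cov!r} in group {g!r}")


def simulate_clinical_table(config: ClinicalSimConfig, seed: int) -> pd.DataFrame:
    """Draw a per-subject clinical table from the configured distributions."""
    rng = np.random.default_rng(seed)
    rows: dict[str, list] = {"group": []}
    for cov in list(config.continuous) + list(config.categorical):
        rows[cov] = []
    index = []
    for g, size in config.group_sizes.items():
        for i in range(size):
            index.append(f"{g}_{i+1:03d}")
            rows["group"].append(g)
        for cov, per_group in config.continuous.items():
            mean, sd = per_group[g]
            rows[cov].extend(rng.normal(mean, sd, size=size).tolist())
        for cov, per_group in config.categorical.items():
            levels = list(per_group[g])
            probs = np.asarray([per_group[g][l] for l in levels], dtype=float)
            rows[cov].extend(rng.choice(levels, size=size, p=probs).tolist())
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))


def table4_clinical_config() -> ClinicalSimConfig:
    """Marker-negative vs marker-positive clinical covariate structure.

    Group sizes and per-group means/SDs/category proportions follow the
    published demographics of the validation cohort's marker-defined
    subgroups (37 marker-negative vs 13 marker-positive patients).
    """
    neg, pos = "marker_negative", "marker_positive"
    return ClinicalSimConfig(
        group_sizes={neg: 37, pos: 13},
        continuous={
            "age": {neg: (32.24, 11.13), pos: (40.0, 11.19)},
            "duration_of_illness": {neg: (8.55, 9.04), pos: (9.54, 8.33)},
            "hospitalizations": {neg: (4.03, 3.33), pos: (3.15, 1.57)},
            "panss_total": {neg: (61.67, 17.50), pos: (54.92, 12.44)},
            "panss_positive": {neg: (14.03, 5.59), pos: (11.54, 3.57)},
            "panss_negative": {neg: (16.75, 5.12), pos: (16.69, 6.58)},
            "panss_general": {neg: (30.89, 9.31), pos: (26.69, 4.11)},
        },
        categorical={
            "sex": {
                neg: {"male": 29 / 38, "female": 9 / 38},
                pos: {"male": 8 / 10, "female": 2 / 10},
            },
            "clozapine": {
                neg: {"yes": 5 / 37, "no": 32 / 37},
                pos: {"yes": 8 / 13, "no": 5 / 13},
            },
            "language": {
                neg: {"german": 30 / 37, "foreign": 7 / 37},
                pos: {"german": 1.0, "foreign": 0.0},
            },
            "handedness": {
                neg: {"right": 33 / 37, "left": 4 / 37, "both": 0.0},
                pos: {"right": 11 / 13, "left": 1 / 13, "both": 1 / 13},
            },
        },
    )
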