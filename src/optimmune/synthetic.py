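"""Synthetic Leslie-matrix ensembles and regression test data.

The ensemble generator emulates the heterogeneity of an age-classified
(one-year classes) animal matrix database: matrices of varying dimension
with varied ages at first reproduction, two-phase survival curves (a
juvenile hazard up to maturity, an adult hazard with an optional
Gompertz-like increase in age), fertility levels spanning more than an
order of magnitude with constant / rising / declining shapes, and a
terminal self-loop strictly below 1.  Every emitted matrix passes the
pipeline's structural filter.

Randomness flows from one top-level seed through named spawned substreams,
so identical seeds give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .comadre import check_matrix
from .demography import build_leslie, life_history_stats, write_matrix_csv

__all__ = ["EnsembleConfig", "generate_leslie_ensemble", "generate_regression_data", "write_ensemble"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Parameter ranges of the ensemble generator.

    Ranges are inclusive; ages in one-year classes, survivals as annual
    probabilities (strictly below 1 so every life expectancy is finite),
    fertility as offspring per class.  ``fertility_level_range`` is sampled
    log-uniformly so reproductive rates span orders of magnitude, as they
    do across real taxa.
    """

    n: int = 300
    first_repro_range: tuple[int, int] = (1, 5)
    repro_years_range: tuple[int, int] = (2, 12)
    juvenile_survival_range: tuple[float, float] = (0.3, 0.9)
    adult_survival_range: tuple[float, float] = (0.5, 0.95)
    gompertz_rate_range: tuple[float, float] = (0.0, 0.15)
    fertility_level_range: tuple[float, float] = (0.2, 6.0)
    fertility_shapes: tuple[str, ...] = ("constant", "rising", "declining")
    terminal_survival_range: tuple[float, float] = (0.05, 0.9)
    max_attempts: int = 1000

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("juvenile_survival_range", "adult_survival_range", "terminal_survival_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi < 1):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi < 1")
        if self.fertility_level_range[0] <= 0:
            raise ValueError("fertility levels must be positive")
        if self.first_repro_range[0] < 1:
            raise ValueError("first reproduction must be class 1 or later")


def _one_matrix(rng: np.random.Generator, cfg: EnsembleConfig) -> np.ndarray:
    m = int(rng.integers(cfg.first_repro_range[0], cfg.first_repro_range[1] + 1))
    repro_years = int(rng.integers(cfg.repro_years_range[0], cfg.repro_years_range[1] + 1))
    D = m + repro_years  # classes beyond maturity set the reproductive span
    s_juv = rng.uniform(*cfg.juvenile_survival_range)
    s_adult = rng.uniform(*cfg.adult_survival_range)
    g = rng.uniform(*cfg.gompertz_rate_range)
    s_term = rng.uniform(*cfg.terminal_survival_range)

    ages = np.arange(1, D + 1)
    h_juv = -np.log(s_juv)
    h_adult = -np.log(s_adult)
    hazard = np.where(ages < m, h_juv, h_adult * np.exp(g * (ages - m)))
    survival = np.exp(-hazard)
    survival[-1] = min(s_term, cfg.terminal_survival_range[1])

    level = np.exp(rng.uniform(*np.log(cfg.fertility_level_range)))
    shape = cfg.fertility_shapes[rng.integers(len(cfg.fertility_shapes))]
    n_repro = D - m + 1
    if shape == "constant":
        seg = np.full(n_repro, level)
    elif shape == "rising":
        seg = np.linspace(0.5 * level, 1.5 * level, n_repro)
    else:
        seg = np.linspace(1.5 * level, 0.5 * level, n_repro)
    fertility = np.concatenate([np.zeros(m - 1), seg])
    return build_leslie(fertility, survival)


def generate_leslie_ensemble(
    config: EnsembleConfig = EnsembleConfig(), seed: int = 0
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Generate ``config.n`` filter-passing matrices plus a metadata table.

    Metadata columns: id, dim, and the four life-history statistics of each
    matrix.  Raises if a matrix cannot satisfy the structural filter within
    ``config.max_attempts`` draws (degenerate ranges).
    """
    ss = np.random.SeedSequence(seed, spawn_key=(0,))  # 'ensemble' substream
    children = ss.spawn(config.n)
    matrices: list[np.ndarray] = []
    rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        for _ in range(config.max_attempts):
            A = _one_matrix(rng, config)
            if check_matrix(A).passed:
                break
        else:
            raise RuntimeError(
                f"could not generate a filter-passing matrix in {config.max_attempts} attempts"
            )
        mid = f"syn{i:04d}"
        stats = life_history_stats(A)
        matrices.append(A)
        rows.append(
            {
                "id": mid,
                "dim": A.shape[0],
                "first_repro_class": stats.first_repro_class,
                "repro_life_expectancy": stats.repro_life_expectancy,
                "mean_repro_rate": stats.mean_repro_rate,
                "generation_time": stats.generation_time,
            }
        )
    meta = pd.DataFrame(
        rows,
        columns=[
            "id",
            "dim",
            "first_repro_class",
            "repro_life_expectancy",
            "mean_repro_rate",
            "generation_time",
        ],
    )
    return matrices, meta


def generate_regression_data(
    n: int,
    alpha: float,
    beta: np.ndarray,
    sigma: float,
    seed: int = 0,
    corr: float = 0.3,
    predictor_names: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Standardized correlated predictors and a linear Gaussian response.

    Predictors are drawn from a multivariate normal with pairwise
    correlation ``corr`` (default 0.3, mimicking life-history trait
    collinearity), then exactly Z-scored; ``y = alpha + X beta + eps`` with
    ``eps ~ Normal(0, sigma)``.
    """
    beta = np.asarray(beta, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    k = len(beta)
    ss = np.random.SeedSequence(seed, spawn_key=(1,))  # 'noise' substream
    rng = np.random.default_rng(ss)
    cov = np.full((k, k), float(corr))
    np.fill_diagonal(cov, 1.0)
    X = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    y = alpha + X @ beta + sigma * rng.standard_normal(n)
    if predictor_names is None:
        predictor_names = tuple(f"x{i + 1}" for i in range(k))
    return pd.DataFrame(X, columns=list(predictor_names)), y


def write_ensemble(
    matrices: list[np.ndarray], meta: pd.DataFrame, directory: str | Path
) -> None:
    """Write matrices as ``<id>.csv`` plus ``metadata.csv`` in pipeline format."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for A, mid in zip(matrices, meta["id"]):
        write_matrix_csv(A, directory / f"{mid}.csv")
    meta.to_csv(directory / "metadata.csv", index=False)
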