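"""Empirical-style projection-matrix pipeline.

Takes age-classified (one-year classes) projection matrices of the kind
distributed by the COMADRE animal matrix database, and for each one:

1. filters on structure (Leslie form, irreducible, primitive, ergodic);
2. computes life-history statistics from the *original* matrix;
3. resizes the matrix to dimension = age at first reproduction +
   reproductive life expectancy (expansion duplicates the terminal class,
   which leaves the dynamics, including lambda, exactly unchanged;
   collapsing merges the oldest classes into one terminal class by
   stable-age-weighted averaging, which perturbs lambda only slightly);
4. splits the matrix's observed mortality into a background share
   ``mu_b[x] = -rho * log(s_x)`` (the fraction ``rho`` of each class's total
   hazard attributed to non-disease causes) and an epidemiological share
   supplied by a scenario;
5. grid-searches the specificity maximizing the rebuilt population's growth
   rate.

The ingestion interface is plain CSV: one numeric D x D file per matrix
plus a metadata table with an ``id`` column (native serialized COMADRE
archives are out of scope; export to CSV first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import (
    LeslieStructureError,
    LifeHistoryStats,
    eigen_summary,
    growth_rate,
    is_ergodic,
    is_irreducible,
    is_leslie_structured,
    is_primitive,
    leslie_parts,
    life_history_stats,
    read_matrix_csv,
)
from .optimizer import Optimum, optimize_strategy
from .schedules import ScenarioSpec, build_risk_schedule

__all__ = [
    "FilterReport",
    "ProcessedRecord",
    "check_matrix",
    "target_dimension",
    "expand_matrix",
    "collapse_matrix",
    "resize_matrix",
    "decompose_background_mortality",
    "process_matrix",
    "process_ensemble",
    "read_matrix_directory",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

CHECK_NAMES = (
    "leslie_structure",
    "positive_subdiagonal",
    "has_fertility",
    "irreducible",
    "primitive",
    "ergodic",
)


@dataclass(frozen=True)
class FilterReport:
    """Named structural checks; ``passed`` is their conjunction."""

    checks: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.checks.values())

    @property
    def failed_checks(self) -> list[str]:
        return [k for k, ok in self.checks.items() if not ok]


def check_matrix(A: np.ndarray) -> FilterReport:
    """Structural filter deciding whether a matrix enters the pipeline."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if not np.all(np.isfinite(A)) or np.any(A < 0):
        raise ValueError("matrix must be finite and nonnegative")
    checks = {}
    checks["leslie_structure"] = is_leslie_structured(A)
    F, S = leslie_parts(A)
    checks["positive_subdiagonal"] = bool(np.all(S[:-1] > 0))
    checks["has_fertility"] = bool(np.any(F > 0))
    checks["irreducible"] = is_irreducible(A)
    checks["primitive"] = is_primitive(A)
    checks["ergodic"] = is_ergodic(A)
    return FilterReport(checks=checks)


def target_dimension(stats: LifeHistoryStats) -> int:
    """Resize target: first reproduction age + reproductive life expectancy,
    rounded half up, floored at 2."""
    raw = stats.first_repro_class + stats.repro_life_expectancy
    return max(2, int(np.floor(raw + 0.5)))


def expand_matrix(A: np.ndarray, target_D: int) -> np.ndarray:
    """Grow to ``target_D`` classes by duplicating the terminal class.

    New classes copy the terminal fertility and survival; the terminal
    self-loop moves to the new corner.  Exactly lambda-preserving because
    the terminal class already describes all older individuals.
    """
    A = np.asarray(A, dtype=float)
    D = A.shape[0]
    if target_D < D:
        raise ValueError(f"target dimension {target_D} smaller than current {D}")
    if target_D == D:
        return A.copy()
    F, S = leslie_parts(A)
    F2 = np.concatenate([F, np.full(target_D - D, F[-1])])
    # old self-loop survival becomes the transition through each new class
    S2 = np.concatenate([S[:-1], np.full(target_D - D + 1, S[-1])])
    from .demography import build_leslie

    return build_leslie(F2, S2)


def collapse_matrix(A: np.ndarray, target_D: int) -> np.ndarray:
    """Shrink to ``target_D`` classes by merging the oldest classes.

    Classes ``target_D..D`` merge into one terminal class whose fertility
    and outgoing survival are means of the merged classes' values weighted
    by the stable age distribution of ``A``.  The transition into the merged
    class (from class ``target_D - 1``) is kept unchanged.
    """
    A = np.asarray(A, dtype=float)
    D = A.shape[0]
    if not 2 <= target_D < D:
        raise ValueError(f"target dimension must lie in [2, {D - 1}], got {target_D}")
    F, S = leslie_parts(A)
    w = eigen_summary(A).w
    merged = slice(target_D - 1, D)  # 0-based block of classes target_D..D
    wm = w[merged]
    if wm.sum() <= 0:
        raise ValueError("stable age weight of the merged block is zero")
    f_new = float(wm @ F[merged] / wm.sum())
    s_new = float(wm @ S[merged] / wm.sum())  # outgoing survival, self-loop for the last
    F2 = np.concatenate([F[: target_D - 1], [f_new]])
    S2 = np.concatenate([S[: target_D - 1], [s_new]])
    # S2[target_D - 2] is the original transition into the merged block.
    from .demography import build_leslie

    return build_leslie(F2, S2)


def resize_matrix(A: np.ndarray, target_D: int) -> tuple[np.ndarray, str]:
    """Dispatch to expansion or collapse; returns (matrix, action)."""
    D = np.asarray(A).shape[0]
    if target_D == D:
        return np.asarray(A, dtype=float).copy(), "unchanged"
    if target_D > D:
        return expand_matrix(A, target_D), "expanded"
    return collapse_matrix(A, target_D), "collapsed"


def decompose_background_mortality(A_resized: np.ndarray, rho: float) -> np.ndarray:
    """Background-mortality vector ``mu_b[x] = -rho * log(s_x)``.

    ``s_x`` is the survival out of class x in the resized matrix (the
    terminal self-loop for the last class).  A terminal self-loop of exactly
    0 yields ``mu_b = +inf``, the sentinel that pins reconstructed terminal
    survival to 0; a zero survival in any earlier class is an exclusion
    error (the class is unreachable-from, so the matrix should have been
    filtered out).
    """
    if not 0 < rho <= 1:
        raise ValueError(f"rho must lie in (0, 1], got {rho}")
    _, S = leslie_parts(np.asarray(A_resized, dtype=float))
    if np.any(S[:-1] <= 0):
        raise ValueError("zero survival before the terminal class; matrix excluded")
    with np.errstate(divide="ignore"):
        mu_b = -rho * np.log(S)
    return mu_b


@dataclass(frozen=True)
class ProcessedRecord:
    """Full result of the pipeline for one matrix."""

    id: str
    stats_orig: LifeHistoryStats
    target_D: int
    resize_action: str
    lam_orig: float
    lam_resized: float
    optimum: Optimum


def process_matrix(
    A: np.ndarray,
    scenario: ScenarioSpec,
    rho: float = 0.75,
    step: float = 0.001,
    matrix_id: str = "",
) -> ProcessedRecord:
    """Run one matrix through the whole pipeline (see module docstring).

    The stepped risk mode jumps at the matrix's own age class of first
    reproduction; the smoothed mode runs linearly from class 1 to the
    resized terminal class, so the total risk change over life is the same
    for every matrix regardless of dimension.
    """

    def _stage(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed for matrix {matrix_id!r}: {exc}") from exc

    report = _stage("filter", check_matrix, A)
    if not report.passed:
        raise ValueError(
            f"matrix {matrix_id!r} failed checks: {', '.join(report.failed_checks)}"
        )
    stats = _stage("life_history", life_history_stats, A)
    tD = target_dimension(stats)
    lam_orig = _stage("eigen", growth_rate, A)
    A2, action = _stage("resize", resize_matrix, A, tD)
    lam_resized = _stage("eigen_resized", growth_rate, A2)
    mu_b = _stage("decompose", decompose_background_mortality, A2, rho)
    risk = _stage(
        "risk_schedule",
        build_risk_schedule,
        scenario,
        tD,
        maturity_class=min(stats.first_repro_class, tD),
        mu_b=mu_b,
    )
    fertility, _ = leslie_parts(A2)
    optimum = _stage("optimize", optimize_strategy, fertility, risk, scenario.gamma, step)
    return ProcessedRecord(
        id=matrix_id,
        stats_orig=stats,
        target_D=tD,
        resize_action=action,
        lam_orig=lam_orig,
        lam_resized=lam_resized,
        optimum=optimum,
    )


def process_ensemble(
    matrices: list[np.ndarray],
    ids: list[str],
    scenario: ScenarioSpec,
    rho: float = 0.75,
    step: float = 0.001,
) -> tuple[list[ProcessedRecord], pd.DataFrame]:
    """Filter and process a collection; returns records + a filter report table."""
    records: list[ProcessedRecord] = []
    rows = []
    for A, mid in zip(matrices, ids):
        report = check_matrix(A)
        rows.append({"id": mid, "passed": report.passed, **report.checks})
        if not report.passed:
            logger.warning("excluding %s: failed %s", mid, ", ".join(report.failed_checks))
            continue
        records.append(process_matrix(A, scenario, rho=rho, step=step, matrix_id=mid))
        logger.info("processed %s (D=%d -> %d)", mid, A.shape[0], records[-1].target_D)
    return records, pd.DataFrame(rows)


def records_to_frame(records: list[ProcessedRecord]) -> pd.DataFrame:
    """Long-format table of processed records (one row per matrix)."""
    return pd.DataFrame(
        {
            "id": r.id,
            "first_repro_class": r.stats_orig.first_repro_class,
            "repro_life_expectancy": r.stats_orig.repro_life_expectancy,
            "mean_repro_rate": r.stats_orig.mean_repro_rate,
            "generation_time": r.stats_orig.generation_time,
            "target_D": r.target_D,
            "resize_action": r.resize_action,
            "lam_orig": r.lam_orig,
            "lam_resized": r.lam_resized,
            "sp_star": r.optimum.sp_star,
            "se_star": r.optimum.se_star,
            "lam_max": r.optimum.lam_max,
        }
        for r in records
    )


def read_matrix_directory(
    directory: str | Path, metadata_csv: str | Path | None = None
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Read every ``*.csv`` matrix in ``directory`` plus its metadata table.

    Without a metadata table the file stems become the ids.  Matrices are
    read unvalidated; run :func:`check_matrix` (or :func:`process_ensemble`)
    to filter.
    """
    directory = Path(directory)
    if metadata_csv is not None:
        meta = pd.read_csv(metadata_csv, dtype={"id": str})
        ids = list(meta["id"])
    else:
        ids = sorted(p.stem for p in directory.glob("*.csv"))
        meta = pd.DataFrame({"id": ids})
    matrices = [read_matrix_csv(directory / f"{mid}.csv", validate=False) for mid in ids]
    return matrices, meta
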