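"""Grid search for the fitness-maximizing immune strategy.

For every specificity on the grid {0, step, ..., 1} (1001 points at the
default step of 0.001) the implied sensitivity, per-class hazards, survival
probabilities, and Leslie matrix are assembled, and the population growth
rate lambda is computed as the dominant eigenvalue.  The optimum is the grid
point maximizing lambda; exact ties go to the smallest specificity (only
reachable when the objective is flat, e.g. with no epidemiological
mortality at all).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RiskSchedule, hazard_profile, sensitivity_from_specificity, survival_probability
from .demography import LeslieStructureError, growth_rates, is_primitive

__all__ = ["Optimum", "sp_grid", "optimize_strategy"]


@dataclass(frozen=True)
class Optimum:
    """Result of a specificity grid search."""

    sp_star: float
    se_star: float
    lam_max: float
    sp_values: np.ndarray
    lam_curve: np.ndarray


def sp_grid(step: float = 0.001) -> np.ndarray:
    """Specificity grid {0, step, ..., 1}, both endpoints included."""
    if not 0 < step <= 0.5:
        raise ValueError("step must lie in (0, 0.5]")
    n = int(round(1.0 / step))
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1 evenly")
    return np.arange(n + 1) * step


def _matrix_stack(fertility: np.ndarray, surv: np.ndarray) -> np.ndarray:
    """(G, D, D) Leslie matrices from one fertility row and (G, D) survivals."""
    G, D = surv.shape
    A = np.zeros((G, D, D))
    A[:, 0, :] = fertility
    idx = np.arange(D - 1)
    A[:, idx + 1, idx] = surv[:, :-1]
    A[:, -1, -1] = surv[:, -1]
    return A


def optimize_strategy(
    fertility: np.ndarray,
    risk: RiskSchedule,
    gamma: float,
    step: float = 0.001,
    check_primitive: bool = True,
) -> Optimum:
    """Maximize lambda over the specificity grid.

    ``check_primitive=False`` skips the structural gate; the spectral
    radius is still well defined for periodic life cycles (e.g. strict
    semelparity with zero terminal survival), it just ceases to describe
    convergent age-structure dynamics.

    Raises
    ------
    LeslieStructureError
        If the assembled life cycle is not primitive (the growth rate of a
        non-primitive matrix does not describe long-run dynamics).
    """
    fertility = np.asarray(fertility, dtype=float)
    if len(fertility) != len(risk):
        raise ValueError(
            f"fertility length {len(fertility)} != risk schedule length {len(risk)}"
        )
    if np.any(fertility < 0) or not np.all(np.isfinite(fertility)):
        raise LeslieStructureError("negative or non-finite fertility")
    grid = sp_grid(step)
    haz = hazard_profile(grid, gamma, risk)  # (G, D)
    surv = survival_probability(haz)
    A = _matrix_stack(fertility, surv)
    # The zero pattern is shared by all grid points (survivals are exp of
    # finite hazards, hence > 0, except inf-hazard classes which are 0 for
    # every sp); one primitivity check covers the whole grid.
    if check_primitive and not is_primitive(A[0]):
        raise LeslieStructureError("assembled matrix failed check: primitive")
    lam = growth_rates(A)
    i = int(np.argmax(lam))  # first maximum: smallest sp wins ties
    return Optimum(
        sp_star=float(grid[i]),
        se_star=sensitivity_from_specificity(float(grid[i]), gamma),
        lam_max=float(lam[i]),
        sp_values=grid,
        lam_curve=lam,
    )
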