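"""Leslie matrices: construction, eigen-analysis, and life-history statistics.

The projection convention is ``n(t+1) = A @ n(t)`` (column j feeds row i).
A D-class Leslie matrix has per-class fertilities in the first row, survival
probabilities on the subdiagonal, and a terminal self-loop in the bottom
right corner describing all individuals in the last class and older.  The
dominant eigenvalue ``lambda`` is the asymptotic population growth rate and
serves as the fitness measure throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.linalg

__all__ = [
    "LeslieStructureError",
    "EigenSummary",
    "LifeHistoryStats",
    "build_leslie",
    "leslie_parts",
    "validate_leslie",
    "is_leslie_structured",
    "is_irreducible",
    "is_primitive",
    "is_ergodic",
    "growth_rate",
    "growth_rates",
    "eigen_summary",
    "life_history_stats",
    "read_matrix_csv",
    "write_matrix_csv",
]


class LeslieStructureError(ValueError):
    """A matrix violates the Leslie structural invariants; names the check."""


def build_leslie(fertility, survival) -> np.ndarray:
    """Assemble a D x D Leslie matrix.

    ``survival[0:D-1]`` are the subdiagonal transitions (class x to x+1) and
    ``survival[D-1]`` is the terminal self-loop.
    """
    F = np.asarray(fertility, dtype=float)
    S = np.asarray(survival, dtype=float)
    if F.ndim != 1 or S.ndim != 1 or len(F) != len(S):
        raise LeslieStructureError("fertility and survival must be equal-length vectors")
    D = len(F)
    if D < 2:
        raise LeslieStructureError("need at least 2 age classes")
    if np.any(F < 0) or not np.all(np.isfinite(F)):
        raise LeslieStructureError("fertility entries must be finite and >= 0")
    if np.any(S < 0) or np.any(S > 1) or not np.all(np.isfinite(S)):
        raise LeslieStructureError("survival entries must lie in [0, 1]")
    A = np.zeros((D, D))
    A[0, :] = F
    A[np.arange(1, D), np.arange(D - 1)] = S[:-1]
    A[-1, -1] = S[-1]
    return A


def leslie_parts(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`build_leslie`: (fertility, survival) vectors."""
    A = np.asarray(A, dtype=float)
    D = A.shape[0]
    F = A[0, :].copy()
    S = np.empty(D)
    S[:-1] = A[np.arange(1, D), np.arange(D - 1)]
    S[-1] = A[-1, -1]
    return F, S


def is_leslie_structured(A: np.ndarray) -> bool:
    """True iff nonzeros occur only in row 1, the subdiagonal, and corner (D,D)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    D = A.shape[0]
    mask = np.zeros((D, D), dtype=bool)
    mask[0, :] = True
    mask[np.arange(1, D), np.arange(D - 1)] = True
    mask[-1, -1] = True
    if np.any(A[~mask] != 0):
        return False
    _, S = leslie_parts(A)
    return bool(np.all(S >= 0) and np.all(S <= 1) and np.all(A[0] >= 0))


def validate_leslie(A: np.ndarray) -> None:
    """Raise :class:`LeslieStructureError` naming the first failed invariant."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise LeslieStructureError("not square")
    if not np.all(np.isfinite(A)):
        raise LeslieStructureError("non-finite entries")
    if A.shape[0] < 2:
        raise LeslieStructureError("need at least 2 age classes")
    D = A.shape[0]
    mask = np.zeros((D, D), dtype=bool)
    mask[0, :] = True
    mask[np.arange(1, D), np.arange(D - 1)] = True
    mask[-1, -1] = True
    if np.any(A[~mask] != 0):
        raise LeslieStructureError(
            "nonzero entries outside first row, subdiagonal, and terminal corner"
        )
    F, S = leslie_parts(A)
    if np.any(F < 0):
        raise LeslieStructureError("negative fertility in first row")
    if np.any(S < 0) or np.any(S > 1):
        raise LeslieStructureError("survival outside [0, 1]")
    if not np.any(F > 0):
        raise LeslieStructureError("no positive fertility entry")


def _life_cycle_graph(A: np.ndarray) -> nx.DiGraph:
    # edge j -> i whenever class j contributes to class i (A[i, j] > 0)
    i_idx, j_idx = np.nonzero(np.asarray(A) > 0)
    G = nx.DiGraph()
    G.add_nodes_from(range(A.shape[0]))
    G.add_edges_from(zip(j_idx, i_idx))
    return G


def is_irreducible(A: np.ndarray) -> bool:
    """Strong connectivity of the life-cycle digraph."""
    return nx.is_strongly_connected(_life_cycle_graph(A))


def is_primitive(A: np.ndarray) -> bool:
    """Primitivity via boolean powers up to the Wielandt bound D^2 - 2D + 2."""
    B = (np.asarray(A) > 0)
    D = B.shape[0]
    limit = D * D - 2 * D + 2
    P = B.copy()
    for _ in range(limit - 1):
        if P.all():
            return True
        P = (P @ B) > 0
    return bool(P.all())


def is_ergodic(A: np.ndarray, rtol: float = 1e-9) -> bool:
    """Unique eigenvalue of maximal modulus (no other mode of equal size)."""
    ev = np.linalg.eigvals(np.asarray(A, dtype=float))
    mods = np.sort(np.abs(ev))[::-1]
    if mods[0] == 0:
        return False
    return len(mods) == 1 or (mods[0] - mods[1]) > rtol * mods[0]


def _dominant_eigenvalue(ev: np.ndarray) -> float:
    # For a nonnegative matrix the spectral radius is itself an eigenvalue
    # (Perron-Frobenius), so the largest real eigenvalue is the growth rate;
    # taking max-modulus instead would tie-break arbitrarily for periodic
    # matrices with a -rho eigenvalue.
    real = ev[np.abs(ev.imag) <= 1e-9 * np.maximum(1.0, np.abs(ev))]
    if len(real) == 0:
        raise np.linalg.LinAlgError("no real dominant eigenvalue found")
    return float(np.max(np.real(real)))


def growth_rate(A: np.ndarray) -> float:
    """Population growth rate: the dominant (Perron) eigenvalue of ``A``."""
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite entries")
    return _dominant_eigenvalue(np.linalg.eigvals(A))


def growth_rates(stack: np.ndarray) -> np.ndarray:
    """Dominant eigenvalues of a (G, D, D) stack of projection matrices."""
    ev = np.linalg.eigvals(np.asarray(stack, dtype=float))
    real_mask = np.abs(ev.imag) <= 1e-9 * np.maximum(1.0, np.abs(ev))
    val = np.where(real_mask, ev.real, -np.inf)  # Perron root = largest real eigenvalue
    return np.max(val, axis=-1)


@dataclass(frozen=True)
class EigenSummary:
    """Dominant eigen-structure of a projection matrix.

    lam
        Population growth rate (dominant eigenvalue).
    w
        Stable age distribution (right eigenvector, sums to 1).
    v
        Reproductive value (left eigenvector, first entry 1).
    E
        Elasticity matrix ``e_ij = (a_ij / lam) * v_i w_j / (v . w)``; the
        proportional response of lambda to a proportional perturbation of
        ``a_ij``.  Entries sum to 1.
    """

    lam: float
    w: np.ndarray
    v: np.ndarray
    E: np.ndarray


def eigen_summary(A: np.ndarray) -> EigenSummary:
    """Growth rate, stable age structure, reproductive value, elasticities."""
    A = np.asarray(A, dtype=float)
    ev, vl, vr = scipy.linalg.eig(A, left=True, right=True)
    lam = _dominant_eigenvalue(ev)
    k = int(np.argmin(np.abs(ev - lam)))
    w = np.real(vr[:, k])
    v = np.real(vl[:, k])
    if w.sum() < 0:
        w = -w
    if v[0] < 0:
        v = -v
    if np.any(w < -1e-9 * np.abs(w).max()) or v[0] <= 0:
        raise np.linalg.LinAlgError("dominant eigenvectors not one-signed; matrix primitive?")
    w = np.clip(w, 0.0, None)
    w = w / w.sum()
    v = v / v[0]
    E = (A / lam) * np.outer(v, w) / float(v @ w)
    return EigenSummary(lam=lam, w=w, v=v, E=E)


@dataclass(frozen=True)
class LifeHistoryStats:
    """Life-history summary of a Leslie matrix (1-based age classes).

    first_repro_class
        Smallest age class with positive fertility, m.
    repro_life_expectancy
        Expected years spent in classes >= m given arrival at class m
        (fundamental-matrix expectation, counts the year of arrival).
    mean_repro_rate
        Arithmetic mean fertility over classes >= m.
    generation_time
        Mean age of mothers at stable structure, T = lam (v.w) / (v.Fw).
    """

    first_repro_class: int
    repro_life_expectancy: float
    mean_repro_rate: float
    generation_time: float


def life_history_stats(A: np.ndarray) -> LifeHistoryStats:
    """Four life-history statistics used by the trait meta-regression."""
    A = np.asarray(A, dtype=float)
    validate_leslie(A)
    F, S = leslie_parts(A)
    D = len(F)
    if S[-1] >= 1.0:
        raise ValueError("terminal self-loop survival of 1 implies an immortal class")
    m = int(np.argmax(F > 0)) + 1  # 1-based

    # Survival-only transition matrix; N = (I - U)^-1 holds expected times.
    U = np.zeros((D, D))
    U[np.arange(1, D), np.arange(D - 1)] = S[:-1]
    U[-1, -1] = S[-1]
    N = np.linalg.inv(np.eye(D) - U)
    # Expected total years in classes >= m entering at class m.
    rle = float(N[m - 1:, m - 1].sum())

    mean_rate = float(F[m - 1:].mean())

    es = eigen_summary(A)
    Fmat = np.zeros_like(A)
    Fmat[0, :] = F
    denom = float(es.v @ (Fmat @ es.w))
    T = es.lam * float(es.v @ es.w) / denom
    return LifeHistoryStats(
        first_repro_class=m,
        repro_life_expectancy=rle,
        mean_repro_rate=mean_rate,
        generation_time=float(T),
    )


def read_matrix_csv(path: str | Path, validate: bool = True) -> np.ndarray:
    """Read a plain numeric CSV (D rows x D columns, no header)."""
    A = np.loadtxt(path, delimiter=",", ndmin=2)
    if validate:
        validate_leslie(A)
    return A


def write_matrix_csv(A: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(A, dtype=float), delimiter=",")
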