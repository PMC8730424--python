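"""Immune-strategy hazard model.

An organism's immune system is a signal detector: it must decide, from
molecular stimuli, whether the host is infected.  Sensitivity ``se`` (the
probability of responding to a genuine parasite signal) and specificity
``sp`` (the probability of ignoring a benign self signal) trade off along a
receiver-operating-characteristic curve

    se = 1 - exp(-gamma * (1 - sp)),

where ``gamma`` measures how well parasite and self signal distributions are
discriminated (larger ``gamma``: less overlap, a better detector).

A strategy then maps, together with per-age epidemiological risks, onto a
total mortality hazard per one-year age class:

    h = mu_b + (1 - ir) * mu_i * (1 - sp) + ir * mu_d * (1 - se) + ir * mu_id * se

with ``ir`` the infection probability of the class, ``mu_b`` background
mortality, ``mu_i`` immunopathology mortality of a false-positive response
in an uninfected host, ``mu_d`` mortality of an undetected infection, and
``mu_id`` mortality of a detected (fought) infection.  Survival over the
class is ``exp(-h)``.

Hazards are instantaneous rates per one-year class; ``se`` is always derived
from ``sp`` so the pair can never be inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ImmuneStrategy",
    "AgeRisk",
    "RiskSchedule",
    "sensitivity_from_specificity",
    "total_hazard",
    "hazard_profile",
    "survival_probability",
]


def sensitivity_from_specificity(sp, gamma):
    """ROC trade-off: sensitivity implied by specificity ``sp``.

    Accepts scalars or arrays of ``sp``.  Strictly decreasing in ``sp``;
    ``se(1) = 0`` and ``se(0) = 1 - exp(-gamma)``.

    Raises
    ------
    ValueError
        If any ``sp`` lies outside [0, 1] or ``gamma <= 0``.
    """
    sp = np.asarray(sp, dtype=float)
    if np.any(sp < 0) or np.any(sp > 1):
        raise ValueError(f"specificity must lie in [0, 1], got {sp!r}")
    if not np.all(np.isfinite(sp)):
        raise ValueError("specificity must be finite")
    if gamma <= 0 or not np.isfinite(gamma):
        raise ValueError(f"discrimination coefficient gamma must be > 0, got {gamma}")
    out = -np.expm1(-gamma * (1.0 - sp))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ImmuneStrategy:
    """A point on the ROC curve: specificity plus discrimination.

    Sensitivity is a derived property, never stored.
    """

    sp: float
    gamma: float

    def __post_init__(self):
        sensitivity_from_specificity(self.sp, self.gamma)  # validates

    @property
    def se(self) -> float:
        return sensitivity_from_specificity(self.sp, self.gamma)


@dataclass(frozen=True)
class AgeRisk:
    """Epidemiological and background risks of a single age class."""

    ir: float
    mu_b: float
    mu_i: float
    mu_d: float
    mu_id: float

    def __post_init__(self):
        if not 0.0 <= self.ir <= 1.0:
            raise ValueError(f"infection risk ir must lie in [0, 1], got {self.ir}")
        # mu_b may be +inf: sentinel for a terminal class pinned to zero survival
        for name in ("mu_i", "mu_d", "mu_id"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be a finite nonnegative rate, got {v}")
        if self.mu_b < 0 or np.isnan(self.mu_b):
            raise ValueError(f"mu_b must be >= 0, got {self.mu_b}")


@dataclass(frozen=True)
class RiskSchedule:
    """Per-age-class risks for a D-class demography, stored as arrays."""

    ir: np.ndarray
    mu_b: np.ndarray
    mu_i: np.ndarray
    mu_d: np.ndarray
    mu_id: np.ndarray

    def __post_init__(self):
        arrays = {}
        for name in ("ir", "mu_b", "mu_i", "mu_d", "mu_id"):
            a = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            arrays[name] = a
            object.__setattr__(self, name, a)
        D = len(arrays["ir"])
        if any(len(a) != D for a in arrays.values()):
            raise ValueError("all risk arrays must share one length")
        for x in self.per_class:  # reuses AgeRisk validation
            pass

    @classmethod
    def from_age_risks(cls, risks: Iterable[AgeRisk]) -> "RiskSchedule":
        risks = list(risks)
        return cls(
            ir=np.array([r.ir for r in risks]),
            mu_b=np.array([r.mu_b for r in risks]),
            mu_i=np.array([r.mu_i for r in risks]),
            mu_d=np.array([r.mu_d for r in risks]),
            mu_id=np.array([r.mu_id for r in risks]),
        )

    @classmethod
    def constant(cls, D: int, *, ir, mu_b, mu_i, mu_d, mu_id) -> "RiskSchedule":
        full = lambda v: np.full(D, float(v))
        return cls(full(ir), full(mu_b), full(mu_i), full(mu_d), full(mu_id))

    @property
    def per_class(self) -> list[AgeRisk]:
        return [
            AgeRisk(self.ir[i], self.mu_b[i], self.mu_i[i], self.mu_d[i], self.mu_id[i])
            for i in range(len(self))
        ]

    def __len__(self) -> int:
        return len(self.ir)

    def __getitem__(self, i: int) -> AgeRisk:
        return AgeRisk(self.ir[i], self.mu_b[i], self.mu_i[i], self.mu_d[i], self.mu_id[i])


def total_hazard(strategy: ImmuneStrategy, risk: AgeRisk) -> float:
    """Total mortality hazard of one age class under ``strategy``."""
    sp, se = strategy.sp, strategy.se
    return (
        risk.mu_b
        + (1.0 - risk.ir) * risk.mu_i * (1.0 - sp)
        + risk.ir * risk.mu_d * (1.0 - se)
        + risk.ir * risk.mu_id * se
    )


def hazard_profile(sp, gamma, schedule: RiskSchedule):
    """Vectorized hazards for specificities ``sp`` over a whole schedule.

    Parameters
    ----------
    sp : scalar or (G,) array of specificities.
    gamma : discrimination coefficient.
    schedule : RiskSchedule of length D.

    Returns
    -------
    (D,) array for scalar ``sp``, else (G, D) array.
    """
    sp_arr = np.asarray(sp, dtype=float)
    se = np.asarray(sensitivity_from_specificity(sp_arr, gamma))
    sp_c = sp_arr[..., None]
    se_c = se[..., None]
    h = (
        schedule.mu_b
        + (1.0 - schedule.ir) * schedule.mu_i * (1.0 - sp_c)
        + schedule.ir * schedule.mu_d * (1.0 - se_c)
        + schedule.ir * schedule.mu_id * se_c
    )
    return h


def survival_probability(hazard):
    """Per-class survival ``exp(-hazard)``.

    ``+inf`` is accepted as a sentinel hazard (a terminal class pinned to
    zero survival) and maps to 0.  Negative hazards are a domain error.
    """
    h = np.asarray(hazard, dtype=float)
    if np.any(h < 0) or np.any(np.isnan(h)):
        raise ValueError("hazard must be nonnegative")
    out = np.exp(-h)
    return float(out) if out.ndim == 0 else out
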