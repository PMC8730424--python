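"""Age schedules of epidemiological risk and reproduction.

Risk varies with age in one of two modes: *stepped* (one jump at
reproductive maturity, e.g. infection risk 0.6 in juvenile classes then 0.2
from the class of first reproduction onward) or *smoothed* (linear change
from the first to the last age class).  Exactly one epidemiological
parameter -- infection risk ``ir`` or undetected-infection mortality
``mu_d`` -- varies; the rest stay constant.

Five reproductive schedules contrast output level and timing: Baseline,
High and Low are constant from maturity at different levels; Rising climbs
linearly across the reproductive classes and Declining is its mirror.  The
default levels (Baseline 1.0, High 1.5, Low 0.5, Rising 0.5->1.5) keep
Rising, Declining and Baseline at the same mean output so level and shape
effects separate cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .core import RiskSchedule

__all__ = [
    "ScenarioSpec",
    "ReproSchedule",
    "REPRO_KINDS",
    "SCENARIOS",
    "stepped_schedule",
    "smoothed_schedule",
    "fertility_schedule",
    "default_repro_schedules",
    "build_risk_schedule",
    "equalize_lambda",
    "load_scenario",
    "save_scenario",
]

REPRO_KINDS = ("Baseline", "High", "Low", "Rising", "Declining")


def stepped_schedule(pre: float, post: float, maturity_class: int, D: int) -> np.ndarray:
    """``pre`` for classes < maturity_class, ``post`` from maturity onward."""
    if not 1 <= maturity_class <= D:
        raise ValueError(f"maturity_class {maturity_class} out of range 1..{D}")
    x = np.arange(1, D + 1)
    return np.where(x < maturity_class, float(pre), float(post))


def smoothed_schedule(first: float, last: float, D: int) -> np.ndarray:
    """Linear change from ``first`` (class 1) to ``last`` (class D)."""
    if D < 1:
        raise ValueError("D must be >= 1")
    if D == 1:
        return np.array([float(first)])
    return np.linspace(float(first), float(last), D)


@dataclass(frozen=True)
class ReproSchedule:
    """One of the five reproductive schedules.

    ``level`` sets the constant output of Baseline/High/Low; ``low``/``high``
    bound the linear ramp of Rising (Declining reverses it).
    """

    kind: str
    maturity_class: int = 3
    level: float = 1.0
    low: float = 0.5
    high: float = 1.5

    def __post_init__(self):
        if self.kind not in REPRO_KINDS:
            raise ValueError(f"unknown schedule kind {self.kind!r}; choose from {REPRO_KINDS}")
        if min(self.level, self.low, self.high) < 0:
            raise ValueError("fertility levels must be >= 0")
        if self.maturity_class < 1:
            raise ValueError("maturity_class must be >= 1")


def fertility_schedule(spec: ReproSchedule, D: int) -> np.ndarray:
    """Per-class fertility vector of length D; zero before maturity."""
    m = spec.maturity_class
    if m > D:
        raise ValueError(f"maturity_class {m} exceeds dimension {D}")
    n_repro = D - m + 1
    if spec.kind == "Baseline":
        seg = np.full(n_repro, spec.level)
    elif spec.kind == "High":
        seg = np.full(n_repro, spec.high)
    elif spec.kind == "Low":
        seg = np.full(n_repro, spec.low)
    elif spec.kind == "Rising":
        seg = np.linspace(spec.low, spec.high, n_repro)
    else:  # Declining: the Rising ramp reversed
        seg = np.linspace(spec.low, spec.high, n_repro)[::-1]
    return np.concatenate([np.zeros(m - 1), seg])


def default_repro_schedules(maturity_class: int = 3) -> dict[str, ReproSchedule]:
    return {k: ReproSchedule(kind=k, maturity_class=maturity_class) for k in REPRO_KINDS}


@dataclass(frozen=True)
class ScenarioSpec:
    """An epidemiological scenario: which parameter varies with age and how.

    ``varied_param`` is ``"ir"`` or ``"mu_d"``; ``mode`` is ``"stepped"``
    (jump at ``maturity_class``) or ``"smoothed"`` (linear across classes).
    ``constants`` holds the age-constant values of every other parameter
    plus ``gamma``.
    """

    name: str
    varied_param: str
    start_value: float
    end_value: float
    mode: str = "stepped"
    maturity_class: int = 3
    constants: dict = field(
        default_factory=lambda: {
            "mu_b": 0.15,
            "mu_i": 0.1,
            "mu_d": 0.3,
            "mu_id": 0.01,
            "gamma": 4.0,
        }
    )

    def __post_init__(self):
        if self.varied_param not in ("ir", "mu_d"):
            raise ValueError("varied_param must be 'ir' or 'mu_d'")
        if self.mode not in ("stepped", "smoothed"):
            raise ValueError("mode must be 'stepped' or 'smoothed'")
        needed = {"mu_b", "mu_i", "mu_id", "gamma"}
        needed.add("ir" if self.varied_param == "mu_d" else "mu_d")
        missing = needed - set(self.constants)
        if missing:
            raise ValueError(f"scenario constants missing {sorted(missing)}")

    @property
    def gamma(self) -> float:
        return float(self.constants["gamma"])

    def with_mode(self, mode: str) -> "ScenarioSpec":
        return replace(self, mode=mode)


def _preset(name, start, end, varied="ir"):
    constants = {"mu_b": 0.15, "mu_i": 0.1, "mu_id": 0.01, "gamma": 4.0}
    if varied == "ir":
        constants["mu_d"] = 0.3
    else:
        constants["ir"] = 0.4
    return ScenarioSpec(
        name=name, varied_param=varied, start_value=start, end_value=end, constants=constants
    )


# Named scenario presets.  Set A contrasts the direction of the risk change
# (falling vs rising at maturity); set B contrasts its level and magnitude.
# *_mud variants move mu_d over the same intervals with ir fixed at 0.4.
_PAIRS = {
    "A1": (0.6, 0.2),
    "A2": (0.2, 0.6),
    "B1": (0.45, 0.2),
    "B2": (0.7, 0.45),
    "B3": (0.7, 0.2),
    "B4": (0.525, 0.375),
}
SCENARIOS: dict[str, ScenarioSpec] = {}
for _name, (_s, _e) in _PAIRS.items():
    SCENARIOS[_name] = _preset(_name, _s, _e, "ir")
    SCENARIOS[_name + "_mud"] = _preset(_name + "_mud", _s, _e, "mu_d")


def build_risk_schedule(
    scenario: ScenarioSpec,
    D: int,
    maturity_class: int | None = None,
    mu_b: np.ndarray | float | None = None,
) -> RiskSchedule:
    """Materialize a scenario as a per-class :class:`RiskSchedule`.

    ``mu_b`` overrides the scenario's constant background mortality, either
    as a scalar or per class (the projection-matrix pipeline passes the
    mortality-decomposition vector here).
    """
    m = scenario.maturity_class if maturity_class is None else maturity_class
    if scenario.mode == "stepped":
        varied = stepped_schedule(scenario.start_value, scenario.end_value, min(m, D), D)
    else:
        varied = smoothed_schedule(scenario.start_value, scenario.end_value, D)
    c = scenario.constants
    values = {
        "mu_i": np.full(D, float(c["mu_i"])),
        "mu_id": np.full(D, float(c["mu_id"])),
    }
    if scenario.varied_param == "ir":
        values["ir"] = varied
        values["mu_d"] = np.full(D, float(c["mu_d"]))
    else:
        values["mu_d"] = varied
        values["ir"] = np.full(D, float(c["ir"]))
    if mu_b is None:
        mu_b = float(c["mu_b"])
    values["mu_b"] = np.broadcast_to(np.asarray(mu_b, dtype=float), (D,)).copy()
    return RiskSchedule(**values)


def equalize_lambda(
    fertility: np.ndarray,
    risk: RiskSchedule,
    gamma: float,
    target_lam: float,
    step: float = 0.001,
    mu_b_max: float = 20.0,
    tol: float = 1e-4,
    check_primitive: bool = True,
) -> float:
    """Uniform background mortality giving optimized growth rate ``target_lam``.

    Replaces ``risk.mu_b`` by a single trial value in every class (classes
    whose ``mu_b`` is ``+inf`` stay pinned: they encode zero terminal
    survival), re-optimizes specificity at each trial, and bisects on the
    strictly decreasing map mu_b -> lambda_opt until
    ``|lambda_opt - target_lam| <= tol``.
    """
    from .optimizer import optimize_strategy  # deferred: optimizer builds on schedules

    import scipy.optimize

    pinned = ~np.isfinite(risk.mu_b)

    def lam_opt(mu_b: float) -> float:
        mb = np.where(pinned, np.inf, float(mu_b))
        trial = RiskSchedule(risk.ir, mb, risk.mu_i, risk.mu_d, risk.mu_id)
        return optimize_strategy(
            fertility, trial, gamma, step=step, check_primitive=check_primitive
        ).lam_max

    f = lambda mu: lam_opt(mu) - target_lam
    lo, hi = 0.0, 1.0
    f_lo = f(lo)
    if abs(f_lo) <= tol:
        return lo
    if f_lo < 0:
        raise ValueError(
            f"target lambda {target_lam} unreachable: even mu_b=0 gives a smaller lambda"
        )
    f_hi = f(hi)
    while f_hi > 0:
        hi *= 2.0
        if hi > mu_b_max:
            raise ValueError(f"no bracket below mu_b={mu_b_max} for target lambda {target_lam}")
        f_hi = f(hi)
    root = scipy.optimize.brentq(f, lo, hi, xtol=1e-8)
    if abs(f(root)) > tol:
        raise RuntimeError("bisection failed to reach the lambda tolerance")
    return float(root)


def save_scenario(scenario: ScenarioSpec, path: str | Path) -> None:
    data = {
        "name": scenario.name,
        "varied_param": scenario.varied_param,
        "mode": scenario.mode,
        "start_value": scenario.start_value,
        "end_value": scenario.end_value,
        "maturity_class": scenario.maturity_class,
        "constants": {k: float(v) for k, v in scenario.constants.items()},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_scenario(path: str | Path) -> ScenarioSpec:
    """Load a scenario config (YAML mapping mirroring :class:`ScenarioSpec`)."""
    data = yaml.safe_load(Path(path).read_text())
    return ScenarioSpec(
        name=str(data.get("name", Path(path).stem)),
        varied_param=data["varied_param"],
        start_value=float(data["start_value"]),
        end_value=float(data["end_value"]),
        mode=data.get("mode", "stepped"),
        maturity_class=int(data.get("maturity_class", 3)),
        constants={k: float(v) for k, v in data["constants"].items()},
    )
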