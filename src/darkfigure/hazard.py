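"""Deterministic hazard recurrence at the heart of the desistance model.

An offender's offending in year ``i`` is Poisson with mean ``lambda_i``.
The annual probability of at least one offense is ``p_i = 1 - exp(-lambda_i)``
and the corresponding odds are ``p_i / (1 - p_i) = exp(lambda_i) - 1``.
Desistance is modelled as a fixed proportional decrease ``d`` in those odds
each year: the year ``i+1`` Poisson mean is the unique value whose odds equal
``(1 - d)`` times the year ``i`` odds,

    lambda_{i+1} = ln(1 + (1 - d) * (exp(lambda_i) - 1)).

With the headline desistance rate d = 0.123 the retention factor is 0.877.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DesistanceSchedule",
    "HazardTrajectory",
    "next_lambda",
    "prob_reoffense",
    "odds_reoffense",
    "trajectory",
]


@dataclass(frozen=True)
class DesistanceSchedule:
    """Annual proportional decrease ``d`` in the odds of reoffending.

    Parameters
    ----------
    d : float
        Fraction by which the odds of reoffending shrink each year,
        in [0, 1].  ``d = 0.123`` is the headline empirical estimate;
        ``d = 0`` is the constant-hazard limiting case.
    """

    d: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.d) or not 0.0 <= self.d <= 1.0:
            raise ValueError(f"desistance rate d must be in [0, 1], got {self.d!r}")

    @property
    def retention(self) -> float:
        """Annual odds retention factor ``1 - d`` (0.877 for d = 0.123)."""
        return 1.0 - self.d


@dataclass(frozen=True)
class HazardTrajectory:
    """Per-year Poisson means with derived annual probabilities and odds."""

    lambdas: np.ndarray
    probs: np.ndarray = field(init=False)
    odds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "probs", -np.expm1(-lam))
        object.__setattr__(self, "odds", np.expm1(lam))

    def __len__(self) -> int:
        return len(self.lambdas)


def _check_lambda(lam: float) -> float:
    lam = float(lam)
    if not np.isfinite(lam) or lam < 0.0:
        raise ValueError(f"Poisson mean must be finite and >= 0, got {lam!r}")
    return lam


def next_lambda(lambda_i, schedule: DesistanceSchedule):
    """Advance the Poisson mean one year down the desistance schedule.

    Evaluates ``ln(1 + (1 - d) * expm1(lambda_i))`` — the numerically stable
    form of the odds-decrement recurrence; ``expm1``/``log1p`` keep full
    precision for the tiny hazards typical of calibrated populations.
    Accepts scalars or arrays.
    """
    lam = np.asarray(lambda_i, dtype=float)
    if lam.ndim == 0:
        _check_lambda(float(lam))
    elif not (np.all(np.isfinite(lam)) and np.all(lam >= 0.0)):
        raise ValueError("all Poisson means must be finite and >= 0")
    out = np.log1p(schedule.retention * np.expm1(lam))
    return float(out) if np.ndim(lambda_i) == 0 else out


def prob_reoffense(lam):
    """Annual probability of >= 1 offense, ``1 - exp(-lambda)``."""
    arr = np.asarray(lam, dtype=float)
    if np.ndim(lam) == 0:
        _check_lambda(float(arr))
    elif not (np.all(np.isfinite(arr)) and np.all(arr >= 0.0)):
        raise ValueError("all Poisson means must be finite and >= 0")
    out = -np.expm1(-arr)
    return float(out) if np.ndim(lam) == 0 else out


def odds_reoffense(lam):
    """Annual odds of reoffending, ``exp(lambda) - 1 = p / (1 - p)``."""
    arr = np.asarray(lam, dtype=float)
    if np.ndim(lam) == 0:
        _check_lambda(float(arr))
    elif not (np.all(np.isfinite(arr)) and np.all(arr >= 0.0)):
        raise ValueError("all Poisson means must be finite and >= 0")
    out = np.expm1(arr)
    return float(out) if np.ndim(lam) == 0 else out


def trajectory(lambda_1, schedule: DesistanceSchedule, T: int) -> HazardTrajectory:
    """Full ``T``-year hazard trajectory starting from ``lambda_1``.

    Years are indexed 1..T; ``lambda_1`` applies to year 1 and each
    successor comes from :func:`next_lambda`.
    """
    if int(T) != T or T < 1:
        raise ValueError(f"horizon T must be an integer >= 1, got {T!r}")
    lam = _check_lambda(lambda_1)
    lams = np.empty(int(T))
    lams[0] = lam
    for i in range(1, int(T)):
        lams[i] = next_lambda(lams[i - 1], schedule)
    return HazardTrajectory(lambdas=lams)


def trajectory_matrix(lambda_1: np.ndarray, schedule: DesistanceSchedule, T: int) -> np.ndarray:
    """Vectorized trajectories: shape ``(n, T)`` for ``n`` starting means.

    Used by the Monte Carlo and quadrature engines, which need the hazard
    path for thousands of offenders or integration nodes at once.
    """
    lam0 = np.asarray(lambda_1, dtype=float)
    if not (np.all(np.isfinite(lam0)) and np.all(lam0 >= 0.0)):
        raise ValueError("all starting Poisson means must be finite and >= 0")
    if int(T) != T or T < 1:
        raise ValueError(f"horizon T must be an integer >= 1, got {T!r}")
    out = np.empty((lam0.size, int(T)))
    out[:, 0] = lam0.ravel()
    for i in range(1, int(T)):
        out[:, i] = np.log1p(schedule.retention * np.expm1(out[:, i - 1]))
    return out
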