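"""Scenario parameterization and rate-estimate containers shared by engines."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .hazard import DesistanceSchedule

DEFAULT_HORIZON = 25
DEFAULT_CHECKPOINTS = (5, 10, 15, 20, 25)
DEFAULT_ITERATIONS = 30_000
DEFAULT_SEED = 20250122


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterization of one simulated offender population.

    Parameters
    ----------
    mu : float
        Mean of the Exponential population distribution of the year-1
        Poisson mean ``lambda_1`` (expected offenses/year).
    r : float
        Per-offense probability that an offense results in a charge,
        in [0, 1] (the Binomial thinning probability).
    schedule : DesistanceSchedule
        Annual odds-decrement schedule.
    T : int
        Simulation horizon in years.
    checkpoints : tuple of int
        Years at which cumulative rates are reported; strictly increasing,
        all within 1..T.
    n_iterations : int
        Monte Carlo trial count.
    seed : int
        RNG seed; identical specs give bit-identical results.
    """

    mu: float
    r: float
    schedule: DesistanceSchedule = field(default_factory=lambda: DesistanceSchedule(0.123))
    T: int = DEFAULT_HORIZON
    checkpoints: tuple = DEFAULT_CHECKPOINTS
    n_iterations: int = DEFAULT_ITERATIONS
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"population mean mu must be > 0, got {self.mu!r}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"charge rate r must be in [0, 1], got {self.r!r}")
        if int(self.T) != self.T or self.T < 1:
            raise ValueError(f"horizon T must be an integer >= 1, got {self.T!r}")
        cps = tuple(int(c) for c in self.checkpoints)
        object.__setattr__(self, "checkpoints", cps)
        if not cps or any(c < 1 or c > self.T for c in cps):
            raise ValueError(f"checkpoints must lie in 1..{self.T}, got {cps}")
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError(f"checkpoints must be strictly increasing, got {cps}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"] = {"d": self.schedule.d}
        d["checkpoints"] = list(self.checkpoints)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioSpec":
        data = dict(data)
        sched = data.pop("schedule", None)
        if isinstance(sched, dict):
            data["schedule"] = DesistanceSchedule(float(sched["d"]))
        elif sched is not None:
            data["schedule"] = DesistanceSchedule(float(sched))
        if "checkpoints" in data:
            data["checkpoints"] = tuple(data["checkpoints"])
        return cls(**data)


@dataclass(frozen=True)
class TrialOutcome:
    """First-event record for one simulated offender."""

    first_offense_year: Optional[int]
    first_charge_year: Optional[int]

    def __post_init__(self) -> None:
        if self.first_charge_year is not None:
            if self.first_offense_year is None or self.first_charge_year < self.first_offense_year:
                raise ValueError("a charge requires an offense in the same or an earlier year")


@dataclass(frozen=True)
class RateEstimates:
    """Cumulative actual and charged reoffending proportions at checkpoints.

    All rates are proportions in [0, 1]; formatting to percentages happens
    only in the presentation layer.  ``method`` is ``"monte_carlo"`` or
    ``"analytic"``; analytic estimates carry zero standard errors.
    """

    checkpoints: tuple
    actual_rate: np.ndarray
    charged_rate: np.ndarray
    actual_se: np.ndarray
    charged_se: np.ndarray
    method: str
    n_iterations: int

    def actual_at(self, year: int) -> float:
        return float(self.actual_rate[self.checkpoints.index(year)])

    def charged_at(self, year: int) -> float:
        return float(self.charged_rate[self.checkpoints.index(year)])

    def to_dict(self) -> dict:
        return {
            "checkpoints": list(self.checkpoints),
            "actual_rate": [float(x) for x in self.actual_rate],
            "charged_rate": [float(x) for x in self.charged_rate],
            "actual_se": [float(x) for x in self.actual_se],
            "charged_se": [float(x) for x in self.charged_se],
            "method": self.method,
            "n_iterations": int(self.n_iterations),
        }
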