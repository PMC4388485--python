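"""Drift-diffusion evidence accumulation and bound crossing.

The decision variable ``z`` starts at 0 and accumulates Gaussian increments
``dz ~ N(mu, sigma^2)`` at discrete steps of ``dt`` seconds until it crosses
one of two symmetric bounds at ``z = +/- b``.  The upper bound corresponds to
the correct choice (drift is oriented toward it); the lower bound to an error.
This module is the purely cognitive layer shared by every model, and is a
complete model on its own: the no-action baseline responds instantaneously at
bound crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "EvidenceParams",
    "EvidenceState",
    "Bound",
    "BoundStatus",
    "accumulate_step",
    "bound_status",
    "run_baseline_trial",
    "StepCapExceeded",
    "DEFAULT_STEP_CAP",
]

#: Hard cap on accumulation steps; guards non-terminating configurations.
DEFAULT_STEP_CAP = 10**6


class StepCapExceeded(RuntimeError):
    """Raised when a trial fails to terminate within the step cap."""


@dataclass(frozen=True)
class EvidenceParams:
    """Parameters of the discrete-time accumulator.

    Attributes
    ----------
    drift_mu : float
        Mean evidence increment per step (dimensionless).  Positive drift
        points toward the correct (upper) bound.
    noise_sigma : float
        Standard deviation of the increment per step; ``0`` is legal and
        yields deterministic linear accumulation.
    dt : float
        Duration of one step in seconds.
    """

    drift_mu: float = 1.0 / 3.0
    noise_sigma: float = 1.0
    dt: float = 0.05

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")

    @classmethod
    def from_rates(
        cls, mu_rate: float = 1.0 / 3.0, sigma_rate: float = 1.0, dt: float = 0.05
    ) -> "EvidenceParams":
        """Diffusion discretization: per-step increment ``N(mu*dt, sigma^2*dt)``.

        ``mu_rate`` is the drift in evidence units per second and
        ``sigma_rate`` the diffusion coefficient per sqrt-second — the usual
        continuous-time parameterization of the accumulator.  This is the
        study configuration used throughout the model comparisons; the plain
        constructor keeps per-step semantics for direct control of the
        discrete walk.
        """
        return cls(
            drift_mu=mu_rate * dt,
            noise_sigma=sigma_rate * dt**0.5,
            dt=dt,
        )


@dataclass(frozen=True)
class EvidenceState:
    """Accumulator state: evidence ``z`` at elapsed time ``t = step_index * dt``."""

    z: float = 0.0
    t: float = 0.0
    step_index: int = 0


@dataclass(frozen=True)
class Bound:
    """Symmetric decision bounds at ``z = +/- b``."""

    b: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"bound b must be positive, got {self.b}")


class BoundStatus(Enum):
    UPPER_CROSSED = "upper_crossed"
    LOWER_CROSSED = "lower_crossed"
    UNDECIDED = "undecided"


def accumulate_step(
    state: EvidenceState, params: EvidenceParams, rng: np.random.Generator
) -> EvidenceState:
    """Advance the accumulator by one step.

    Draws ``dz ~ N(drift_mu, noise_sigma^2)`` from ``rng`` and returns a new
    state; the input state is unmodified.  Time advances by exactly ``dt``
    via the step index, so ``t == step_index * dt`` holds without float drift.
    """
    dz = rng.normal(params.drift_mu, params.noise_sigma)
    k = state.step_index + 1
    return replace(state, z=state.z + dz, t=k * params.dt, step_index=k)


def bound_status(z: float, b: Bound) -> BoundStatus:
    """Classify evidence relative to the symmetric bounds.

    Crossing is inclusive (``z >= b`` counts as crossed) so that zero-noise
    configurations terminate at exact multiples of ``dt``.  The upper bound
    takes precedence, which only matters in impossible degenerate inputs.
    """
    if z >= b.b:
        return BoundStatus.UPPER_CROSSED
    if z <= -b.b:
        return BoundStatus.LOWER_CROSSED
    return BoundStatus.UNDECIDED


def run_baseline_trial(
    params: EvidenceParams,
    b: Bound,
    rng: np.random.Generator,
    step_cap: int = DEFAULT_STEP_CAP,
) -> tuple[bool, float]:
    """Run one no-action trial: accumulate until a bound is crossed.

    Returns ``(correct, rt)`` where ``correct`` is True for an upper-bound
    crossing and ``rt`` is the first-crossing time in seconds.  The decision
    is checked after every increment; there is no within-step interpolation
    of the crossing time, matching the discrete formulation.
    """
    state = EvidenceState()
    for _ in range(step_cap):
        state = accumulate_step(state, params, rng)
        status = bound_status(state.z, b)
        if status is not BoundStatus.UNDECIDED:
            return status is BoundStatus.UPPER_CROSSED, state.t
    raise StepCapExceeded(
        f"no bound crossing within {step_cap} steps (b={b.b}, mu={params.drift_mu})"
    )
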