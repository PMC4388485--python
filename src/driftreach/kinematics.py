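"""Arena geometry, action-focus functions, movement update and commitment.

The agent moves at constant speed in a 2D arena from a start point toward an
*action focus* — the point the action system currently steers at.  The four
models differ only in how the focus is derived from the decision variable:

* serial (Model 1): focus frozen on the chosen target at decision time;
* switching (Model 2): focus tracks the last bound crossed (changes of mind);
* interpolated (Models 3/4): focus slides along the inter-target segment in
  proportion to the current evidence, clamped to a target beyond the bounds.

Commitment (Model 4) feeds position back into the decision: proximity to a
target adds effective evidence for that target, scaled by a gain ``g``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .evidence import Bound

__all__ = [
    "TaskGeometry",
    "AgentPosition",
    "FocusPoint",
    "CommitmentSpec",
    "move_step",
    "focus_serial",
    "focus_switching",
    "focus_interpolated",
    "commitment_term",
    "effective_evidence",
]

Point = tuple[float, float]


@dataclass(frozen=True)
class TaskGeometry:
    """The 2AFC arena: start, two targets, movement speed and clock.

    Defaults are the standard task: start at the origin, targets at
    ``(-1, 1.5)`` and ``(+1, 1.5)``, speed ``v = 2`` arena units/s, step
    50 ms.  The straight-line travel time to either target is then
    ``sqrt(3.25)/2 ~= 0.9014 s``.
    """

    start: Point = (0.0, 0.0)
    target1: Point = (-1.0, 1.5)
    target2: Point = (1.0, 1.5)
    speed_v: float = 2.0
    dt: float = 0.05

    def __post_init__(self) -> None:
        if self.speed_v <= 0 or self.dt <= 0:
            raise ValueError("speed_v and dt must be positive")

    @property
    def travel_time(self) -> float:
        """Straight-line time from start to target 1 (s)."""
        return _dist(self.start, self.target1) / self.speed_v


@dataclass(frozen=True)
class AgentPosition:
    pos: Point = (0.0, 0.0)


@dataclass(frozen=True)
class FocusPoint:
    """Current steering point; undefined before any decision in Models 1-2."""

    focus: Point = (0.0, 0.0)
    defined: bool = True

    #: sentinel for "no choice yet: the agent cannot move"
    @staticmethod
    def undefined() -> "FocusPoint":
        return FocusPoint((math.nan, math.nan), defined=False)


@dataclass(frozen=True)
class CommitmentSpec:
    """Commitment gain ``g`` (evidence units); the default rule is g = 4b."""

    gain_g: float

    def __post_init__(self) -> None:
        if self.gain_g < 0:
            raise ValueError(f"gain_g must be >= 0, got {self.gain_g}")

    @classmethod
    def from_bound(cls, b: Bound, factor: float = 4.0) -> "CommitmentSpec":
        return cls(gain_g=factor * b.b)


def _dist(p: Point, q: Point) -> float:
    # plain sqrt rather than hypot: bitwise-identical to the vectorized
    # engine's arithmetic (overflow is not a concern at arena scale)
    dx, dy = p[0] - q[0], p[1] - q[1]
    return math.sqrt(dx * dx + dy * dy)


def move_step(pos: AgentPosition, focus: FocusPoint, geom: TaskGeometry) -> AgentPosition:
    """Move one step of length ``v*dt`` from ``pos`` toward ``focus``.

    The step is shortened to land exactly on the focus when it is within
    reach; a position already at the focus stays put.
    """
    if not focus.defined:
        raise ValueError("cannot move toward an undefined focus")
    d = _dist(pos.pos, focus.focus)
    step = geom.speed_v * geom.dt
    if d <= step:
        return AgentPosition(focus.focus)
    f = step / d
    x, y = pos.pos
    fx, fy = focus.focus
    return AgentPosition((x + f * (fx - x), y + f * (fy - y)))


def focus_serial(
    z_at_decision: float, decided: bool, b: Bound, geom: TaskGeometry
) -> FocusPoint:
    """Model 1 focus: undefined pre-decision, then frozen on the chosen target."""
    if not decided:
        return FocusPoint.undefined()
    if z_at_decision >= b.b:
        return FocusPoint(geom.target1)
    if z_at_decision <= -b.b:
        return FocusPoint(geom.target2)
    raise ValueError("decided=True requires |z_at_decision| >= b")


def focus_switching(
    z: float, current_focus: FocusPoint, b: Bound, geom: TaskGeometry
) -> FocusPoint:
    """Model 2 focus: tracks the last bound crossed; holds between bounds.

    Undefined until the first crossing ("the agent cannot move"); thereafter
    the agent keeps heading toward the last-instructed target until the
    opposing bound is crossed — the change-of-mind mechanism.
    """
    if z >= b.b:
        return FocusPoint(geom.target1)
    if z <= -b.b:
        return FocusPoint(geom.target2)
    return current_focus


def focus_interpolated(z_eff: float, b: Bound, geom: TaskGeometry) -> FocusPoint:
    """Models 3/4 focus: linear interpolation along the inter-target segment.

    focus = [(b + z) * target1 + (b - z) * target2] / (2b) for |z| <= b,
    clamped to target1 for z >= b and target2 for z <= -b.  Always defined,
    so movement starts at time zero.
    """
    bb = b.b
    if z_eff >= bb:
        return FocusPoint(geom.target1)
    if z_eff <= -bb:
        return FocusPoint(geom.target2)
    w1 = (bb + z_eff) / (2.0 * bb)
    w2 = 1.0 - w1
    x1, y1 = geom.target1
    x2, y2 = geom.target2
    return FocusPoint((w1 * x1 + w2 * x2, w1 * y1 + w2 * y2))


def commitment_term(
    pos: AgentPosition, geom: TaskGeometry, spec: CommitmentSpec
) -> float:
    """Position-dependent evidence: ``g * (d2 - d1) / (d1 + d2)``.

    ``d1``/``d2`` are Euclidean distances to the targets.  Proximity to
    target 1 adds positive effective evidence (toward target 1's bound), so
    an approach in progress is self-reinforcing.  Bounded in ``[-g, +g]``;
    zero on the perpendicular bisector of the targets.
    """
    d1 = _dist(pos.pos, geom.target1)
    d2 = _dist(pos.pos, geom.target2)
    return spec.gain_g * (d2 - d1) / (d1 + d2)


def effective_evidence(
    z: float,
    pos: AgentPosition,
    geom: TaskGeometry,
    commitment: CommitmentSpec | None,
) -> float:
    """Evidence the focus computation sees.

    Without commitment this is the raw accumulator ``z``.  With commitment
    (Model 4) the positional term is *added on read*, never folded back into
    the accumulator: removing the agent from the arena recovers ``z`` exactly.
    """
    if commitment is None:
        return z
    return z + commitment_term(pos, geom, commitment)
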