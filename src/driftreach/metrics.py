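"""Trajectory analytics: deviation area, mean trajectory, approach angles.

All metrics reparameterize a trajectory by its height ``y``, which is valid
because every focus lies on the inter-target line and movement never has a
negative vertical component, so ``y`` is non-decreasing along any trial.
Stationary phases (and the terminal slide along the target line) produce
duplicate ``y`` samples; these are collapsed to the *last* sample at each
height so that ``x(y)`` is single-valued.

The mean trajectory is the per-height average of ``x`` over a common
``y``-grid — an average "computed parallel to the x-axis", not the usual
mouse-tracking time normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .engine import TrialResult
from .kinematics import TaskGeometry

__all__ = [
    "MeanTrajectory",
    "TrajectoryMetrics",
    "trajectory_area",
    "mean_trajectory",
    "angle_from_vertical",
    "auc_curvature",
    "default_y_grid",
]


@dataclass(frozen=True)
class MeanTrajectory:
    """Per-height mean path: ``mean_x[j]`` is the average ``x`` at ``y_grid[j]``."""

    y_grid: np.ndarray
    mean_x: np.ndarray
    n_trajectories: int


@dataclass(frozen=True)
class TrajectoryMetrics:
    area_to_target_line: float
    initial_angle_deg: float
    final_angle_deg: float
    auc_curvature: float


def default_y_grid(geom: TaskGeometry | None = None, n: int = 101) -> np.ndarray:
    """Uniform grid spanning start height to target height (default 101 points)."""
    if geom is None:
        geom = TaskGeometry()
    return np.linspace(geom.start[1], geom.target1[1], n)


def _raw_monotone(traj) -> tuple[np.ndarray, np.ndarray]:
    """Raw samples, validated non-decreasing in y.

    Area integrals run directly on these: segments at constant height (the
    stationary start, the terminal slide along the target line) have dy = 0
    and correctly contribute nothing to an integral over y.
    """
    y = np.asarray(traj.y, dtype=float)
    x = np.asarray(traj.x, dtype=float)
    if np.any(np.diff(y) < -1e-12):
        raise ValueError("trajectory y must be non-decreasing")
    return y, x


def _xy_by_height(traj) -> tuple[np.ndarray, np.ndarray]:
    """Collapse duplicate-y samples (keeping the last) -> single-valued x(y).

    Used for per-height interpolation: the mean trajectory must be a
    function of y, and keeping the last sample makes it end on the target
    the way the plotted average paths do.
    """
    y, x = _raw_monotone(traj)
    keep = np.r_[y[1:] != y[:-1], True]
    return y[keep], x[keep]


def _chosen_target(result: TrialResult, geom: TaskGeometry):
    tgt = geom.target1 if result.choice == "target1" else geom.target2
    traj = result.trajectory
    if traj is None:
        raise ValueError("trial has no stored trajectory")
    if abs(traj.x[-1] - tgt[0]) > 1e-9 or abs(traj.y[-1] - tgt[1]) > 1e-9:
        raise ValueError("trajectory does not terminate at a target")
    return tgt, traj


def trajectory_area(result: TrialResult, geom: TaskGeometry | None = None) -> float:
    """Area between the path and the vertical line through the chosen target.

    ``integral |x(y) - x_target| dy`` over the full height range, by
    trapezoidal integration on the native samples.  Larger areas mean the
    path deviated more from heading straight down the target line.
    """
    if geom is None:
        geom = TaskGeometry()
    tgt, traj = _chosen_target(result, geom)
    y, x = _raw_monotone(traj)
    return float(np.trapezoid(np.abs(x - tgt[0]), y))


def mean_trajectory(
    results: Sequence[TrialResult],
    y_grid: np.ndarray | None = None,
    geom: TaskGeometry | None = None,
) -> MeanTrajectory:
    """Average ``x`` at each grid height over trials ending at a common target."""
    if geom is None:
        geom = TaskGeometry()
    if y_grid is None:
        y_grid = default_y_grid(geom)
    if not results:
        raise ValueError("no trajectories supplied")
    targets = {r.choice for r in results}
    if len(targets) != 1:
        raise ValueError(f"mixed end targets {sorted(targets)}; select one side first")
    acc = np.zeros_like(y_grid, dtype=float)
    for r in results:
        tgt, traj = _chosen_target(r, geom)
        y, x = _xy_by_height(traj)
        acc += np.interp(y_grid, y, x)
    return MeanTrajectory(
        y_grid=np.asarray(y_grid, float),
        mean_x=acc / len(results),
        n_trajectories=len(results),
    )


def angle_from_vertical(
    mt: MeanTrajectory,
    segment: Literal["initial", "final"] = "initial",
    fraction: float = 0.1,
) -> float:
    """Angle (degrees) of the mean path from vertical over an end segment.

    A straight line is least-squares fitted (x on y) over the first or last
    ``fraction`` of the height range; the returned angle is
    ``arctan(|dx/dy|)`` in degrees, 0 = vertical, 90 = horizontal.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    y, x = mt.y_grid, mt.mean_x
    y0, y1 = y[0], y[-1]
    span = (y1 - y0) * fraction
    mask = y <= y0 + span if segment == "initial" else y >= y1 - span
    if mask.sum() < 2:
        raise ValueError("fewer than 2 grid points in the requested segment")
    slope = np.polyfit(y[mask], x[mask], 1)[0]
    return float(np.degrees(np.arctan(abs(slope))))


def auc_curvature(result: TrialResult, geom: TaskGeometry | None = None) -> float:
    """Area between the path and the straight chord joining its endpoints.

    The standard mouse-tracking "area under the curve": both path and chord
    are parameterized by height and ``integral |x(y) - x_chord(y)| dy`` is
    taken; a straight-line trial scores exactly zero.
    """
    if geom is None:
        geom = TaskGeometry()
    _, traj = _chosen_target(result, geom)
    y, x = _raw_monotone(traj)
    x_chord = np.interp(y, [y[0], y[-1]], [x[0], x[-1]])
    return float(np.trapezoid(np.abs(x - x_chord), y))


def summarize_trajectories(
    results: Sequence[TrialResult],
    geom: TaskGeometry | None = None,
    initial_fraction: float = 0.2,
    final_fraction: float = 0.02,
) -> TrajectoryMetrics:
    """Headline metrics of a set of same-target trials.

    Areas are averaged per trajectory (not taken on the mean path); angles
    are read off the mean trajectory.  The default windows operationalize
    the two descriptors: the *initial* heading is fitted over the first
    fifth of the rise (after movement onset but before the paths commit),
    while the *final approach* is the terminal secant of the mean path — a
    2% window, i.e. its last grid segment — which captures a horizontal
    slide along the target line that any longer window dilutes.  On a
    straight path both windows give the same angle.
    """
    if geom is None:
        geom = TaskGeometry()
    areas = [trajectory_area(r, geom) for r in results]
    aucs = [auc_curvature(r, geom) for r in results]
    mt = mean_trajectory(results, geom=geom)
    return TrajectoryMetrics(
        area_to_target_line=float(np.mean(areas)),
        initial_angle_deg=angle_from_vertical(mt, "initial", initial_fraction),
        final_angle_deg=angle_from_vertical(mt, "final", final_fraction),
        auc_curvature=float(np.mean(aucs)),
    )
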