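"""Per-trial simulation loop coupling evidence to action, and batch execution.

Step semantics
--------------
Each iteration ``k`` covers the wall-clock interval ``[(k-1)*dt, k*dt]``:

1. *movement phase* — the agent moves toward the focus that was current at
   the end of the previous iteration (models with action only).  If that
   focus is a target within one step's reach, the step is shortened to land
   exactly and the trial terminates with ``rt = (k-1)*dt + remaining/v``.
2. *evidence phase* — the increment received by time ``k*dt`` is added to
   ``z``; the baseline model terminates here on bound crossing.
3. *focus phase* — the effective evidence (raw ``z``, plus the positional
   commitment term under Model 4) updates the focus per the model's rule.

Movement therefore lags the evidence stream by one step, which makes
Model 1's response time exactly the baseline first-crossing time plus the
straight-line travel time to a target.

Reproducibility: trial ``i`` of a batch draws from the dedicated substream
seeded by ``(master_seed, i)``, so results are independent of execution
order and of how a batch is split.  ``run_batch`` is a vectorized
implementation of the same loop and agrees bitwise with ``run_trial`` on
shared substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .evidence import (
    DEFAULT_STEP_CAP,
    Bound,
    EvidenceParams,
    StepCapExceeded,
)
from .kinematics import (
    AgentPosition,
    CommitmentSpec,
    FocusPoint,
    TaskGeometry,
    commitment_term,
    focus_interpolated,
)

__all__ = [
    "ModelId",
    "ModelSpec",
    "Trajectory",
    "TrialResult",
    "BatchSummary",
    "run_trial",
    "run_batch",
    "select_trajectories",
    "trial_rng",
]

ModelId = Literal["baseline", "m1", "m2", "m3", "m4"]

_MODEL_IDS = ("baseline", "m1", "m2", "m3", "m4")


@dataclass(frozen=True)
class ModelSpec:
    """Complete configuration of one decision-action architecture.

    ``commitment`` is only consulted by Model 4; when left ``None`` for m4
    the default gain rule ``g = 4b`` is applied.  A single clock drives both
    the accumulator and the arena, so ``evidence.dt`` must equal
    ``geometry.dt``.
    """

    model_id: ModelId
    bound: Bound
    evidence: EvidenceParams = field(default_factory=EvidenceParams.from_rates)
    geometry: TaskGeometry = field(default_factory=TaskGeometry)
    commitment: CommitmentSpec | None = None
    step_cap: int = DEFAULT_STEP_CAP

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.evidence.dt != self.geometry.dt:
            raise ValueError(
                "evidence.dt and geometry.dt must agree "
                f"({self.evidence.dt} != {self.geometry.dt})"
            )
        if self.model_id == "m4" and self.commitment is None:
            object.__setattr__(
                self, "commitment", CommitmentSpec.from_bound(self.bound)
            )

    @property
    def gain_g(self) -> float:
        return self.commitment.gain_g if self.commitment is not None else 0.0


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped samples (t, x, y, z, z_eff); the first row is t = 0."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    z_eff: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class TrialResult:
    choice: Literal["target1", "target2"]
    correct: bool
    rt: float
    t_dec: float
    n_focus_switches: int
    trajectory: Trajectory | None = None


@dataclass(frozen=True)
class BatchSummary:
    n_trials: int
    mean_rt: float
    mean_error: float
    seed: int


def trial_rng(master_seed: int, trial_index: int) -> np.random.Generator:
    """The dedicated random stream of trial ``trial_index``."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, trial_index)))


def _focus_side(fx: float, midline_x: float) -> int:
    if fx < midline_x:
        return -1
    if fx > midline_x:
        return 1
    return 0


def run_trial(
    spec: ModelSpec,
    rng: np.random.Generator,
    script: Sequence[float] | None = None,
    keep_trajectory: bool = True,
) -> TrialResult:
    """Run a single trial (scalar reference implementation).

    ``script``, when given, replaces the stochastic evidence increments with
    a fixed sequence (one value per step) for deterministic tests; the trial
    errors out if the script is exhausted before termination.
    """
    ev, geom, b = spec.evidence, spec.geometry, spec.bound
    model = spec.model_id
    v = geom.speed_v
    midline_x = 0.5 * (geom.target1[0] + geom.target2[0])

    z = 0.0
    pos = AgentPosition(geom.start)
    commit = spec.commitment if model == "m4" else None
    z_eff = z + (commitment_term(pos, geom, commit) if commit else 0.0)
    if model in ("m3", "m4"):
        focus = focus_interpolated(z_eff, b, geom)
    else:
        focus = FocusPoint.undefined()
    focus_is_target = model in ("m3", "m4") and abs(z_eff) >= b.b
    decided = False
    t_dec = np.nan
    side_prev = _focus_side(focus.focus[0], midline_x) if focus.defined else 0
    n_switch = 0

    rows = [(0.0, pos.pos[0], pos.pos[1], z, z_eff)] if keep_trajectory else None

    def draw(k: int) -> float:
        if script is not None:
            if k - 1 >= len(script):
                raise StepCapExceeded("noise script exhausted before termination")
            return float(script[k - 1])
        return rng.normal(ev.drift_mu, ev.noise_sigma)

    for k in range(1, spec.step_cap + 1):
        t_prev = (k - 1) * ev.dt
        # -- movement phase over [(k-1)dt, k dt] --------------------------
        if model != "baseline" and focus.defined:
            # inlined movement arithmetic, kept operation-for-operation
            # identical to the vectorized batch path so the two engines
            # agree bitwise
            x, y = pos.pos
            fx, fy = focus.focus
            dx, dy = fx - x, fy - y
            d = math.sqrt(dx * dx + dy * dy)
            if focus_is_target and d <= v * ev.dt:
                rt = t_prev + d / v
                pos = AgentPosition(focus.focus)
                choice = "target1" if focus.focus == geom.target1 else "target2"
                if rows is not None:
                    rows.append((rt, pos.pos[0], pos.pos[1], z, z_eff))
                return _finish(choice, rt, t_dec, n_switch, rows)
            if d <= v * ev.dt:
                pos = AgentPosition(focus.focus)
            elif d > 0:
                f = v * ev.dt / d
                pos = AgentPosition((x + f * (fx - x), y + f * (fy - y)))
        # -- evidence phase: increment received by time k*dt --------------
        z += draw(k)
        t = k * ev.dt
        if np.isnan(t_dec) and abs(z) >= b.b:
            t_dec = t
        if model == "baseline":
            if abs(z) >= b.b:
                choice = "target1" if z >= b.b else "target2"
                if rows is not None:
                    rows.append((t, pos.pos[0], pos.pos[1], z, z))
                return _finish(choice, t, t_dec, 0, rows)
            z_eff = z
        else:
            # -- focus phase ----------------------------------------------
            z_eff = z + (commitment_term(pos, geom, commit) if commit else 0.0)
            if model == "m1":
                if not decided and abs(z) >= b.b:
                    decided = True
                    focus = FocusPoint(geom.target1 if z >= b.b else geom.target2)
                    focus_is_target = True
            elif model == "m2":
                if z >= b.b:
                    focus = FocusPoint(geom.target1)
                    focus_is_target = True
                elif z <= -b.b:
                    focus = FocusPoint(geom.target2)
                    focus_is_target = True
            else:  # m3 / m4
                focus = focus_interpolated(z_eff, b, geom)
                focus_is_target = abs(z_eff) >= b.b
            if focus.defined:
                side = _focus_side(focus.focus[0], midline_x)
                if side != 0:
                    if side_prev != 0 and side != side_prev:
                        n_switch += 1
                    side_prev = side
        if rows is not None:
            rows.append((t, pos.pos[0], pos.pos[1], z, z_eff))
    raise StepCapExceeded(f"trial did not terminate within {spec.step_cap} steps")


def _finish(choice, rt, t_dec, n_switch, rows) -> TrialResult:
    traj = None
    if rows is not None:
        arr = np.asarray(rows, dtype=float)
        traj = Trajectory(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])
    return TrialResult(
        choice=choice,
        correct=choice == "target1",
        rt=float(rt),
        t_dec=float(t_dec),
        n_focus_switches=int(n_switch),
        trajectory=traj,
    )


def run_batch(
    spec: ModelSpec,
    n_trials: int,
    master_seed: int,
    keep_trajectories: bool = True,
    chunk: int = 64,
) -> tuple[list[TrialResult], BatchSummary]:
    """Run ``n_trials`` independent trials on per-trial substreams.

    Vectorized synchronous stepping: all still-running trials advance one
    step per iteration, drawing their increments from their own substreams
    in chunks.  Results are bitwise identical to calling :func:`run_trial`
    with ``trial_rng(master_seed, i)`` for each ``i``, in any order.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ev, geom, b = spec.evidence, spec.geometry, spec.bound
    model = spec.model_id
    n = n_trials
    v, dt, bb = geom.speed_v, ev.dt, b.b
    t1 = np.array(geom.target1)
    t2 = np.array(geom.target2)
    start = np.array(geom.start)
    midline_x = 0.5 * (t1[0] + t2[0])
    g = spec.gain_g if model == "m4" else 0.0

    rngs = [trial_rng(master_seed, i) for i in range(n)]
    buf = np.empty((n, chunk))
    col = chunk  # forces initial refill

    z = np.zeros(n)
    px = np.full(n, start[0])
    py = np.full(n, start[1])
    fx = np.empty(n)
    fy = np.empty(n)
    fdef = np.zeros(n, dtype=bool)
    f_target = np.zeros(n, dtype=bool)
    decided = np.zeros(n, dtype=bool)
    t_dec = np.full(n, np.nan)
    side_prev = np.zeros(n, dtype=np.int8)
    n_switch = np.zeros(n, dtype=np.int64)
    rt = np.full(n, np.nan)
    choice_t1 = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)

    def interp_focus(zv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w1 = np.clip((bb + zv) / (2.0 * bb), 0.0, 1.0)
        return w1 * t1[0] + (1 - w1) * t2[0], w1 * t1[1] + (1 - w1) * t2[1]

    def commit_term(pxv, pyv):
        d1 = np.sqrt((pxv - t1[0]) ** 2 + (pyv - t1[1]) ** 2)
        d2 = np.sqrt((pxv - t2[0]) ** 2 + (pyv - t2[1]) ** 2)
        return g * (d2 - d1) / (d1 + d2)

    z_eff = z + (commit_term(px, py) if model == "m4" else 0.0)
    if model in ("m3", "m4"):
        fx[:], fy[:] = interp_focus(z_eff)
        fdef[:] = True
        f_target[:] = np.abs(z_eff) >= bb
        side_prev[:] = np.sign(fx - midline_x)

    keep = keep_trajectories
    step_rows: list[tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    final_rows: dict[int, tuple[float, float, float, float, float]] = {}

    for k in range(1, spec.step_cap + 1):
        if not active.any():
            break
        t_prev = (k - 1) * dt
        t = k * dt
        idx = np.nonzero(active)[0]

        # -- movement phase ----------------------------------------------
        if model != "baseline":
            mov = idx[fdef[idx]]
            if mov.size:
                dx = fx[mov] - px[mov]
                dy = fy[mov] - py[mov]
                d = np.sqrt(dx * dx + dy * dy)
                arrive = f_target[mov] & (d <= v * dt)
                arr_i = mov[arrive]
                if arr_i.size:
                    rt[arr_i] = t_prev + d[arrive] / v
                    choice_t1[arr_i] = fx[arr_i] == t1[0]
                    px[arr_i] = fx[arr_i]
                    py[arr_i] = fy[arr_i]
                    active[arr_i] = False
                    if keep:
                        for i in arr_i:
                            final_rows[int(i)] = (
                                rt[i], px[i], py[i], z[i], z_eff[i]
                            )
                go = mov[~arrive]
                if go.size:
                    dgo = d[~arrive]
                    snap = dgo <= v * dt  # land exactly on a non-target focus
                    f = np.where(snap, 1.0, np.divide(
                        v * dt, dgo, out=np.ones_like(dgo), where=dgo > 0))
                    px[go] += f * (fx[go] - px[go])
                    py[go] += f * (fy[go] - py[go])
            idx = np.nonzero(active)[0]
            if idx.size == 0:
                continue

        # -- evidence phase -----------------------------------------------
        if col == chunk:
            for i in idx:
                buf[i] = rngs[i].normal(ev.drift_mu, ev.noise_sigma, chunk)
            col = 0
        z[idx] += buf[idx, col]
        col += 1

        crossed = np.abs(z[idx]) >= bb
        newdec = idx[crossed & np.isnan(t_dec[idx])]
        t_dec[newdec] = t

        if model == "baseline":
            done_i = idx[crossed]
            if done_i.size:
                rt[done_i] = t
                choice_t1[done_i] = z[done_i] >= bb
                active[done_i] = False
                if keep:
                    for i in done_i:
                        final_rows[int(i)] = (t, px[i], py[i], z[i], z[i])
            z_eff[idx] = z[idx]
        else:
            # -- focus phase ----------------------------------------------
            z_eff[idx] = z[idx] + (commit_term(px[idx], py[idx])
                                   if model == "m4" else 0.0)
            if model == "m1":
                nd = idx[~decided[idx] & (np.abs(z[idx]) >= bb)]
                if nd.size:
                    decided[nd] = True
                    up = z[nd] >= bb
                    fx[nd] = np.where(up, t1[0], t2[0])
                    fy[nd] = np.where(up, t1[1], t2[1])
                    fdef[nd] = True
                    f_target[nd] = True
            elif model == "m2":
                up = idx[z[idx] >= bb]
                dn = idx[z[idx] <= -bb]
                fx[up], fy[up] = t1[0], t1[1]
                fx[dn], fy[dn] = t2[0], t2[1]
                fdef[up] = fdef[dn] = True
                f_target[up] = f_target[dn] = True
            else:
                fx[idx], fy[idx] = interp_focus(z_eff[idx])
                f_target[idx] = np.abs(z_eff[idx]) >= bb
            upd = idx[fdef[idx]]
            side = np.sign(fx[upd] - midline_x).astype(np.int8)
            nz = side != 0
            sw = nz & (side_prev[upd] != 0) & (side != side_prev[upd])
            n_switch[upd[sw]] += 1
            side_prev[upd[nz]] = side[nz]

        if keep:
            live = active.copy()
            step_rows.append(
                (t, px.copy(), py.copy(), z.copy(), z_eff.copy(), live)
            )

    if active.any():
        raise StepCapExceeded(
            f"{int(active.sum())} trials did not terminate within "
            f"{spec.step_cap} steps"
        )

    results: list[TrialResult] = []
    if keep:
        masks = np.array([r[5] for r in step_rows]) if step_rows else np.zeros((0, n), bool)
        init_zeff = float(commit_term(start[0], start[1])) if model == "m4" else 0.0
    for i in range(n):
        traj = None
        if keep:
            rows = [(0.0, start[0], start[1], 0.0, init_zeff)]
            ks = np.nonzero(masks[:, i])[0] if len(step_rows) else []
            for kk in ks:
                tr = step_rows[kk]
                rows.append((tr[0], tr[1][i], tr[2][i], tr[3][i], tr[4][i]))
            if i in final_rows:
                rows.append(final_rows[i])
            arr = np.asarray(rows, dtype=float)
            traj = Trajectory(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])
        choice = "target1" if choice_t1[i] else "target2"
        results.append(
            TrialResult(
                choice=choice,
                correct=bool(choice_t1[i]),
                rt=float(rt[i]),
                t_dec=float(t_dec[i]),
                n_focus_switches=int(n_switch[i]),
                trajectory=traj,
            )
        )
    summary = BatchSummary(
        n_trials=n,
        mean_rt=float(np.mean(rt)),
        mean_error=float(1.0 - np.mean(choice_t1)),
        seed=master_seed,
    )
    return results, summary


def select_trajectories(
    results: Sequence[TrialResult],
    target: Literal["target1", "target2"],
    k: int,
) -> list[TrialResult]:
    """The first ``k`` trials (in trial-index order) ending at ``target``."""
    out = [r for r in results if r.choice == target][:k]
    if len(out) < k:
        raise ValueError(
            f"only {len(out)} trials end at {target}; {k} requested"
        )
    return out
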