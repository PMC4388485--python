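"""CSV/JSON artifact I/O, flat-config parsing and deterministic fixtures.

File formats (comma-separated, header row, ``.`` decimal, LF endings):

* trajectory CSV — ``trial_id, step, t, x, y, z, z_eff``; deterministic row
  order (trial-major, then step).
* trial-index CSV — ``trial_id, choice, correct, rt, t_dec, n_focus_switches``.
* sweep CSV — ``model_id, b, g, n_trials, mean_rt, mean_error, seed``.
* metrics CSV — ``model_id, n_trajectories, mean_area, initial_angle_deg,
  final_angle_deg, mean_auc, sigma, bound_b, seed``.
* run manifest — JSON with the resolved configuration, seed and version.

Every artifact embeds enough provenance (config + seed) to be regenerated
byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .engine import Trajectory, TrialResult
from .kinematics import TaskGeometry
from .sweep import SweepCurve

__all__ = [
    "trajectories_to_frame",
    "trial_index_frame",
    "write_trajectories",
    "write_trial_index",
    "read_trajectories",
    "write_sweep",
    "write_metrics_report",
    "write_manifest",
    "parse_flat_config",
    "read_external_trajectories",
    "generate_fixtures",
]

TRAJ_COLUMNS = ["trial_id", "step", "t", "x", "y", "z", "z_eff"]
INDEX_COLUMNS = ["trial_id", "choice", "correct", "rt", "t_dec", "n_focus_switches"]


def trajectories_to_frame(results: Sequence[TrialResult]) -> pd.DataFrame:
    frames = []
    for i, r in enumerate(results):
        if r.trajectory is None:
            raise ValueError(f"trial {i} has no stored trajectory")
        tr = r.trajectory
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": i,
                    "step": np.arange(len(tr)),
                    "t": tr.t,
                    "x": tr.x,
                    "y": tr.y,
                    "z": tr.z,
                    "z_eff": tr.z_eff,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRAJ_COLUMNS]


def trial_index_frame(results: Sequence[TrialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": np.arange(len(results)),
            "choice": [r.choice for r in results],
            "correct": [r.correct for r in results],
            "rt": [r.rt for r in results],
            "t_dec": [r.t_dec for r in results],
            "n_focus_switches": [r.n_focus_switches for r in results],
        }
    )


def _write_csv(df: pd.DataFrame, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def write_trajectories(results: Sequence[TrialResult], path: Path | str) -> None:
    _write_csv(trajectories_to_frame(results), path)


def write_trial_index(results: Sequence[TrialResult], path: Path | str) -> None:
    _write_csv(trial_index_frame(results), path)


def read_trajectories(
    traj_path: Path | str, index_path: Path | str | None = None
) -> list[TrialResult]:
    """Rebuild :class:`TrialResult` records from the trajectory CSV.

    With the companion index CSV all scalar fields round-trip exactly;
    without it, choice/rt are inferred from the final sample (nearest
    target) and switch counts are unknown (-1).
    """
    df = pd.read_csv(traj_path)
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    index = pd.read_csv(index_path).set_index("trial_id") if index_path else None
    geom = TaskGeometry()
    out = []
    for tid, grp in df.groupby("trial_id", sort=True):
        grp = grp.sort_values("step")
        traj = Trajectory(
            grp["t"].to_numpy(),
            grp["x"].to_numpy(),
            grp["y"].to_numpy(),
            grp["z"].to_numpy(),
            grp["z_eff"].to_numpy(),
        )
        if index is not None:
            row = index.loc[tid]
            out.append(
                TrialResult(
                    choice=str(row["choice"]),
                    correct=bool(row["correct"]),
                    rt=float(row["rt"]),
                    t_dec=float(row["t_dec"]),
                    n_focus_switches=int(row["n_focus_switches"]),
                    trajectory=traj,
                )
            )
        else:
            xf, yf = traj.x[-1], traj.y[-1]
            d1 = np.hypot(xf - geom.target1[0], yf - geom.target1[1])
            d2 = np.hypot(xf - geom.target2[0], yf - geom.target2[1])
            choice = "target1" if d1 <= d2 else "target2"
            out.append(
                TrialResult(
                    choice=choice,
                    correct=choice == "target1",
                    rt=float(traj.t[-1]),
                    t_dec=float("nan"),
                    n_focus_switches=-1,
                    trajectory=traj,
                )
            )
    return out


def write_sweep(curve: SweepCurve, path: Path | str) -> None:
    df = pd.DataFrame(
        {
            "model_id": curve.model_id,
            "b": curve.b,
            "g": curve.g,
            "n_trials": curve.n_trials,
            "mean_rt": curve.mean_rt,
            "mean_error": curve.mean_error,
            "seed": curve.seed,
        }
    )
    _write_csv(df, path)


def write_metrics_report(rows: Sequence[dict], path: Path | str) -> None:
    cols = [
        "model_id", "n_trajectories", "mean_area", "initial_angle_deg",
        "final_angle_deg", "mean_auc", "sigma", "bound_b", "seed",
    ]
    _write_csv(pd.DataFrame(list(rows))[cols], path)


def write_manifest(config: dict, seed: int, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = {"config": config, "seed": seed, "version": __version__}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def parse_flat_config(path: Path | str) -> dict[str, str]:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def read_external_trajectories(
    path: Path | str, normalize: bool = True
) -> list[TrialResult]:
    """Read a generic tabular trajectory file (``trial_id, t, x, y``).

    With ``normalize=True`` each trial is affinely mapped to the default
    arena: its first sample to the start (0, 0) and its final sample to
    target 1 at (-1, 1.5), so externally recorded 2AFC paths can be fed to
    the same metrics as simulated ones.  Evidence columns are NaN.
    """
    df = pd.read_csv(path)
    required = {"trial_id", "t", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"external trajectory file missing columns: {sorted(missing)}")
    geom = TaskGeometry()
    out = []
    for _, grp in df.groupby("trial_id", sort=True):
        grp = grp.sort_values("t")
        x = grp["x"].to_numpy(dtype=float)
        y = grp["y"].to_numpy(dtype=float)
        t = grp["t"].to_numpy(dtype=float)
        if normalize:
            if x[-1] == x[0] or y[-1] == y[0]:
                raise ValueError("degenerate trial: endpoints coincide on an axis")
            x = (x - x[0]) * (geom.target1[0] - geom.start[0]) / (x[-1] - x[0])
            y = (y - y[0]) * (geom.target1[1] - geom.start[1]) / (y[-1] - y[0])
        nan = np.full_like(x, np.nan)
        out.append(
            TrialResult(
                choice="target1",
                correct=True,
                rt=float(t[-1] - t[0]),
                t_dec=float("nan"),
                n_focus_switches=-1,
                trajectory=Trajectory(t - t[0], x, y, nan, nan),
            )
        )
    return out


def generate_fixtures(outdir: Path | str, seed: int = 0) -> dict[str, Path]:
    """Write the deterministic fixture bundle used by the tests.

    * ``script_ramp.csv`` — zero-noise increments (constant drift 1/3).
    * ``script_switch.csv`` — increments driving z to +b then across to -b
      (b = 1): a scripted change of mind.
    * ``m1_trajectories.csv`` / ``m1_index.csv`` — a small serial-model batch.
    * ``mirrored_pair.csv`` — two mirror-image paths whose mean is the midline.
    """
    from .engine import run_batch  # local import to avoid cycle at module load
    from .sweep import make_spec

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ramp = pd.DataFrame({"dz": np.full(40, 1.0 / 3.0)})
    paths["script_ramp"] = outdir / "script_ramp.csv"
    _write_csv(ramp, paths["script_ramp"])

    # reach +1 in 3 steps, then swing to -1 in one large opposing increment
    switch = pd.DataFrame({"dz": [1 / 3, 1 / 3, 1 / 3, -2.0] + [0.0] * 40})
    paths["script_switch"] = outdir / "script_switch.csv"
    _write_csv(switch, paths["script_switch"])

    spec = make_spec("m1", b=1.0)
    results, _ = run_batch(spec, 10, master_seed=seed)
    paths["m1_trajectories"] = outdir / "m1_trajectories.csv"
    paths["m1_index"] = outdir / "m1_index.csv"
    write_trajectories(results, paths["m1_trajectories"])
    write_trial_index(results, paths["m1_index"])

    # mirror pair about the target line x = -1; both trials end on target 1,
    # so the per-height mean collapses onto the symmetry axis exactly
    y = np.linspace(0.0, 1.5, 16)
    e = (1.0 - y / 1.5) * (1.0 + 0.3 * np.sin(np.pi * y / 1.5))
    rows = []
    for tid, xs in enumerate([-1.0 + e, -1.0 - e]):
        for t, (xx, yy) in enumerate(zip(xs, y)):
            rows.append({"trial_id": tid, "t": 0.05 * t, "x": xx, "y": yy})
    paths["mirrored_pair"] = outdir / "mirrored_pair.csv"
    _write_csv(pd.DataFrame(rows), paths["mirrored_pair"])
    return paths
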