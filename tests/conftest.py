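import numpy as np
import pytest
from hypothesis import settings

from driftreach import EvidenceParams, TaskGeometry, Trajectory, TrialResult

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

TRAVEL = float(np.hypot(1.0, 1.5) / 2.0)  # straight-line time to a target (s)


@pytest.fixture(scope="session")
def geom() -> TaskGeometry:
    return TaskGeometry()


@pytest.fixture
def zero_noise_step() -> EvidenceParams:
    """Deterministic per-step accumulator: dz = 1/3 each 50 ms step."""
    return EvidenceParams(drift_mu=1.0 / 3.0, noise_sigma=0.0, dt=0.05)


def make_path_result(points, choice="target1") -> TrialResult:
    """Wrap a polyline (list of (x, y)) into a TrialResult for metric tests."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    t = 0.05 * np.arange(n)
    nan = np.full(n, np.nan)
    return TrialResult(
        choice=choice,
        correct=choice == "target1",
        rt=float(t[-1]),
        t_dec=float("nan"),
        n_focus_switches=0,
        trajectory=Trajectory(t, pts[:, 0], pts[:, 1], nan, nan),
    )
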