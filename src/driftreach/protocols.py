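"""Canonical study protocols: calibrated trajectory batches and summaries.

These helpers bundle the full reproduction pipeline used by the analyses:

1. calibrate the bound of each model to its target mean response time
   (1.5 s for the serial, change-of-mind and preparation models; 1.0 s for
   the commitment model, whose attainable range is faster);
2. simulate until 150 trials completing at target 1 are collected, in
   trial-index order;
3. compute the headline trajectory metrics (mean deviation area, initial and
   final angle of the per-height mean trajectory, mean AUC curvature);
4. optionally repeat at a noise scale of 4x (with the bound recalibrated by
   the same rule) for the difficulty comparison.

All randomness is derived from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import ModelId, TrialResult, run_batch, select_trajectories
from .evidence import EvidenceParams
from .metrics import TrajectoryMetrics, summarize_trajectories
from .sweep import CalibrationResult, calibrate_boundary, make_spec

__all__ = [
    "TARGET_MEAN_RT",
    "N_SELECT",
    "study_evidence",
    "derive_seed",
    "collect_target1_trials",
    "Study1Result",
    "study1_metrics",
    "study1_over_seeds",
]

#: Mean response time (s) each model's bound is calibrated to.
TARGET_MEAN_RT: dict[ModelId, float] = {"m1": 1.5, "m2": 1.5, "m3": 1.5, "m4": 1.0}

#: Number of target-1 trajectories entering the Study-1 metrics.
N_SELECT = 150


def study_evidence(sigma_scale: float = 1.0) -> EvidenceParams:
    """Study accumulator: drift 1/3 /s, diffusion ``sigma_scale`` /sqrt(s)."""
    return EvidenceParams.from_rates(1.0 / 3.0, sigma_scale, 0.05)


def derive_seed(seed: int, *tags: int) -> int:
    """A reproducible sub-seed (< 2^31) for an independent random stream."""
    return int(np.random.SeedSequence((seed, *tags)).generate_state(1)[0] % 2**31)


def collect_target1_trials(
    model_id: ModelId,
    b: float,
    k: int,
    master_seed: int,
    evidence: EvidenceParams | None = None,
) -> list[TrialResult]:
    """The first ``k`` trials (by trial index) that complete at target 1.

    The batch is grown geometrically until enough qualifying trials exist;
    per-trial substreams make the result independent of the growth schedule.
    """
    spec = make_spec(model_id, b, evidence)
    n = 2 * k
    while True:
        results, _ = run_batch(spec, n, master_seed)
        try:
            return select_trajectories(results, "target1", k)
        except ValueError:
            if n > 512 * k:
                raise
            n *= 2


@dataclass(frozen=True)
class Study1Result:
    model_id: ModelId
    calibration: CalibrationResult
    metrics: TrajectoryMetrics
    n_trajectories: int
    sigma_scale: float
    seed: int


def study1_metrics(
    model_id: ModelId,
    seed: int,
    sigma_scale: float = 1.0,
    k: int = N_SELECT,
    n_calib: int = 10_000,
) -> Study1Result:
    """Calibrate, simulate and summarize one model under the study protocol."""
    evidence = study_evidence(sigma_scale)
    cal = calibrate_boundary(
        model_id,
        TARGET_MEAN_RT[model_id],
        n_trials=n_calib,
        seed=derive_seed(seed, 0),
        evidence=evidence,
    )
    trials = collect_target1_trials(
        model_id, cal.b_star, k, derive_seed(seed, 1), evidence
    )
    return Study1Result(
        model_id=model_id,
        calibration=cal,
        metrics=summarize_trajectories(trials),
        n_trajectories=k,
        sigma_scale=sigma_scale,
        seed=seed,
    )


def study1_over_seeds(
    model_id: ModelId,
    seeds: list[int],
    sigma_scale: float = 1.0,
    k: int = N_SELECT,
    n_calib: int = 10_000,
) -> dict[str, float]:
    """Grand means of the Study-1 metrics over independent seeds."""
    runs = [study1_metrics(model_id, s, sigma_scale, k, n_calib) for s in seeds]
    return {
        "mean_area": float(np.mean([r.metrics.area_to_target_line for r in runs])),
        "initial_angle_deg": float(
            np.mean([r.metrics.initial_angle_deg for r in runs])
        ),
        "final_angle_deg": float(np.mean([r.metrics.final_angle_deg for r in runs])),
        "mean_auc": float(np.mean([r.metrics.auc_curvature for r in runs])),
        "b_star": float(np.mean([r.calibration.b_star for r in runs])),
    }
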