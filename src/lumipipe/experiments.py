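"""Simulated stimulation experiments: subject -> full chain -> AUC stats.

Thin orchestration over the simulator, pipeline and statistics modules used
to emulate whole cohorts of head-fixed imaging sessions: each simulated
subject gets its own noise realization, is analyzed with the standard
chain, and is reduced to a cortical response trace with early/late AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pipeline import analyze_stack
from .stats import (ResponseStats, ResponseTrace, compare_groups,
                    rezero_prestim, roi_response_trace, split_auc)
from .synthetic import (CameraModel, HeadGeometry, ResponseKernel,
                        StimulusSchedule, SubstrateKinetics,
                        make_stimulus_schedule, simulate_video)

__all__ = ["SubjectResult", "simulate_subject", "simulate_cohort",
           "cohort_early_auc_test"]


@dataclass
class SubjectResult:
    """Per-subject output of one simulated imaging session."""

    trace: ResponseTrace
    stats: ResponseStats


def simulate_subject(kernels: Sequence[ResponseKernel], seed: int, *,
                     schedule: StimulusSchedule | None = None,
                     kinetics: SubstrateKinetics = SubstrateKinetics(),
                     camera: CameraModel = CameraModel(),
                     geometry: HeadGeometry = HeadGeometry(),
                     duration: float | None = None,
                     noise: bool = True,
                     n_first: int | str = "all",
                     split_time: float = 2.0,
                     late_end: float = 6.0,
                     subject_id: str = "") -> SubjectResult:
    """Simulate one subject and run the full analysis chain.

    The default schedule is the standard 1 s on / 19 s off design starting
    60 s into the acquisition; pass ``duration`` to leave a recording tail
    after the last cycle.  The head mask is estimated from the data (Otsu),
    not taken from the simulation truth.
    """
    if schedule is None:
        schedule = make_stimulus_schedule(57, 1.0, 19.0, 60.0)
    video, _truth = simulate_video(kinetics, camera, schedule,
                                   geometry=geometry, kernels=kernels,
                                   seed=seed, duration=duration, noise=noise)
    result = analyze_stack(video, schedule, dark=camera.dark_offset,
                           n_first=n_first)
    trace = roi_response_trace(result.movie, result.mask,
                               pre_window=result.trials.pre_window,
                               frame_rate=video.frame_rate,
                               n_trials_averaged=result.n_trials_averaged,
                               subject_id=subject_id)
    trace = rezero_prestim(trace)
    stats = split_auc(trace, split_time=split_time,
                      late_window=(split_time, late_end))
    return SubjectResult(trace, stats)


def simulate_cohort(kernels: Sequence[ResponseKernel], n_subjects: int,
                    seed: int, **kwargs) -> list[SubjectResult]:
    """Simulate ``n_subjects`` independent subjects with spawned seeds."""
    seeds = np.random.SeedSequence(seed).generate_state(n_subjects)
    return [simulate_subject(kernels, int(s % 2**31),
                             subject_id=f"sim{i:02d}", **kwargs)
            for i, s in enumerate(seeds)]


def cohort_early_auc_test(group_a: Sequence[SubjectResult],
                          group_b: Sequence[SubjectResult]):
    """Unpaired Student's t-test on per-subject early AUCs of two cohorts."""
    return compare_groups([r.stats.early_auc for r in group_a],
                          [r.stats.early_auc for r in group_b])
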