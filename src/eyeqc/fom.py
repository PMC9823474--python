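"""Accuracy-vs-latency Figure of Merit and the frame-timing protocol.

A frame classifier for a real-time pupillometer must be both accurate and
fast.  The combined score used here is

    FOM = A^2 * exp(-(SFPT / tau)^2)

where A in [0, 1] is the classification accuracy, SFPT (single-frame
prediction time) is the elapsed time from frame-in-memory to emitted label,
and tau is a time constant calibrated so that a reference operating point —
accuracy 0.8 at SFPT 10 ms — scores exactly 0.5.  Squaring A makes any
classifier below ~0.71 accuracy score under 0.5 however fast it is, while
the squared-exponential decay caps the usable latency at about 16.8 ms even
at perfect accuracy.

SFPT is measured per frame with a monotonic clock, predicting one frame at
a time (batching would hide per-frame overhead that a live instrument
pays); a warmup prefix is excluded, and both the mean and the nearest-rank
90th percentile are reported.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np

__all__ = [
    "TimingStats",
    "FOMResult",
    "calibrate_tau",
    "compute_fom",
    "sfpt_limit",
    "measure_sfpt",
    "nearest_rank_percentile",
]

#: reference operating point used to calibrate tau
TARGET_ACCURACY = 0.8
TARGET_SFPT = 0.010  # seconds
TARGET_FOM = 0.5


@dataclass(frozen=True)
class TimingStats:
    """Per-frame latency measurements (seconds)."""

    durations: tuple
    mean_sfpt: float
    p90_sfpt: float

    @classmethod
    def from_durations(cls, durations: Sequence[float]) -> "TimingStats":
        d = [float(x) for x in durations]
        if not d:
            raise ValueError("no durations to summarize")
        if any(x <= 0 for x in d):
            raise ValueError("durations must be positive")
        return cls(
            durations=tuple(d),
            mean_sfpt=float(np.mean(d)),
            p90_sfpt=nearest_rank_percentile(d, 90.0),
        )


@dataclass(frozen=True)
class FOMResult:
    """Accuracy, latency, time constant, and the combined score."""

    accuracy: float
    sfpt: float
    tau: float
    fom: float


def nearest_rank_percentile(values: Sequence[float], q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest value."""
    v = sorted(values)
    if not v:
        raise ValueError("empty sample")
    k = max(1, math.ceil(q / 100.0 * len(v)))
    return v[k - 1]


def calibrate_tau(
    target_accuracy: float = TARGET_ACCURACY,
    target_sfpt: float = TARGET_SFPT,
    target_fom: float = TARGET_FOM,
) -> float:
    """Time constant making the reference operating point score target_fom.

    Closed form: tau = SFPT / sqrt(ln(A^2 / FOM)).  With the defaults
    (A = 0.8, SFPT = 10 ms, FOM = 0.5) this gives tau ~= 0.020127 s.
    """
    if target_sfpt <= 0:
        raise ValueError("target_sfpt must be positive")
    if not (0.0 < target_fom < target_accuracy ** 2):
        raise ValueError(
            "need 0 < target_fom < target_accuracy^2 for a positive solution"
        )
    return target_sfpt / math.sqrt(math.log(target_accuracy ** 2 / target_fom))


def compute_fom(accuracy: float, sfpt: float, tau: Optional[float] = None) -> float:
    """Evaluate FOM = A^2 * exp(-(SFPT/tau)^2).

    Strictly increasing in accuracy, strictly decreasing in latency, and
    bounded in [0, 1].  ``tau`` defaults to the calibrated constant.
    """
    if not (0.0 <= accuracy <= 1.0):
        raise ValueError(f"accuracy must be in [0, 1], got {accuracy}")
    if sfpt < 0:
        raise ValueError(f"sfpt must be non-negative, got {sfpt}")
    if tau is None:
        tau = calibrate_tau()
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return accuracy ** 2 * math.exp(-((sfpt / tau) ** 2))


def sfpt_limit(
    accuracy: float, tau: Optional[float] = None, target_fom: float = TARGET_FOM
) -> float:
    """Latency at which a classifier of given accuracy drops to target_fom.

    Inverse of :func:`compute_fom` in the SFPT argument:
    SFPT_limit = tau * sqrt(ln(A^2 / FOM)).  Only defined for
    A^2 > target_fom; at perfect accuracy and the default calibration this
    is ~16.76 ms.
    """
    if tau is None:
        tau = calibrate_tau()
    if accuracy ** 2 <= target_fom:
        raise ValueError(
            f"no positive latency solution: accuracy^2 = {accuracy ** 2:.4f} "
            f"<= target FOM {target_fom}"
        )
    return tau * math.sqrt(math.log(accuracy ** 2 / target_fom))


def measure_sfpt(
    classifier: Callable[[np.ndarray], object],
    frames: Sequence[np.ndarray],
    warmup: int = 10,
    timer: Callable[[], float] = time.perf_counter,
) -> TimingStats:
    """Time a frame->label procedure one frame at a time.

    Frames must already be in memory (load time is excluded by protocol).
    The first ``warmup`` calls are made but excluded from the statistics to
    discard cache/JIT effects.  ``timer`` is injectable for testing.
    """
    if len(frames) <= warmup:
        raise ValueError(
            f"need more than warmup={warmup} frames, got {len(frames)}"
        )
    durations: List[float] = []
    for i, frame in enumerate(frames):
        t0 = timer()
        classifier(frame)
        dt = timer() - t0
        if i >= warmup:
            durations.append(dt)
    return TimingStats.from_durations(durations)
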