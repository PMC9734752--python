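"""Phase extraction and synchrony metrics for hand trajectories.

Instantaneous phase is read off geometrically: the hand position is
projected onto the movement (YZ) plane and the angle around the circle
centre taken with ``atan2``.  This inverts the generative circular
kinematics exactly and is causal, so it matches what an online system
can compute in real time.  A Hilbert-transform alternative is available
for offline analysis of the vertical component.

From phases the module derives the wrapped relative phase between two
hands, the Kuramoto order parameter, phase-lock intervals (windowed
relative-phase drift below a tolerance) and the time-in-sync summary of
a button stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal import hilbert

from .core_model import HandTrajectory, R_MIN, wrap_phase
from .errors import GridMismatchError, MirrorGameError

__all__ = [
    "PhaseSeries",
    "SyncReport",
    "extract_phase",
    "relative_phase",
    "order_parameter",
    "detect_lock",
    "sync_time",
]


@dataclass(frozen=True)
class PhaseSeries:
    """Wrapped instantaneous phase of one hand over time."""

    times: np.ndarray
    phases: np.ndarray
    side: str
    source: str = "human"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "phases",
                           np.asarray(self.phases, dtype=float))
        if len(self.times) != len(self.phases):
            raise ValueError("times and phases must have equal length")

    def unwrapped(self) -> np.ndarray:
        return np.unwrap(self.phases)


@dataclass(frozen=True)
class SyncReport:
    """Time a participant reported feeling in synchrony in one trial."""

    condition: str
    time_pressed: float
    ratio: float


def extract_phase(
    trajectory: HandTrajectory,
    center: Optional[np.ndarray] = None,
    source: str = "human",
    method: str = "atan2",
) -> PhaseSeries:
    """Instantaneous phase of a hand moving on a (noisy) circle.

    Right hands use ``atan2(y - c_y, z - c_z)``; left hands flip the sign
    of the lateral coordinate, matching the mirror-symmetric kinematic
    convention so that both sides report increasing phase for their
    nominal rotation direction.  ``center`` defaults to the trajectory's
    mean position.  Samples closer than ``R_MIN`` to the centre carry no
    angular information; their phase repeats the previous value (freeze
    rule).

    ``method="hilbert"`` instead derives phase from the analytic signal
    of the vertical coordinate (offline alternative).

    Raises
    ------
    MirrorGameError
        If fewer than 10% of samples are at usable radial distance.
    """
    pos = trajectory.positions
    if center is None:
        center = pos.mean(axis=0)
    center = np.asarray(center, dtype=float)
    radial = np.linalg.norm(pos - center, axis=1)
    usable = radial >= R_MIN
    if usable.mean() < 0.10:
        raise MirrorGameError(
            "degenerate trajectory: hand never moves away from the centre"
        )
    if method == "hilbert":
        # analytic phase of r*sin(theta) is theta - pi/2; shift to the
        # atan2 convention where theta = 0 points along +z
        y = pos[:, 1] - center[1]
        phases = np.angle(hilbert(y)) + 0.5 * np.pi
    elif method == "atan2":
        y = pos[:, 1] - center[1]
        z = pos[:, 2] - center[2]
        if trajectory.side == "left":
            z = -z
        phases = np.arctan2(y, z)
    else:
        raise ValueError(f"unknown method: {method!r}")
    # freeze rule: hold the last informative phase through the dead zone
    phases = phases.copy()
    last = phases[np.argmax(usable)]
    for i in range(len(phases)):
        if usable[i]:
            last = phases[i]
        else:
            phases[i] = last
    return PhaseSeries(trajectory.times, wrap_phase(phases),
                       trajectory.side, source)


def relative_phase(a: PhaseSeries, b: PhaseSeries) -> np.ndarray:
    """Wrapped elementwise phase difference ``a - b``."""
    if len(a.times) != len(b.times) or np.max(
        np.abs(a.times - b.times)
    ) > 1e-9:
        raise GridMismatchError("phase series are on different time grids")
    return wrap_phase(a.phases - b.phases)


def order_parameter(phases: np.ndarray) -> np.ndarray:
    """Kuramoto order parameter R(t) of two or more phase streams.

    ``phases`` has shape (n_streams, n_times) (or (n_streams,) for a
    single instant).  R = |mean of exp(i * phase)| lies in [0, 1]: 1 for
    perfectly aligned phases, near 1/sqrt(n) for incoherent ones.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.shape[0] < 2:
        raise ValueError("need at least two phase streams")
    # referencing to the first stream leaves R unchanged (rotation
    # invariance) but makes identical phases give exactly 1.0
    return np.abs(np.exp(1j * (phases - phases[0])).mean(axis=0))


def detect_lock(
    rel_phase: np.ndarray,
    sample_rate: float,
    window: float = 2.0,
    tolerance: float = 0.1,
) -> List[Tuple[float, float]]:
    """Intervals where the relative phase drifts slower than ``tolerance``.

    The relative phase is unwrapped, differentiated, and its absolute
    derivative averaged over a centred moving ``window`` (seconds);
    samples below ``tolerance`` (rad/s) are in lock.  Contiguous runs are
    reported as (start, end) times; adjacent runs merge by construction.
    """
    if window < 1.0:
        raise ValueError("window must be at least 1 s")
    unwrapped = np.unwrap(np.asarray(rel_phase, dtype=float))
    if len(unwrapped) < 2:
        return []
    dt = 1.0 / sample_rate
    deriv = np.abs(np.gradient(unwrapped, dt))
    w = max(1, int(round(window * sample_rate)))
    kernel = np.ones(w) / w
    smooth = np.convolve(deriv, kernel, mode="same")
    locked = smooth < tolerance
    intervals: List[Tuple[float, float]] = []
    start = None
    times = np.arange(len(locked)) * dt
    for i, flag in enumerate(locked):
        if flag and start is None:
            start = times[i]
        elif not flag and start is not None:
            intervals.append((start, times[i - 1]))
            start = None
    if start is not None:
        intervals.append((start, times[-1]))
    return intervals


def lock_fraction(
    rel_phase: np.ndarray,
    sample_rate: float,
    window: float = 2.0,
    tolerance: float = 0.1,
    transient: float = 0.0,
) -> float:
    """Fraction of the (post-transient) trial spent phase-locked."""
    n = len(rel_phase)
    duration = (n - 1) / sample_rate
    intervals = detect_lock(rel_phase, sample_rate, window, tolerance)
    total = sum(
        max(0.0, min(e, duration) - max(s, transient)) for s, e in intervals
    )
    span = duration - transient
    return total / span if span > 0 else 0.0


def sync_time(button: np.ndarray, sample_rate: float,
              condition: str = "unknown") -> SyncReport:
    """Summarise a button stream as total pressed time and ratio."""
    button = np.asarray(button, dtype=bool)
    if len(button) == 0:
        raise ValueError("button series is empty")
    time_pressed = float(button.sum() / sample_rate)
    span = len(button) / sample_rate
    return SyncReport(condition, time_pressed, time_pressed / span)
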