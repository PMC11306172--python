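"""Kinematic event detection: maximum apex velocity and first applanation.

Classical non-contact tonometry reads the IOP at the first applanation
instant — when the central cornea becomes locally flat — but that instant
depends on corneal stiffness and thickness.  The apex-velocity maximum (zero
apex acceleration, i.e. zero net force) is the event the work-based
estimator uses instead.  This module detects both events from simulated
trajectories or device-style velocity traces and quantifies their lag.

Applanation criterion: the best-fit curvature of the central 3 mm chord of
the anterior profile drops below 1 m^-1 (radius above 1 m), a documented
convention standing in for the device's proprietary detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VelocityTrace",
    "max_velocity_time",
    "first_applanation_time",
    "central_curvature",
    "EventDetectionError",
    "ApplanationNotReached",
]


class EventDetectionError(ValueError):
    """No interior velocity extremum (monotone or degenerate trace)."""


class ApplanationNotReached(ValueError):
    """The central cornea never flattens under the applied load."""


@dataclass
class VelocityTrace:
    """Sampled apex-velocity signal (time in ms, inward velocity in mm/ms).

    Device-style traces carry ~140 samples over the ~30 ms air pulse.
    ``provenance`` is one of 'simulated', 'clinical-style' or 'synthetic';
    simulated traces keep a reference to their trajectory so applanation can
    be detected from the deforming profile, synthetic traces may carry their
    ground-truth event times instead.
    """

    time_ms: np.ndarray
    velocity: np.ndarray
    displacement: np.ndarray | None = None
    provenance: str = "clinical-style"
    trajectory: object = field(default=None, repr=False)
    known_peak_ms: float | None = None
    known_applanation_ms: float | None = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.time_ms.ndim != 1 or self.time_ms.shape != self.velocity.shape:
            raise ValueError("time and velocity must be matching 1-d arrays")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time samples must be strictly increasing")
        if not (np.isfinite(self.time_ms).all() and np.isfinite(self.velocity).all()):
            raise ValueError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.time_ms)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="valid")
    return out[: len(x)]


def max_velocity_time(trace: VelocityTrace, smooth_window: int | None = None,
                      refine_halfwidth: int = 8) -> float:
    """Time (ms) of the maximum inward apex velocity.

    Measured traces are smoothed with a short moving average (default 3
    samples; simulated traces are used raw), then the discrete peak is
    refined by a least-squares parabola over ``refine_halfwidth`` samples
    on each side (noise-robust sub-sample localisation).  A trace whose
    maximum sits on the boundary (monotone, no interior extremum) raises
    :class:`EventDetectionError`.
    """
    if smooth_window is None:
        smooth_window = 1 if trace.provenance == "simulated" else 3
    v = _moving_average(trace.velocity, smooth_window)
    t = trace.time_ms
    j = int(np.argmax(v))
    if j == 0 or j == len(v) - 1:
        raise EventDetectionError(
            "velocity maximum lies on the trace boundary; no interior peak")
    lo = max(j - refine_halfwidth, 0)
    hi = min(j + refine_halfwidth + 1, len(v))
    tt = t[lo:hi] - t[j]
    vv = v[lo:hi]
    A = np.column_stack([tt ** 2, tt, np.ones_like(tt)])
    (a, b, _), *_ = np.linalg.lstsq(A, vv, rcond=None)
    if a >= 0:                     # degenerate: fall back to the sample
        return float(t[j])
    t_star = -b / (2.0 * a)
    if not (tt[0] <= t_star <= tt[-1]):
        return float(t[j])
    return float(t[j] + t_star)


def central_curvature(r: np.ndarray, y: np.ndarray, chord: float = 3.0) -> float:
    """Signed best-fit curvature (mm^-1) of the central anterior profile
    over the given chord; positive = convex outward (+y)."""
    sel = np.abs(r) <= 0.5 * chord
    if sel.sum() < 3:
        raise ValueError("fewer than 3 profile points inside the central chord")
    rr = r[sel]
    # enforce axisymmetry by mirroring, then fit y = c0 + c2 r^2
    rr2 = np.concatenate([rr, -rr]) ** 2
    yy = np.concatenate([y[sel], y[sel]])
    A = np.column_stack([np.ones_like(rr2), rr2])
    c, *_ = np.linalg.lstsq(A, yy, rcond=None)
    return float(-2.0 * c[1])      # y ~ y0 - kappa r^2 / 2


def first_applanation_time(trajectory, chord: float = 3.0,
                           curvature_threshold: float = 1e-3,
                           from_time: float | None = None) -> float:
    """Earliest time (ms) the central cornea is flat.

    ``trajectory`` is a simulated :class:`wiop.dynamics.Trajectory` (or any
    object with ``times``, ``coords`` and ``mesh``).  Flatness: the best-fit
    curvature of the central ``chord`` mm falls below
    ``curvature_threshold`` (default 1e-3 mm^-1, i.e. radius above 1 m).
    The crossing is located by linear interpolation between output
    increments.  Raises :class:`ApplanationNotReached` if the cornea never
    flattens in the window.
    """
    if isinstance(trajectory, VelocityTrace):
        if trajectory.trajectory is None:
            raise ValueError("trace carries no profile data for applanation")
        trajectory = trajectory.trajectory
    times = np.asarray(trajectory.times)
    mesh = trajectory.mesh
    ant = mesh.anterior_nodes
    start = 0 if from_time is None else int(np.searchsorted(times, from_time))
    kappa = np.array([
        central_curvature(trajectory.coords[j, ant, 0],
                          trajectory.coords[j, ant, 1], chord)
        for j in range(start, len(times))
    ])
    below = kappa < curvature_threshold
    if not below.any():
        raise ApplanationNotReached(
            f"central curvature never fell below {curvature_threshold} 1/mm")
    j = int(np.argmax(below))
    if j == 0:
        return float(times[start])
    t0, t1 = times[start + j - 1], times[start + j]
    k0, k1 = kappa[j - 1], kappa[j]
    frac = (k0 - curvature_threshold) / (k0 - k1)
    return float(t0 + frac * (t1 - t0))
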