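"""Clinical-facing wIOP estimation from an apex-velocity trace.

The tonometer exports the apex velocity over the air pulse; the estimator
detects the maximum-velocity time and evaluates the calibration quartic at
it.  By construction the estimate depends only on the *timing* of the peak,
not on the velocity amplitude — the property that removes the corneal
stiffness and thickness dependence of applanation-based readings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationFit, default_calibration
from .events import (ApplanationNotReached, VelocityTrace,
                     first_applanation_time, max_velocity_time)

__all__ = ["WiopEstimate", "estimate_wiop", "compare_with_applanation",
           "ApplanationReport"]


@dataclass
class WiopEstimate:
    """wIOP estimate with the event report behind it (times in ms from the
    trace's own origin, pressure in mmHg)."""

    wiop_mmhg: float
    t_maxvel_ms: float
    t_applanation_ms: float | None
    lag_ms: float | None
    extrapolated: bool
    calibration_source: str

    def summary(self) -> str:
        lines = [
            f"wIOP estimate: {self.wiop_mmhg:.2f} mmHg"
            + ("  [extrapolated]" if self.extrapolated else ""),
            f"  t(max velocity)    = {self.t_maxvel_ms:.3f} ms",
        ]
        if self.t_applanation_ms is not None:
            lines.append(f"  t(1st applanation) = {self.t_applanation_ms:.3f} ms")
            lines.append(f"  lag                = {self.lag_ms:.3f} ms")
        lines.append(f"  calibration: {self.calibration_source}")
        return "\n".join(lines)


def _applanation_of(trace: VelocityTrace):
    if trace.trajectory is not None:
        try:
            return first_applanation_time(
                trace.trajectory,
                from_time=getattr(trace.trajectory, "load_onset_ms", None))
        except ApplanationNotReached:
            return None
    return trace.known_applanation_ms


def estimate_wiop(trace: VelocityTrace,
                  calibration: CalibrationFit | None = None,
                  time_offset_ms: float = 0.0) -> WiopEstimate:
    """Estimate the wIOP from an apex-velocity trace.

    ``time_offset_ms`` shifts the trace's time base so that 0 is the puff
    onset (device traces already start there).  A peak time outside the
    calibration's fitted range flags the result as extrapolated rather than
    refusing.  A trace without a detectable interior peak raises
    :class:`wiop.events.EventDetectionError`.
    """
    calib = calibration or default_calibration()
    t_mv = max_velocity_time(trace) - time_offset_ms
    t_app = _applanation_of(trace)
    if t_app is not None:
        t_app -= time_offset_ms
    return WiopEstimate(
        wiop_mmhg=calib.wiop(t_mv),
        t_maxvel_ms=t_mv,
        t_applanation_ms=t_app,
        lag_ms=None if t_app is None else t_mv - t_app,
        extrapolated=calib.is_extrapolated(t_mv),
        calibration_source=calib.source)


@dataclass
class ApplanationReport:
    """First-applanation vs maximum-velocity comparison for one trace."""

    t_maxvel_ms: float
    t_applanation_ms: float | None
    difference_ms: float | None
    ordering_ok: bool | None     # applanation precedes the velocity peak
    partial: bool                # True when applanation was unavailable


def compare_with_applanation(trace: VelocityTrace) -> ApplanationReport:
    """Report both event times and their difference.

    The first applanation is expected to precede the velocity maximum (the
    cornea keeps accelerating inward past flatness); the difference varies
    between eyes.  If no applanation information is available the report is
    partial.
    """
    t_mv = max_velocity_time(trace)
    t_app = _applanation_of(trace)
    if t_app is None:
        return ApplanationReport(t_mv, None, None, None, partial=True)
    return ApplanationReport(t_mv, t_app, t_mv - t_app,
                             ordering_ok=t_app <= t_mv, partial=False)
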