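"""Synthetic fixtures with known ground truth.

Two generators support testing of the analysis side without any clinical
download:

* apex-velocity traces with the morphology of device recordings — inward
  acceleration, a velocity maximum 1-5 ms after first applanation,
  deceleration to zero at the highest concavity, then reversal — plus
  additive Gaussian measurement noise;
* toy work-curve pairs (decreasing IOP work, increasing air work) crossing
  exactly once at a prescribed time and value.

Every random element is drawn from a seeded generator, so fixtures are
fully reproducible; healthy vs keratoconic-like archetypes differ only in
peak amplitude and lag distribution (they exercise batch behaviour, not
clinical realism).
"""

from __future__ import annotations

import numpy as np

from .events import VelocityTrace

__all__ = ["generate_trace", "generate_work_curves", "ARCHETYPES"]

#: archetype -> (peak velocity mm/ms, (lag_lo, lag_hi) ms, applanation window ms)
ARCHETYPES = {
    "healthy": {"peak_velocity": 0.11, "lag_range": (1.5, 3.5),
                "t_app_range": (6.5, 8.5)},
    "keratoconic-like": {"peak_velocity": 0.16, "lag_range": (1.0, 5.0),
                         "t_app_range": (5.5, 8.0)},
}


def _waveform(t, t_onset, t_peak, t_concavity, peak):
    """C1 piecewise pulse: sin^2 rise to the peak, cosine decay through zero
    at the highest concavity into the outward (negative) lobe."""
    v = np.zeros_like(t)
    rise = (t >= t_onset) & (t <= t_peak)
    v[rise] = peak * np.sin(0.5 * np.pi * (t[rise] - t_onset)
                            / (t_peak - t_onset)) ** 2
    after = t > t_peak
    phase = 0.5 * np.pi * (t[after] - t_peak) / (t_concavity - t_peak)
    v[after] = peak * np.cos(np.minimum(phase, 1.5 * np.pi))
    return v


def generate_trace(archetype: str = "healthy", t_app: float | None = None,
                   lag: float | None = None, peak_velocity: float | None = None,
                   noise_sd: float = 0.0, seed: int | None = None,
                   n_samples: int = 140, duration_ms: float = 30.0):
    """Generate a device-style apex-velocity trace with known ground truth.

    The true maximum-velocity time is ``t_app + lag``; unspecified
    parameters are drawn from the archetype's documented ranges (uniform)
    using ``seed``.  Returns ``(trace, truth)`` where ``truth`` holds
    t_applanation, t_maxvel, t_concavity and peak_velocity.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    arch = ARCHETYPES[archetype]
    rng = np.random.default_rng(seed)
    if t_app is None:
        t_app = float(rng.uniform(*arch["t_app_range"]))
    if lag is None:
        lag = float(rng.uniform(*arch["lag_range"]))
    if lag < 0:
        raise ValueError("lag must be non-negative")
    if peak_velocity is None:
        peak_velocity = arch["peak_velocity"]

    t_peak = t_app + lag
    t_onset = max(t_app - 4.0, 0.25)
    t_concavity = min(t_peak + 4.0, duration_ms - 2.0)
    t = np.linspace(0.0, duration_ms, n_samples)
    v = _waveform(t, t_onset, t_peak, t_concavity, peak_velocity)
    if noise_sd > 0.0:
        v = v + rng.normal(0.0, noise_sd, size=v.shape)

    trace = VelocityTrace(time_ms=t, velocity=v, provenance="synthetic",
                          known_peak_ms=t_peak, known_applanation_ms=t_app)
    truth = {"t_applanation_ms": t_app, "t_maxvel_ms": t_peak,
             "t_concavity_ms": t_concavity, "peak_velocity": peak_velocity,
             "archetype": archetype}
    return trace, truth


def generate_work_curves(initial_work: float = 0.02, crossing_time: float = 12.0,
                         crossing_ratio: float = 0.5, steepness_ms: float = 3.0,
                         duration_ms: float = 30.0, n_samples: int = 140,
                         noise_sd: float = 0.0, seed: int | None = None):
    """Generate a (Work_IOP, Work_AIR) pair crossing once at a known point.

    Work_IOP decreases monotonically from ``initial_work`` along a logistic
    ramp centred at the crossing; Work_AIR increases monotonically and is
    scaled to meet Work_IOP exactly at ``crossing_time`` with value
    ``crossing_ratio * initial_work``.  Returns ``(t, w_iop, w_air, truth)``.
    """
    if not (0.0 < crossing_time < duration_ms):
        raise ValueError("crossing_time must lie inside the window")
    if not (0.0 < crossing_ratio < 1.0):
        raise ValueError("crossing_ratio must be in (0, 1)")
    t = np.linspace(0.0, duration_ms, n_samples)

    def logistic(tt):
        return 1.0 / (1.0 + np.exp(-(tt - crossing_time) / steepness_ms))

    # normalize so phi(0) = 0 (work starts exactly at initial_work)
    phi = (logistic(t) - logistic(np.array([0.0]))[0])
    phi = np.maximum(phi, 0.0)
    phi_c = (logistic(np.array([crossing_time]))[0]
             - logistic(np.array([0.0]))[0])
    w_iop = initial_work * (1.0 - (1.0 - crossing_ratio) * phi / phi_c)

    psi = 1.0 - np.exp(-t / steepness_ms)          # monotone rise from 0
    psi_c = 1.0 - np.exp(-crossing_time / steepness_ms)
    w_air = crossing_ratio * initial_work * psi / psi_c

    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        w_iop = w_iop + rng.normal(0.0, noise_sd, size=t.shape)
        w_air = w_air + rng.normal(0.0, noise_sd, size=t.shape)

    truth = {"crossing_time_ms": crossing_time,
             "crossing_value_mJ": crossing_ratio * initial_work,
             "initial_work_mJ": initial_work}
    return t, w_iop, w_air, truth
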