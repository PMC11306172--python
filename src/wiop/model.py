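"""High-level modelling surface: build an eye, pressurize it, load it.

``EyeModel`` bundles geometry and regional materials the way a statsmodels
user would expect: construct from a config (or a sweep case), call
``pressurize()`` to obtain the in vivo state, then ``simulate_air_puff()``
or ``simulate_falling_mass()`` for a :class:`SimulationResult` carrying the
trajectory, the work ledger and the detected events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import SweepCase
from .cavity import PressurizedEye, pressurize, recover_zero_pressure
from .constitutive import MaterialParams
from .dynamics import (AirPuffProfile, FallingMassConfig, Trajectory,
                       apex_kinematics, run_air_puff, run_falling_mass)
from .energetics import WorkLedger, build_work_ledger, find_intersection
from .events import (ApplanationNotReached, first_applanation_time,
                     max_velocity_time)
from .geometry import EyeGeometryConfig, EyeMesh, build_eye_mesh

__all__ = ["EyeModel", "SimulationResult", "default_materials"]


def default_materials(C10: float = 0.045, k1: float = 0.027,
                      k2: float = 180.0) -> dict[str, MaterialParams]:
    """Regional material map: HGO cornea/limbus, Neo-Hookean sclera.

    The corneal parameters default to the baseline parameter set
    (C10 = 0.045 MPa, k1 = 0.027 MPa, k2 = 180); the limbus shares them
    with a single circumferential fibre family, and the sclera uses
    C10 = 0.3 MPa — both conventions, see docs/methods.md.
    """
    corneal = MaterialParams(C10, k1, k2)
    return {"cornea": corneal, "limbus": corneal, "sclera": MaterialParams(0.3)}


class EyeModel:
    """Reduced-order biomechanical eye at a given IOP.

    Parameters
    ----------
    geometry : EyeGeometryConfig, optional
    materials : dict mapping 'cornea' | 'limbus' | 'sclera' to MaterialParams
    iop_mmhg : float
        In vivo IOP; the measured geometry is interpreted as the state
        loaded by this pressure, so pressurization first recovers the
        zero-pressure configuration.
    """

    def __init__(self, geometry: EyeGeometryConfig | None = None,
                 materials: dict | None = None, iop_mmhg: float = 15.0):
        self.geometry = geometry or EyeGeometryConfig()
        self.materials = materials or default_materials()
        self.iop_mmhg = float(iop_mmhg)
        self.mesh: EyeMesh = build_eye_mesh(self.geometry)
        self._zero_pressure: EyeMesh | None = None
        self._pressurized: PressurizedEye | None = None

    @classmethod
    def from_case(cls, case: SweepCase, mesh_resolution: int = 1) -> "EyeModel":
        """Build the model for one sweep-design row."""
        geo = EyeGeometryConfig(cct_um=case.cct_um, mesh_resolution=mesh_resolution)
        return cls(geometry=geo,
                   materials=default_materials(case.C10, case.k1, case.k2),
                   iop_mmhg=case.iop_mmhg)

    # ------------------------------------------------------------- pipeline
    def zero_pressure_mesh(self, tol: float = 1e-3) -> EyeMesh:
        """Stress-free configuration recovered by fixed-point pull-back."""
        if self._zero_pressure is None:
            self._zero_pressure = recover_zero_pressure(
                self.mesh, self.materials, self.iop_mmhg, tol=tol)
        return self._zero_pressure

    def pressurize(self, n_increments: int = 8) -> PressurizedEye:
        """Inflate the zero-pressure configuration back to the in vivo IOP,
        accumulating the work of the IOP on the anterior corneal surface."""
        if self._pressurized is None:
            self._pressurized = pressurize(
                self.zero_pressure_mesh(), self.materials, self.iop_mmhg,
                n_increments=n_increments)
        return self._pressurized

    def simulate_air_puff(self, profile: AirPuffProfile | None = None,
                          **kwargs) -> "SimulationResult":
        profile = profile or AirPuffProfile()
        traj = run_air_puff(self.pressurize(), profile, **kwargs)
        return SimulationResult(self, traj)

    def simulate_falling_mass(self, config: FallingMassConfig | None = None,
                              **kwargs) -> "SimulationResult":
        config = config or FallingMassConfig()
        traj = run_falling_mass(self.pressurize(), config, **kwargs)
        return SimulationResult(self, traj)


@dataclass
class SimulationResult:
    """Trajectory plus derived energetics and events of one loading run."""

    model: EyeModel
    trajectory: Trajectory
    _ledger: WorkLedger | None = field(default=None, repr=False)

    @property
    def ledger(self) -> WorkLedger:
        if self._ledger is None:
            self._ledger = build_work_ledger(
                self.trajectory, initial_work=self.model.pressurize().initial_work)
        return self._ledger

    def apex_trace(self):
        return apex_kinematics(self.trajectory)

    def events(self) -> dict:
        """Event times (ms, relative to load onset) and intersection data."""
        onset = self.trajectory.load_onset_ms
        out = {"load_onset_ms": onset}
        try:
            out["t_maxvel_ms"] = max_velocity_time(self.apex_trace()) - onset
        except ValueError:
            out["t_maxvel_ms"] = np.nan
        try:
            out["t_applanation_ms"] = first_applanation_time(
                self.trajectory, from_time=onset) - onset
        except (ApplanationNotReached, ValueError):
            out["t_applanation_ms"] = np.nan
        inter = find_intersection(self.ledger)
        out["t_intersection_ms"] = (inter.primary_time - onset
                                    if inter.found else np.nan)
        out["work_at_intersection_mJ"] = inter.primary_value
        out["intersection_ratio"] = inter.ratio_to_initial
        return out

    def summary(self) -> str:
        ev = self.events()
        led = self.ledger
        lines = [
            f"{self.trajectory.scenario} simulation "
            f"({self.trajectory.n_increments} increments, "
            f"IOP {self.model.iop_mmhg:g} mmHg)",
            "-" * 56,
            f"initial work of IOP:      {led.initial_work:.5f} mJ",
            f"t(max apex velocity):     {ev['t_maxvel_ms']:.3f} ms after onset",
            f"t(work intersection):     {ev['t_intersection_ms']:.3f} ms after onset",
            f"work at intersection:     {ev['work_at_intersection_mJ']:.5f} mJ "
            f"({ev['intersection_ratio']:.2f} of initial)",
        ]
        if not np.isnan(ev["t_applanation_ms"]):
            lines.append(
                f"t(first applanation):     {ev['t_applanation_ms']:.3f} ms after onset")
        lines.append(
            f"peak cavity pressure:     "
            f"{float(np.max(self.trajectory.cavity_pressure_mmhg)):.2f} mmHg")
        return "\n".join(lines)
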