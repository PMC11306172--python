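"""Work bookkeeping on the anterior corneal surface.

The mechanical work exchanged on the anterior corneal surface is accumulated
nodally with the trapezoidal rule over output increments: at increment j the
y-force on node i is the acting pressure times the node's current
(y-projected) area, and the work increment is the average of consecutive
forces times the nodal y-displacement increment,

    W = sum_j sum_i (F_i^j + F_i^(j-1)) / 2 * (u_i^j - u_i^(j-1)).

Two channels are kept: the work of the IOP (the spatially uniform cavity
pressure; positive while the fluid inflates the wall, decreasing while an
external load indents it) and the work of the air puff (the non-uniform jet
pressure).  For the falling-mass scenario the external channel is the cube's
mechanical energy instead.  All series live on the trajectory's output time
base, in mJ.

Bookkeeping is restricted to the anterior corneal node set — the surface the
tonometer camera actually tracks — never the posterior surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import mmhg_to_mpa

__all__ = [
    "WorkLedger",
    "IntersectionResult",
    "trapezoidal_nodal_work",
    "work_iop",
    "work_air",
    "mass_energies",
    "build_work_ledger",
    "find_intersection",
    "find_crossings",
]


def trapezoidal_nodal_work(forces: np.ndarray, displacements: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal work (mJ) of nodal force histories over nodal
    displacement histories, both shaped (T, n_nodes); W[0] = 0."""
    forces = np.asarray(forces, dtype=float)
    displacements = np.asarray(displacements, dtype=float)
    if forces.shape != displacements.shape or forces.ndim != 2:
        raise ValueError("forces and displacements must share shape (T, n)")
    f_mid = 0.5 * (forces[1:] + forces[:-1])
    du = np.diff(displacements, axis=0)
    inc = (f_mid * du).sum(axis=1)
    return np.concatenate([[0.0], np.cumsum(inc)])


def _check_trajectory(trajectory) -> None:
    t = np.asarray(trajectory.times)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("trajectory must carry at least two strictly "
                         "increasing output increments")


def work_iop(trajectory, mesh=None, initial_work: float = 0.0) -> np.ndarray:
    """Cumulative signed work of the IOP (mJ) on the anterior corneal
    surface along y, offset by the work already accumulated during
    pressurization (``initial_work``)."""
    _check_trajectory(trajectory)
    mesh = mesh if mesh is not None else trajectory.mesh
    ant = mesh.anterior_nodes
    T = trajectory.n_increments
    F = np.empty((T, len(ant)))
    for j in range(T):
        a_proj = mesh.anterior_nodal_area_array(trajectory.coords[j], projected=True)
        F[j] = mmhg_to_mpa(trajectory.cavity_pressure_mmhg[j]) * a_proj[ant]
    y = trajectory.coords[:, ant, 1]
    return initial_work + trapezoidal_nodal_work(F, y)


def work_air(trajectory, mesh=None) -> np.ndarray:
    """Cumulative work of the air-puff pressure (mJ) on the anterior corneal
    surface along y (the jet pushes inward, so the channel grows during the
    inward phase)."""
    _check_trajectory(trajectory)
    if trajectory.air_pressure is None:
        raise ValueError("trajectory carries no air-pressure history")
    mesh = mesh if mesh is not None else trajectory.mesh
    ant = mesh.anterior_nodes
    T = trajectory.n_increments
    F = np.empty((T, len(ant)))
    for j in range(T):
        a_proj = mesh.anterior_nodal_area_array(trajectory.coords[j], projected=True)
        F[j] = -trajectory.air_pressure[j, ant] * a_proj[ant]
    y = trajectory.coords[:, ant, 1]
    return trapezoidal_nodal_work(F, y)


def mass_energies(trajectory, config=None):
    """(kinetic, potential, total) mechanical energy series of the falling
    mass (mJ); the potential-energy datum is the face height at first contact
    with the undeformed apex."""
    if trajectory.mass_y is None:
        raise ValueError("not a falling-mass trajectory")
    cfg = config if config is not None else trajectory.config
    y_datum = trajectory.coords[0, trajectory.mesh.apex_node, 1]
    ke = 0.5 * cfg.mass_g * trajectory.mass_v ** 2
    pe = cfg.mass_g * cfg.gravity * (trajectory.mass_y - y_datum)
    return ke, pe, ke + pe


@dataclass
class WorkLedger:
    """Energy/work time series of one simulation, all in mJ on a common
    output time base (ms)."""

    time_ms: np.ndarray
    work_iop: np.ndarray
    eye_internal: np.ndarray          # strain + cavity potential, rel. to t=0
    cornea_internal: np.ndarray
    eye_kinetic: np.ndarray
    work_air: np.ndarray | None = None
    mass_kinetic: np.ndarray | None = None
    mass_potential: np.ndarray | None = None
    mass_total: np.ndarray | None = None
    transferred: np.ndarray | None = None   # energy given up by the mass
    contact: np.ndarray | None = None
    initial_work: float = 0.0
    load_onset_ms: float = 0.0
    scenario: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_ms": self.time_ms, "work_iop_mJ": self.work_iop,
                "eye_internal_mJ": self.eye_internal,
                "cornea_internal_mJ": self.cornea_internal,
                "eye_kinetic_mJ": self.eye_kinetic}
        for name, series in (("work_air_mJ", self.work_air),
                             ("mass_kinetic_mJ", self.mass_kinetic),
                             ("mass_potential_mJ", self.mass_potential),
                             ("mass_total_mJ", self.mass_total),
                             ("transferred_mJ", self.transferred),
                             ("contact_mJ", self.contact)):
            if series is not None:
                cols[name] = series
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_work_ledger(trajectory, initial_work: float = 0.0) -> WorkLedger:
    """Assemble the full work/energy ledger of a trajectory."""
    mesh = trajectory.mesh
    w_iop = work_iop(trajectory, mesh, initial_work=initial_work)
    e = trajectory.energies
    eye_internal = e["eye_internal"] - e["eye_internal"][0]
    cornea = e["cornea_strain"] - e["cornea_strain"][0]
    ledger = WorkLedger(
        time_ms=trajectory.times, work_iop=w_iop, eye_internal=eye_internal,
        cornea_internal=cornea, eye_kinetic=e["eye_kinetic"],
        initial_work=initial_work, load_onset_ms=trajectory.load_onset_ms,
        scenario=trajectory.scenario)
    if trajectory.air_pressure is not None:
        ledger.work_air = work_air(trajectory, mesh)
    if trajectory.mass_y is not None:
        ke, pe, tot = mass_energies(trajectory)
        ledger.mass_kinetic, ledger.mass_potential, ledger.mass_total = ke, pe, tot
        ledger.transferred = tot[0] - tot
        ledger.contact = e.get("contact")
    return ledger


@dataclass
class IntersectionResult:
    """Crossings of the internal and external work curves.

    The primary crossing is the first one after load onset (the inward
    phase); for the air-puff scenario a second crossing during rebound may
    follow and is reported but unused by the estimator.
    """

    found: bool
    times_ms: list = field(default_factory=list)
    values_mJ: list = field(default_factory=list)
    initial_work: float = 0.0

    @property
    def primary_time(self) -> float:
        return self.times_ms[0] if self.found else np.nan

    @property
    def primary_value(self) -> float:
        return self.values_mJ[0] if self.found else np.nan

    @property
    def ratio_to_initial(self) -> float:
        if not self.found or self.initial_work == 0.0:
            return np.nan
        return self.primary_value / self.initial_work


def find_crossings(t: np.ndarray, w1: np.ndarray, w2: np.ndarray):
    """Sub-increment crossing times/values of two curves by linear
    interpolation (sign changes of w1 - w2)."""
    g = np.asarray(w1, dtype=float) - np.asarray(w2, dtype=float)
    times, values = [], []
    s = np.sign(g)
    for j in np.nonzero(s[:-1] * s[1:] < 0)[0]:
        frac = g[j] / (g[j] - g[j + 1])
        times.append(float(t[j] + frac * (t[j + 1] - t[j])))
        values.append(float(w1[j] + frac * (w1[j + 1] - w1[j])))
    for j in np.nonzero(g == 0.0)[0]:        # exact touches
        times.append(float(t[j]))
        values.append(float(w1[j]))
    order = np.argsort(times)
    return [times[k] for k in order], [values[k] for k in order]


def find_intersection(ledger: WorkLedger, load_onset: float | None = None) -> IntersectionResult:
    """Locate where the work of the IOP meets the external work channel
    (air-puff work, or the mass's transferred energy), after load onset."""
    onset = ledger.load_onset_ms if load_onset is None else load_onset
    if ledger.work_air is not None:
        other = ledger.work_air
    elif ledger.transferred is not None:
        other = ledger.transferred
    else:
        raise ValueError("ledger has neither an air-work nor a mass channel")
    times, values = find_crossings(ledger.time_ms, ledger.work_iop, other)
    keep = [(tt, vv) for tt, vv in zip(times, values) if tt >= onset]
    if not keep:
        return IntersectionResult(found=False, initial_work=ledger.initial_work)
    return IntersectionResult(
        found=True, times_ms=[k[0] for k in keep], values_mJ=[k[1] for k in keep],
        initial_work=ledger.initial_work)
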