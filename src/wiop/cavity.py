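"""Fluid-cavity pressurization and zero-pressure (pre-stress) recovery.

The measured (reference) eye geometry is already loaded by the IOP, so each
simulation first recovers the stress-free (zero-pressure) configuration: the
geometry which, inflated to the in vivo IOP, reproduces the reference nodal
positions.  The classic fixed-point pull-back is used,

    X0^(k+1) = X0^(k) - (inflate(X0^(k), IOP) - X_ref),

iterated until the round-trip error drops below tolerance.

Pressurization itself is performed as a sequence of quasi-static equilibria
at linearly ramped pressure; the Eq.-style trapezoidal work of the IOP on the
anterior corneal surface is accumulated over the increments, which defines
the "initial work of the IOP" used by the calibration.  After pressurization
the humors are handed to the stiff pressure-volume cavity law
(:class:`wiop.dynamics.CavityState`) with the pressurized volume as
reference, so transient indentation raises the chamber pressure uniformly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from ._solver import MembraneSystem
from .constitutive import MaterialParams
from .dynamics import CavityState
from .energetics import trapezoidal_nodal_work
from .geometry import EyeMesh
from .units import mmhg_to_mpa

__all__ = ["PressurizedEye", "pressurize", "recover_zero_pressure",
           "ZeroPressureDivergence"]


class ZeroPressureDivergence(RuntimeError):
    """Fixed-point pull-back residual grew for three consecutive iterations."""

    def __init__(self, history):
        super().__init__(
            "zero-pressure recovery diverged; residual history: "
            + ", ".join(f"{r:.3e}" for r in history))
        self.history = list(history)


@dataclass
class PressurizedEye:
    """Quasi-static equilibrium of the eye at the target IOP.

    ``system`` is built on the zero-pressure reference, so its strain
    energies are measured from the stress-free state; ``coords`` is the
    pressurized geometry.  ``work_iop_series`` is the cumulative work of the
    IOP on the anterior corneal surface over the pressurization increments;
    its final value is the initial work of the IOP.
    """

    system: MembraneSystem
    coords: np.ndarray
    iop_mmhg: float
    cavity: CavityState
    pressures_mmhg: np.ndarray        # ramp values, one per increment
    work_iop_series: np.ndarray       # mJ, cumulative over increments
    coords_history: np.ndarray        # (K+1, N, 2) increment states
    residual_kinetic_fraction: float = 0.0   # quasi-static: identically 0

    @property
    def initial_work(self) -> float:
        """Work of the IOP at the end of pressurization (mJ)."""
        return float(self.work_iop_series[-1])

    @property
    def apex_displacement(self) -> float:
        """Apex displacement magnitude from zero pressure to pressurized (mm)."""
        a = self.system.mesh.apex_node
        return float(abs(self.coords[a, 1] - self.system.mesh.nodes[a, 1]))

    @property
    def max_anterior_displacement(self) -> float:
        ant = self.system.mesh.anterior_nodes
        d = self.coords[ant] - self.system.mesh.nodes[ant]
        return float(np.max(np.hypot(d[:, 0], d[:, 1])))

    def internal_energy(self) -> float:
        energies, _ = self.system.strain_energy_forces(self.coords)
        return energies["total"]

    def save(self, path) -> None:
        """Checkpoint the pressurized state (npz) so sweeps can reuse it."""
        np.savez(path, coords=self.coords, iop=self.iop_mmhg,
                 nodes=self.system.mesh.nodes,
                 reference_volume=self.cavity.reference_volume,
                 bulk=self.cavity.bulk_stiffness_mpa,
                 pressures=self.pressures_mmhg, work=self.work_iop_series,
                 history=self.coords_history)


def pressurize(mesh: EyeMesh, materials: dict[str, MaterialParams],
               target_iop_mmhg: float, n_increments: int = 8,
               cavity_bulk_mpa: float = 20.0,
               system: MembraneSystem | None = None) -> PressurizedEye:
    """Inflate a zero-pressure mesh to the target IOP through quasi-static
    increments.

    Returns the equilibrated state with the IOP-work path.  With
    ``target_iop_mmhg = 0`` the displacement field is identically zero.
    """
    if target_iop_mmhg < 0:
        raise ValueError("IOP must be non-negative")
    system = system or MembraneSystem(mesh, materials)
    pressures = np.linspace(0.0, target_iop_mmhg, n_increments + 1)
    coords_hist = np.empty((n_increments + 1,) + mesh.nodes.shape)
    coords_hist[0] = mesh.nodes
    states = system.ramp_solve(mesh.nodes.copy(),
                               [mmhg_to_mpa(p) for p in pressures[1:]])
    for k, xs in enumerate(states, start=1):
        coords_hist[k] = xs
    x = coords_hist[-1]

    ant = mesh.anterior_nodes
    F = np.empty((n_increments + 1, len(ant)))
    for k in range(n_increments + 1):
        a_proj = mesh.anterior_nodal_area_array(coords_hist[k], projected=True)
        F[k] = mmhg_to_mpa(pressures[k]) * a_proj[ant]
    work = trapezoidal_nodal_work(F, coords_hist[:, ant, 1])

    cavity = CavityState(reference_volume=mesh.enclosed_volume(x),
                         baseline_iop_mmhg=target_iop_mmhg,
                         bulk_stiffness_mpa=cavity_bulk_mpa)
    return PressurizedEye(system=system, coords=x, iop_mmhg=target_iop_mmhg,
                          cavity=cavity, pressures_mmhg=pressures,
                          work_iop_series=work, coords_history=coords_hist)


def _with_nodes(mesh: EyeMesh, nodes: np.ndarray) -> EyeMesh:
    """Copy of the mesh with new reference coordinates (fibre tangents are
    recomputed; thickness is a material attribute and stays)."""
    tang = nodes[mesh.elements[:, 1]] - nodes[mesh.elements[:, 0]]
    tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)
    fibre_mer = np.column_stack([tang, np.zeros(len(tang))])
    return dataclasses.replace(mesh, nodes=nodes.copy(), fibre_meridional=fibre_mer)


def recover_zero_pressure(reference_mesh: EyeMesh,
                          materials: dict[str, MaterialParams],
                          iop_mmhg: float, tol: float = 1e-3,
                          max_iter: int = 30) -> EyeMesh:
    """Recover the stress-free configuration by fixed-point pull-back.

    Postcondition (round trip): statically inflating the returned mesh to
    ``iop_mmhg`` reproduces ``reference_mesh.nodes`` within ``tol`` (max
    nodal distance).  ``iop_mmhg = 0`` returns the reference unchanged.
    """
    if iop_mmhg < 0:
        raise ValueError("IOP must be non-negative")
    if iop_mmhg == 0.0:
        return _with_nodes(reference_mesh, reference_mesh.nodes)
    X_ref = reference_mesh.nodes
    X0 = X_ref.copy()
    history = []
    grew = 0
    x_guess = X_ref
    # strongly fibre-stiffened materials need a gentler pressure ramp
    n_sub = max(2, int(np.ceil(iop_mmhg / 10.0)))
    sub_pressures = mmhg_to_mpa(np.linspace(0.0, iop_mmhg, n_sub + 1)[1:])
    for _ in range(max_iter):
        mesh_k = _with_nodes(reference_mesh, X0)
        system = MembraneSystem(mesh_k, materials)
        x_inf = system.ramp_solve(x_guess, sub_pressures)[-1]
        err = float(np.max(np.hypot(*(x_inf - X_ref).T)))
        history.append(err)
        if err <= tol:
            return mesh_k
        if len(history) >= 2 and err > history[-2]:
            grew += 1
            if grew >= 3:
                raise ZeroPressureDivergence(history)
        else:
            grew = 0
        X0 = X0 - (x_inf - X_ref)
        X0[reference_mesh.apex_node, 0] = 0.0
        X0[reference_mesh.clamped_nodes] = X_ref[reference_mesh.clamped_nodes]
        x_guess = x_inf
    raise ZeroPressureDivergence(history)
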