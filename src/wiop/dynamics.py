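"""Explicit transient simulation of the two loading scenarios.

Scenario 1 — falling mass: a rigid 2.02 g cube (1.5 mm side) dropped from
8 mm above the corneal apex, coupled to the cornea through a frictionless
penalty contact.  Scenario 2 — air puff: a prescribed axisymmetric pressure
field (Gaussian footprint, smooth temporal pulse) standing in for the
tonometer jet.  Both start from a statically pressurized state; the humors
respond through the stiff fluid-cavity law, so indentation raises the
chamber pressure uniformly.

Integration is velocity-Verlet (explicit central difference) with lumped
masses and a CFL-based stable step; no damping is applied while a load acts,
so the mass-scenario energy balance closes without dissipation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solver import MembraneSystem
from .units import GRAVITY, mmhg_to_mpa, mpa_to_mmhg

__all__ = [
    "FallingMassConfig",
    "AirPuffProfile",
    "CavityState",
    "Trajectory",
    "run_falling_mass",
    "run_air_puff",
    "apex_kinematics",
    "cavity_pressure",
]


@dataclass
class FallingMassConfig:
    """Rigid falling-mass load (g, mm, mm/ms^2)."""

    mass_g: float = 2.02
    cube_side: float = 1.5
    drop_height: float = 8.0
    gravity: float = GRAVITY
    #: total penalty stiffness of the contact, N/mm (sets penetration < 2% CCT)
    contact_stiffness: float = 40.0

    def __post_init__(self) -> None:
        for name in ("mass_g", "cube_side", "drop_height", "gravity",
                     "contact_stiffness"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def punch_radius(self) -> float:
        """Radius of the equal-area circular footprint of the cube face."""
        return self.cube_side / np.sqrt(np.pi)


@dataclass
class AirPuffProfile:
    """Prescribed air-jet surface pressure.

    The spatial footprint is Gaussian, p(r) = p_peak * exp(-(r/footprint)^2),
    which decays below 1% of peak beyond ~2.1 footprint radii; the temporal
    shape is a named smooth pulse over ``duration_ms``.  ``coupling`` >= 0
    optionally increases the local pressure where the surface has receded
    (deformation-dependent jet loading); 0 disables it.
    """

    onset_ms: float = 5.0
    duration_ms: float = 30.0
    peak_pressure_mmhg: float = 100.0
    footprint_radius: float = 1.5
    shape: str = "sin2"
    coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.peak_pressure_mmhg < 0:
            raise ValueError("peak pressure must be non-negative")
        if self.shape not in ("sin2", "triangle"):
            raise ValueError(f"unknown temporal shape {self.shape!r}")

    def temporal(self, t: float) -> float:
        """Dimensionless pulse amplitude at time ``t`` (ms, absolute)."""
        tau = (t - self.onset_ms) / self.duration_ms
        if tau <= 0.0 or tau >= 1.0:
            return 0.0
        if self.shape == "sin2":
            return float(np.sin(np.pi * tau) ** 2)
        return float(1.0 - abs(2.0 * tau - 1.0))

    def spatial(self, r: np.ndarray) -> np.ndarray:
        return np.exp(-(r / self.footprint_radius) ** 2)


@dataclass
class CavityState:
    """Hydrostatic fluid cavity: stiff linear pressure-volume law
    P = IOP + K_f (V0 - V) / V0 approximating the incompressible humors."""

    reference_volume: float                  # mm^3, at end of pressurization
    baseline_iop_mmhg: float
    bulk_stiffness_mpa: float = 20.0

    def pressure_mpa(self, volume: float) -> float:
        return (mmhg_to_mpa(self.baseline_iop_mmhg)
                + self.bulk_stiffness_mpa
                * (self.reference_volume - volume) / self.reference_volume)


def cavity_pressure(volume: float, state: CavityState) -> float:
    """Cavity pressure (mmHg) at a given cavity volume (mm^3)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return mpa_to_mmhg(state.pressure_mpa(volume))


@dataclass
class Trajectory:
    """Output time series of a transient run (one row per output increment)."""

    times: np.ndarray                 # ms
    coords: np.ndarray                # (T, N, 2) nodal positions
    cavity_pressure_mmhg: np.ndarray  # (T,)
    energies: dict = field(default_factory=dict)   # name -> (T,) series, mJ
    air_pressure: np.ndarray | None = None         # (T, N) MPa on anterior nodes
    mass_y: np.ndarray | None = None               # cube lower-face height, mm
    mass_v: np.ndarray | None = None               # mm/ms
    load_onset_ms: float = 0.0
    scenario: str = ""
    mesh: object = field(default=None, repr=False)
    config: object = field(default=None, repr=False)

    @property
    def apex_y(self) -> np.ndarray:
        return self.coords[:, self.mesh.apex_node, 1]

    @property
    def n_increments(self) -> int:
        return len(self.times)


class _RigidMass:
    """Rigid cube state: lower-face height and velocity."""

    def __init__(self, config: FallingMassConfig, y_apex: float):
        self.cfg = config
        self.y = y_apex + config.drop_height
        self.v = 0.0
        self.datum = y_apex            # PE reference: face at first contact


def _contact_forces(x, mass: _RigidMass, mesh, k_node):
    """Penalty contact between the cube face and anterior corneal nodes.

    Returns (nodal y-forces, reaction on mass, spring energy, max penetration).
    """
    pen = np.zeros(len(x))
    idx = mesh.anterior_nodes
    r = x[idx, 0]
    inside = r <= mass.cfg.punch_radius
    p = x[idx, 1] - mass.y
    active = inside & (p > 0.0)
    f_nodes = np.zeros(len(x))
    ids = idx[active]
    pen_a = p[active]
    f = k_node[ids] * pen_a
    f_nodes[ids] = -f
    return f_nodes, float(f.sum()), float(0.5 * (k_node[ids] * pen_a ** 2).sum()), \
        float(pen_a.max()) if len(pen_a) else 0.0


def _integrate(system: MembraneSystem, x0: np.ndarray, t_end: float,
               dt_out: float, cavity: CavityState,
               profile: AirPuffProfile | None = None,
               mass: _RigidMass | None = None,
               damping: float = 0.0, damping_until: float = 0.0,
               dt_max: float = np.inf) -> Trajectory:
    mesh = system.mesh
    free = system.free_mask
    m_node = np.maximum(system.node_mass, 1e-9)[:, None]
    x = x0.copy()
    v = np.zeros_like(x)

    ant = mesh.anterior_nodes
    k_node = np.zeros(mesh.n_nodes)
    if mass is not None:
        a_ref = mesh.anterior_nodal_area_array()
        sel = mesh.nodes[ant, 0] <= mass.cfg.punch_radius
        w = a_ref[ant[sel]]
        k_node[ant[sel]] = mass.cfg.contact_stiffness * w / w.sum()

    def forces(x, t, mass_state):
        energies, F = system.strain_energy_forces(x)
        V = mesh.enclosed_volume(x)
        P = cavity.pressure_mpa(V)
        F += P * mesh.enclosed_volume_gradient(x)
        u_cav = (-mmhg_to_mpa(cavity.baseline_iop_mmhg) * (V - cavity.reference_volume)
                 + 0.5 * cavity.bulk_stiffness_mpa
                 * (V - cavity.reference_volume) ** 2 / cavity.reference_volume)
        p_air = None
        if profile is not None:
            amp = profile.temporal(t)
            p_air = np.zeros(mesh.n_nodes)
            if amp > 0.0:
                a_proj = mesh.anterior_nodal_area_array(x, projected=True)
                p_loc = mmhg_to_mpa(profile.peak_pressure_mmhg) * amp \
                    * profile.spatial(x[ant, 0])
                if profile.coupling:
                    recession = np.maximum(x0[ant, 1] - x[ant, 1], 0.0)
                    p_loc = p_loc * (1.0 + profile.coupling * recession)
                p_air[ant] = p_loc
                F[ant, 1] -= p_loc * a_proj[ant]
        f_mass = e_contact = pen = 0.0
        if mass_state is not None:
            fc, f_mass, e_contact, pen = _contact_forces(x, mass_state, mesh, k_node)
            F[:, 1] += fc
        return F, energies, P, u_cav, p_air, f_mass, e_contact, pen

    # stable step: membrane/bending CFL plus contact and cavity stiffness
    def compute_dt(x):
        dt = system.stable_dt(x)
        a_proj = mesh.projected_nodal_areas(x)
        k_cav = cavity.bulk_stiffness_mpa / cavity.reference_volume * a_proj ** 2
        k_extra = k_cav + k_node
        mask = k_extra > 0
        if mask.any():
            dt = min(dt, 0.25 * np.min(
                2.0 / np.sqrt(k_extra[mask] / system.node_mass[mask])))
        return min(dt, dt_max)

    n_out = int(np.floor(t_end / dt_out)) + 1
    out_times = np.arange(n_out) * dt_out
    T = len(out_times)
    N = mesh.n_nodes
    rec = {
        "coords": np.empty((T, N, 2)),
        "cavity_p": np.empty(T),
        "air": np.empty((T, N)) if profile is not None else None,
        "mass_y": np.empty(T) if mass is not None else None,
        "mass_v": np.empty(T) if mass is not None else None,
    }
    e_names = ("eye_strain", "cornea_strain", "cavity", "eye_kinetic",
               "contact", "mass_kinetic", "mass_potential")
    rec_e = {k: np.zeros(T) for k in e_names}

    t = 0.0
    dt = compute_dt(x)
    F, energies, P, u_cav, p_air, f_mass, e_contact, pen = forces(x, t, mass)
    a = np.where(free, F / m_node, 0.0)
    cct = mesh.config.cct_mm if mesh.config is not None else 0.5
    i_out = 0
    steps = 0
    while True:
        if t + 1e-9 >= out_times[i_out]:
            rec["coords"][i_out] = x
            rec["cavity_p"][i_out] = mpa_to_mmhg(P)
            if rec["air"] is not None:
                rec["air"][i_out] = p_air if p_air is not None else 0.0
            if mass is not None:
                rec["mass_y"][i_out] = mass.y
                rec["mass_v"][i_out] = mass.v
                rec_e["mass_kinetic"][i_out] = 0.5 * mass.cfg.mass_g * mass.v ** 2
                rec_e["mass_potential"][i_out] = (mass.cfg.mass_g * mass.cfg.gravity
                                                  * (mass.y - mass.datum))
            rec_e["eye_strain"][i_out] = energies["total"]
            rec_e["cornea_strain"][i_out] = energies["cornea"]
            rec_e["cavity"][i_out] = u_cav
            rec_e["eye_kinetic"][i_out] = float(
                0.5 * (system.node_mass[:, None] * v ** 2).sum())
            rec_e["contact"][i_out] = e_contact
            i_out += 1
            if i_out >= T:
                break
        # velocity-Verlet step (kick-drift-kick); trim the step so output
        # times are hit exactly
        dt_step = min(dt, out_times[i_out] - t)
        c = damping if t < damping_until else 0.0
        if c:
            v *= np.exp(-0.5 * c * dt_step)
        v += 0.5 * dt_step * a
        x = x + dt_step * v
        if mass is not None:
            mass.v += 0.5 * dt_step * (f_mass / mass.cfg.mass_g - mass.cfg.gravity)
            mass.y += dt_step * mass.v
        t += dt_step
        F, energies, P, u_cav, p_air, f_mass, e_contact, pen = forces(x, t, mass)
        if pen > 0.10 * cct:
            raise RuntimeError(
                f"contact penetration {pen:.4f} mm exceeds 10% of CCT at "
                f"t={t:.2f} ms; reduce the time step or raise contact stiffness")
        a = np.where(free, F / m_node, 0.0)
        v += 0.5 * dt_step * a
        if c:
            v *= np.exp(-0.5 * c * dt_step)
        if mass is not None:
            mass.v += 0.5 * dt_step * (f_mass / mass.cfg.mass_g - mass.cfg.gravity)
        steps += 1
        if steps % 500 == 0:
            if not np.isfinite(x).all():
                raise FloatingPointError("integration diverged (non-finite state)")
            dt = compute_dt(x)

    energies_out = dict(rec_e)
    energies_out["eye_internal"] = rec_e["eye_strain"] + rec_e["cavity"]
    energies_out["mass_total"] = rec_e["mass_kinetic"] + rec_e["mass_potential"]
    return Trajectory(
        times=out_times, coords=rec["coords"], cavity_pressure_mmhg=rec["cavity_p"],
        energies=energies_out, air_pressure=rec["air"],
        mass_y=rec["mass_y"], mass_v=rec["mass_v"], mesh=mesh)


def run_falling_mass(pressurized, config: FallingMassConfig | None = None,
                     t_end: float | None = None, dt_out: float = 0.25) -> Trajectory:
    """Drop the rigid cube onto the pressurized eye and integrate through
    impact and rebound.

    ``pressurized`` is the equilibrium state from
    :func:`wiop.cavity.pressurize`.  The trajectory starts at release
    (t = 0); free fall lasts sqrt(2 h / g), after which contact transfers the
    cube's mechanical energy to the eye with no dissipation.
    """
    config = config or FallingMassConfig()
    system = pressurized.system
    y_apex = pressurized.coords[system.mesh.apex_node, 1]
    mass = _RigidMass(config, y_apex)
    t_fall = np.sqrt(2.0 * config.drop_height / config.gravity)
    if t_end is None:
        t_end = t_fall + 25.0
    traj = _integrate(system, pressurized.coords, t_end, dt_out,
                      pressurized.cavity, mass=mass)
    traj.scenario = "falling_mass"
    traj.config = config
    traj.load_onset_ms = t_fall
    return traj


def run_air_puff(pressurized, profile: AirPuffProfile | None = None,
                 t_end: float | None = None,
                 dt_out: float = 30.0 / 140.0) -> Trajectory:
    """Apply the air-puff pressure pulse to the pressurized eye.

    The default output increment matches the tonometer camera (140 frames
    over the 30 ms pulse).  The apex moves inward, peaks in velocity,
    decelerates to the highest concavity and rebounds while the cavity
    pressure rises above the baseline IOP.
    """
    profile = profile or AirPuffProfile()
    system = pressurized.system
    if t_end is None:
        t_end = profile.onset_ms + profile.duration_ms + 2.0
    traj = _integrate(system, pressurized.coords, t_end, dt_out,
                      pressurized.cavity, profile=profile,
                      damping=1.0, damping_until=max(profile.onset_ms - 1.0, 0.0))
    traj.scenario = "air_puff"
    traj.config = profile
    traj.load_onset_ms = profile.onset_ms
    return traj


def apex_kinematics(trajectory: Trajectory):
    """Apex velocity trace from a trajectory (central differences of the apex
    position; inward motion positive)."""
    from .events import VelocityTrace

    if trajectory.n_increments < 3:
        raise ValueError("trajectory must have at least 3 increments")
    t = trajectory.times
    y = trajectory.apex_y
    v = np.gradient(y, t)            # central differences inside, one-sided ends
    return VelocityTrace(
        time_ms=t, velocity=-v, displacement=y[0] - y,
        provenance="simulated", trajectory=trajectory)
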