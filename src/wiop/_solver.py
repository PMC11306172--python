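"""Reduced-order axisymmetric membrane solver (internal).

Each meridian segment, revolved about the y axis, is an incompressible
plane-stress membrane frustum carrying the regional hyperelastic law; a
discrete meridional bending penalty (turning-angle springs scaled by the
flexural rigidity E t^3 / 12) regularises the membrane against compressive
wrinkling and gives the central cornea a finite flattening response.  The
humors are a hydrostatic fluid cavity: spatially uniform pressure acting on
the enclosed volume through its analytic gradient.

Quasi-static states (pressurization, zero-pressure pull-back) are obtained
by minimising total potential energy with analytic gradients (L-BFGS);
transient loading scenarios use explicit velocity-Verlet integration in
``dynamics``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .constitutive import MaterialParams, membrane_energy_derivs
from .geometry import EyeMesh, REGION_CORNEA, REGION_LIMBUS, REGION_SCLERA
from .units import TISSUE_DENSITY

__all__ = ["MembraneSystem", "StaticSolveError"]

#: fibre-family counts (meridional, circumferential) per region
_REGION_FAMILIES = {
    REGION_CORNEA: (1, 1),
    REGION_LIMBUS: (0, 1),
    REGION_SCLERA: (0, 0),
}


class StaticSolveError(RuntimeError):
    """Quasi-static equilibrium solve failed to converge."""


@dataclass
class _RegionArrays:
    C10: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    n_mer: np.ndarray
    n_circ: np.ndarray


class MembraneSystem:
    """Force/energy assembly for one reference configuration of the eye.

    The reference configuration (``mesh.nodes``) defines element rest
    lengths, rest radii, reference volumes and rest turning angles.  After a
    zero-pressure pull-back a new ``MembraneSystem`` is built on the updated
    reference.
    """

    def __init__(self, mesh: EyeMesh, materials: dict[str, MaterialParams],
                 density: float = TISSUE_DENSITY,
                 bending_modulus_factor: float = 6.0):
        self.mesh = mesh
        self.materials = materials
        self.density = density

        X = mesh.nodes
        e = mesh.elements
        self.L0 = np.hypot(*(X[e[:, 1]] - X[e[:, 0]]).T)
        self.Rsum0 = X[e[:, 0], 0] + X[e[:, 1], 0]
        self.A0 = np.pi * self.Rsum0 * self.L0          # reference element area
        self.V0e = self.A0 * mesh.thickness             # reference element volume

        n_e = len(e)
        arr = _RegionArrays(*(np.zeros(n_e) for _ in range(3)),
                            np.zeros(n_e, dtype=int), np.zeros(n_e, dtype=int))
        for code, name in ((REGION_CORNEA, "cornea"), (REGION_LIMBUS, "limbus"),
                           (REGION_SCLERA, "sclera")):
            mask = mesh.region == code
            mp = materials[name]
            arr.C10[mask] = mp.C10
            arr.k1[mask] = mp.k1
            arr.k2[mask] = mp.k2
            arr.n_mer[mask], arr.n_circ[mask] = _REGION_FAMILIES[code]
        self.mat = arr

        # lumped nodal masses from reference areas and thickness
        a0 = mesh.nodal_areas()
        self.node_mass = density * mesh.node_thickness * a0
        # bending springs at interior nodes (incl. apex through a mirror ghost)
        n = mesh.n_nodes
        C10_node = np.zeros(n)
        cnt = np.zeros(n)
        np.add.at(C10_node, e[:, 0], arr.C10)
        np.add.at(C10_node, e[:, 1], arr.C10)
        np.add.at(cnt, e[:, 0], 1.0)
        np.add.at(cnt, e[:, 1], 1.0)
        C10_node /= cnt
        E_b = bending_modulus_factor * C10_node          # ~Young's modulus scale
        t_node = mesh.node_thickness
        l0 = np.empty(n)
        l0[1:-1] = 0.5 * (self.L0[:-1] + self.L0[1:])
        l0[0], l0[-1] = self.L0[0], self.L0[-1]
        r0_eff = np.maximum(X[:, 0], 0.5 * l0)
        # U_b = B (phi - phi0)^2 per node, B = pi E_b t^3 r0 / (12 l0)
        self.B = np.pi * E_b * t_node ** 3 * r0_eff / (12.0 * l0)
        self.phi0 = self._turning_angles(X)

        self.free_mask = np.ones((n, 2), dtype=bool)
        self.free_mask[mesh.apex_node, 0] = False        # symmetry: apex r = 0
        self.free_mask[mesh.clamped_nodes, :] = False

    # ------------------------------------------------------------ kinematics
    def stretches(self, x: np.ndarray):
        e = self.mesh.elements
        d = x[e[:, 1]] - x[e[:, 0]]
        slant = np.hypot(d[:, 0], d[:, 1])
        lam_s = slant / self.L0
        lam_t = (x[e[:, 0], 0] + x[e[:, 1], 0]) / self.Rsum0
        return lam_s, lam_t, d, slant

    def _turning_angles(self, x: np.ndarray) -> np.ndarray:
        """Turning angle at nodes 0..N-2 (apex uses a mirror ghost)."""
        n = self.mesh.n_nodes
        phi = np.zeros(n - 1)
        xm = x[:-2]
        x0 = x[1:-1]
        xp = x[2:]
        u = x0 - xm
        v = xp - x0
        c = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
        d = (u * v).sum(axis=1)
        phi[1:] = np.arctan2(c, d)
        # apex: ghost node is node 1 mirrored across the axis
        g = np.array([-x[1, 0], x[1, 1]])
        u0 = x[0] - g
        v0 = x[1] - x[0]
        phi[0] = np.arctan2(u0[0] * v0[1] - u0[1] * v0[0], (u0 * v0).sum())
        return phi

    # ------------------------------------------------------- energy / forces
    def strain_energy_forces(self, x: np.ndarray):
        """Return (energy_dict, F) with F = -dU/dx, shape (N, 2).

        energy_dict has keys 'total', 'membrane', 'bending', 'cornea',
        'limbus', 'sclera' (membrane energy split by region; bending folded
        into 'total' and per-region via the node's adjacent elements).
        """
        mesh = self.mesh
        e = mesh.elements
        lam_s, lam_t, d, slant = self.stretches(x)
        m = self.mat

        psi = np.zeros(len(e))
        dps = np.zeros(len(e))
        dpt = np.zeros(len(e))
        # evaluate per region to keep the constitutive kernel scalar-paramed
        for code, name in ((REGION_CORNEA, "cornea"), (REGION_LIMBUS, "limbus"),
                           (REGION_SCLERA, "sclera")):
            mask = mesh.region == code
            if not mask.any():
                continue
            mp = self.materials[name]
            nm, nc = _REGION_FAMILIES[code]
            p, ds_, dt_ = membrane_energy_derivs(
                lam_s[mask], lam_t[mask], mp.C10, mp.k1, mp.k2, nm, nc)
            psi[mask], dps[mask], dpt[mask] = p, ds_, dt_

        Ue = psi * self.V0e
        F = np.zeros_like(x)
        # meridional stretch gradient
        coef = (self.V0e * dps / (slant * self.L0))[:, None] * d
        np.add.at(F, e[:, 0], coef)
        np.add.at(F, e[:, 1], -coef)
        # circumferential stretch gradient (r components only)
        coef_t = self.V0e * dpt / self.Rsum0
        np.add.at(F[:, 0], e[:, 0], -coef_t)
        np.add.at(F[:, 0], e[:, 1], -coef_t)

        U_bend, F_bend, bend_node = self._bending_forces(x)
        F += F_bend

        energies = {"membrane": float(Ue.sum()), "bending": float(U_bend)}
        # per-region energy; nodal bending energy of node i is attributed to
        # the region of element i (nodes and elements are aligned along the
        # meridian, so this assigns each bending spring to the region it sits in)
        n_bend = len(bend_node)
        for code, name in ((REGION_CORNEA, "cornea"), (REGION_LIMBUS, "limbus"),
                           (REGION_SCLERA, "sclera")):
            mask = mesh.region == code
            energies[name] = float(Ue[mask].sum()) + float(bend_node[mask[:n_bend]].sum())
        energies["total"] = energies["membrane"] + energies["bending"]
        return energies, F

    def _bending_forces(self, x: np.ndarray):
        """Turning-angle bending energy, forces and per-node energies."""
        B = self.B
        phi = self._turning_angles(x)
        dphi = phi - self.phi0
        U_node = B[: len(phi)] * dphi ** 2
        U = U_node.sum()
        F = np.zeros_like(x)

        # interior nodes 1..N-2 (vectorized)
        xm, x0, xp = x[:-2], x[1:-1], x[2:]
        u = x0 - xm
        v = xp - x0
        c = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
        dd = (u * v).sum(axis=1)
        denom = c * c + dd * dd
        M = 2.0 * B[1: len(phi)] * dphi[1:]              # dU/dphi
        s = (M / denom)
        # dphi/dx = (d * dc/dx - c * dd/dx) / denom
        dc_dxm = np.column_stack([-v[:, 1], v[:, 0]])
        dd_dxm = -v
        dc_dx0 = np.column_stack([v[:, 1] + u[:, 1], -v[:, 0] - u[:, 0]])
        dd_dx0 = v - u
        dc_dxp = np.column_stack([-u[:, 1], u[:, 0]])
        dd_dxp = u
        for dc, ddx, sl in ((dc_dxm, dd_dxm, np.s_[:-2]),
                            (dc_dx0, dd_dx0, np.s_[1:-1]),
                            (dc_dxp, dd_dxp, np.s_[2:])):
            grad = (dd[:, None] * dc - c[:, None] * ddx) * s[:, None]
            np.add.at(F, np.arange(len(x))[sl], -grad)

        # apex node with mirror ghost
        g = np.array([-x[1, 0], x[1, 1]])
        u0 = x[0] - g
        v0 = x[1] - x[0]
        c0 = u0[0] * v0[1] - u0[1] * v0[0]
        d0 = float((u0 * v0).sum())
        den0 = c0 * c0 + d0 * d0
        M0 = 2.0 * B[0] * dphi[0]
        dc_du = np.array([v0[1], -v0[0]])
        dd_du = v0
        dc_dv = np.array([-u0[1], u0[0]])
        dd_dv = u0
        # x0 dependencies: u0 = x0 - g -> du/dx0 = I ; v0 = x1 - x0 -> dv/dx0 = -I
        grad_x0 = (d0 * (dc_du - dc_dv) - c0 * (dd_du - dd_dv)) / den0
        # x1 dependencies: dv/dx1 = I ; ghost g = (-r1, y1): du/dr1 = (+1, 0),
        # du/dy1 = (0, -1)
        grad_x1 = (d0 * dc_dv - c0 * dd_dv) / den0
        dU_dg_r = (d0 * dc_du[0] - c0 * dd_du[0]) / den0     # dphi/du_r
        dU_dg_y = (d0 * dc_du[1] - c0 * dd_du[1]) / den0
        grad_x1 = grad_x1 + np.array([dU_dg_r, -dU_dg_y])
        F[0] -= M0 * grad_x0
        F[1] -= M0 * grad_x1
        return U, F, U_node

    # ------------------------------------------------------------ statics
    def total_potential(self, x: np.ndarray, pressure_mpa: float):
        """Potential energy and gradient under a prescribed uniform cavity
        pressure (MPa): Pi = U_strain - P * V_enclosed."""
        energies, F = self.strain_energy_forces(x)
        V = self.mesh.enclosed_volume(x)
        dV = self.mesh.enclosed_volume_gradient(x)
        Pi = energies["total"] - pressure_mpa * V
        grad = -F - pressure_mpa * dV
        return Pi, grad

    def static_solve(self, x0: np.ndarray, pressure_mpa: float,
                     gtol: float = 1e-9, maxiter: int = 4000) -> np.ndarray:
        """Quasi-static equilibrium at a prescribed cavity pressure."""
        mask = self.free_mask.ravel()
        x_fixed = x0.copy()

        def fun(q):
            x = x_fixed.copy().ravel()
            x[mask] = q
            x = x.reshape(-1, 2)
            Pi, grad = self.total_potential(x, pressure_mpa)
            return Pi, grad.ravel()[mask]

        # nodal force scale against which the equilibrium residual is judged
        f_scale = max(abs(pressure_mpa), 1.33e-4) * float(
            np.mean(self.mesh.nodal_areas(x0)))
        q = x0.ravel()[mask]
        gnorm = np.inf
        for _ in range(4):        # L-BFGS line searches occasionally stall;
            res = minimize(fun, q, jac=True, method="L-BFGS-B",   # restart
                           options={"maxiter": maxiter, "gtol": gtol,
                                    "ftol": 1e-16})
            q = res.x
            gnorm = float(np.max(np.abs(res.jac)))
            if gnorm <= 1e-3 * f_scale:
                break
        if gnorm > 1e-2 * f_scale:
            raise StaticSolveError(
                f"static solve at P={pressure_mpa:.3e} MPa did not converge: "
                f"|grad|_inf={gnorm:.3e} vs force scale {f_scale:.3e}, "
                f"message={res.message}")
        x = x_fixed.ravel()
        x[mask] = q
        return x.reshape(-1, 2)

    def ramp_solve(self, x0: np.ndarray, pressures_mpa) -> list[np.ndarray]:
        """Walk a schedule of prescribed pressures quasi-statically, warm
        starting each solve from the previous state.

        When a step stalls (strongly nonlinear soft or stiff-fibre
        materials), the pressure interval is bisected adaptively up to 6
        levels before giving up.  Returns the equilibrium state at each
        scheduled pressure (same length as ``pressures_mpa``).
        """
        out = []
        x = x0
        p_prev = 0.0
        for p in pressures_mpa:
            x = self._solve_adaptive(x, p_prev, p, 0)
            out.append(x)
            p_prev = p
        return out

    def _solve_adaptive(self, x, p_from, p_to, depth):
        try:
            return self.static_solve(x, p_to)
        except StaticSolveError:
            if depth >= 6:
                raise
            p_mid = 0.5 * (p_from + p_to)
            x_mid = self._solve_adaptive(x, p_from, p_mid, depth + 1)
            return self._solve_adaptive(x_mid, p_mid, p_to, depth + 1)

    # ------------------------------------------------------------ dynamics
    def stable_dt(self, x: np.ndarray, safety: float = 0.25,
                  extra_stiffness: float = 0.0) -> float:
        """CFL-style stable explicit time step (ms).

        Tangent moduli are estimated by differencing the analytic first
        derivatives of the membrane energy; bending and any extra nodal
        stiffness (contact, cavity) are folded in.
        """
        lam_s, lam_t, _, _ = self.stretches(x)
        h = 1e-5
        m = self.mat
        _, dps1, dpt1 = self._derivs_all(lam_s + h, lam_t)
        _, dps0, dpt0 = self._derivs_all(lam_s - h, lam_t)
        _, dqs1, dqt1 = self._derivs_all(lam_s, lam_t + h)
        _, dqs0, dqt0 = self._derivs_all(lam_s, lam_t - h)
        E_tan = np.maximum.reduce([
            (dps1 - dps0) / (2 * h), (dqt1 - dqt0) / (2 * h),
            np.full_like(lam_s, 4.0 * m.C10),
        ])
        c = np.sqrt(np.maximum(E_tan, 1e-9) / self.density)
        dt_mem = np.min(self.L0 / c)

        # bending: omega^2 ~ k_b / m with k_b ~ 8 B / l^3
        l0 = np.empty(self.mesh.n_nodes)
        l0[1:-1] = 0.5 * (self.L0[:-1] + self.L0[1:])
        l0[0], l0[-1] = self.L0[0], self.L0[-1]
        nb = len(self.B)
        k_b = 8.0 * self.B / l0[:nb] ** 3
        with np.errstate(divide="ignore"):
            dt_bend = np.min(2.0 / np.sqrt(
                np.maximum(k_b, 1e-12) / self.node_mass[:nb]))

        dt = min(dt_mem, dt_bend)
        if extra_stiffness > 0.0:
            m_min = self.node_mass[self.free_mask[:, 1]].min()
            dt = min(dt, 2.0 / np.sqrt(extra_stiffness / m_min))
        return safety * dt

    def _derivs_all(self, lam_s, lam_t):
        mesh = self.mesh
        psi = np.zeros_like(lam_s)
        dps = np.zeros_like(lam_s)
        dpt = np.zeros_like(lam_s)
        for code, name in ((REGION_CORNEA, "cornea"), (REGION_LIMBUS, "limbus"),
                           (REGION_SCLERA, "sclera")):
            mask = mesh.region == code
            if not mask.any():
                continue
            mp = self.materials[name]
            nm, nc = _REGION_FAMILIES[code]
            p, ds_, dt_ = membrane_energy_derivs(
                lam_s[mask], lam_t[mask], mp.C10, mp.k1, mp.k2, nm, nc)
            psi[mask], dps[mask], dpt[mask] = p, ds_, dt_
        return psi, dps, dpt
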