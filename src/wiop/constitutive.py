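"""Hyperelastic constitutive laws for the ocular tissues.

Cornea and limbus follow the Holzapfel-Gasser-Ogden (HGO) law: an isotropic
Neo-Hookean ground matrix plus exponentially stiffening collagen-fibre
families,

    psi_bar = C10 (I1_bar - 3) + k1/(2 k2) * sum_i [exp(k2 (Ii_bar - 1)^2) - 1]

with i over the pseudo-invariants of the fibre families (I4, I6).  C10 [MPa]
characterises the extracellular matrix, k1 [MPa] the fibre stiffness and
k2 [-] the fibre non-linearity.  The sclera is isotropic Neo-Hookean
(k1 = 0).  Near-incompressibility is imposed through a volumetric penalty
U(J) = K/2 (J - 1)^2 with K >> C10.

Fibre terms are active in tension only (Ii_bar > 1), the standard HGO switch
that prevents non-physical compressive fibre stiffening.

The module provides the full 3-D energy/stress (used for verification and by
property tests) and an incompressible plane-stress membrane specialisation
``membrane_energy``/``membrane_stress_resultants`` in the principal
stretches (meridional, circumferential), which is what the axisymmetric
solver evaluates element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialParams",
    "DeformationState",
    "hgo_energy",
    "hgo_stress",
    "neohookean_energy",
    "membrane_energy",
    "membrane_energy_derivs",
    "MaterialInstabilityError",
]

#: exponent guard: exp overflows around 709
_EXP_GUARD = 700.0


class MaterialInstabilityError(FloatingPointError):
    """Raised when the fibre exponent k2 (I-1)^2 exceeds the overflow guard."""


@dataclass
class MaterialParams:
    """HGO / Neo-Hookean material parameters (stresses in MPa).

    ``fibre_directions`` holds the reference unit direction of each fibre
    family (none for sclera, one circumferential for limbus, two orthogonal
    for cornea).
    """

    C10: float
    k1: float = 0.0
    k2: float = 1.0
    fibre_directions: list = field(default_factory=list)
    bulk_penalty: float | None = None

    def __post_init__(self) -> None:
        if not self.C10 > 0:
            raise ValueError("C10 must be positive")
        if self.k1 < 0:
            raise ValueError("k1 must be non-negative")
        if self.k1 > 0 and not self.k2 > 0:
            raise ValueError("k2 must be positive when fibres are present")
        if self.bulk_penalty is None:
            self.bulk_penalty = 1e3 * self.C10
        if self.bulk_penalty < 1e3 * self.C10:
            raise ValueError("bulk_penalty must be at least 1000 x C10")
        dirs = []
        for a in self.fibre_directions:
            a = np.asarray(a, dtype=float)
            n = np.linalg.norm(a)
            if not np.isclose(n, 1.0, atol=1e-8):
                raise ValueError("fibre directions must be unit vectors")
            dirs.append(a / n)
        self.fibre_directions = dirs


@dataclass
class DeformationState:
    """Deformation gradient and derived isochoric invariants."""

    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float).reshape(3, 3)
        self.J = float(np.linalg.det(self.F))
        if self.J <= 0:
            raise ValueError(f"non-positive Jacobian J={self.J}")
        self.C = self.F.T @ self.F
        self.I1_bar = float(self.J ** (-2.0 / 3.0) * np.trace(self.C))

    def fibre_invariant(self, a: np.ndarray) -> float:
        """Isochoric pseudo-invariant of fibre family with reference
        direction ``a`` (I4_bar or I6_bar)."""
        a = np.asarray(a, dtype=float)
        return float(self.J ** (-2.0 / 3.0) * (a @ self.C @ a))


def _fibre_psi(I_bar: float, k1: float, k2: float) -> float:
    """Tension-only exponential fibre energy of one family."""
    if k1 == 0.0 or I_bar <= 1.0:
        return 0.0
    arg = k2 * (I_bar - 1.0) ** 2
    if arg > _EXP_GUARD:
        raise MaterialInstabilityError(
            f"fibre exponent k2*(I-1)^2 = {arg:.3g} exceeds the overflow guard"
        )
    return k1 / (2.0 * k2) * (np.exp(arg) - 1.0)


def _fibre_dpsi(I_bar: float, k1: float, k2: float) -> float:
    """d(psi_fibre)/d(I_bar), tension only."""
    if k1 == 0.0 or I_bar <= 1.0:
        return 0.0
    arg = k2 * (I_bar - 1.0) ** 2
    if arg > _EXP_GUARD:
        raise MaterialInstabilityError(
            f"fibre exponent k2*(I-1)^2 = {arg:.3g} exceeds the overflow guard"
        )
    return k1 * (I_bar - 1.0) * np.exp(arg)


def hgo_energy(state: DeformationState, params: MaterialParams,
               include_volumetric: bool = False) -> float:
    """Isochoric HGO strain-energy density (MPa = mJ/mm^3).

    With ``include_volumetric`` the penalty U(J) = K/2 (J-1)^2 is added.
    """
    psi = params.C10 * (state.I1_bar - 3.0)
    for a in params.fibre_directions:
        psi += _fibre_psi(state.fibre_invariant(a), params.k1, params.k2)
    if include_volumetric:
        psi += 0.5 * params.bulk_penalty * (state.J - 1.0) ** 2
    return float(psi)


def neohookean_energy(state: DeformationState, params: MaterialParams,
                      include_volumetric: bool = False) -> float:
    """Isochoric Neo-Hookean energy density C10 (I1_bar - 3); the k1 -> 0
    limit of the HGO law."""
    psi = params.C10 * (state.I1_bar - 3.0)
    if include_volumetric:
        psi += 0.5 * params.bulk_penalty * (state.J - 1.0) ** 2
    return float(psi)


def hgo_stress(state: DeformationState, params: MaterialParams,
               include_volumetric: bool = True) -> np.ndarray:
    """Cauchy stress (MPa) of the HGO law, analytic.

    sigma = J^-1 P F^T with P = d(psi)/dF assembled from
      d(I1_bar)/dF = 2 J^(-2/3) (F - I1/3 F^-T)
      d(Ii_bar)/dF = J^(-2/3) (2 (F a) a^T - 2/3 Ii F^-T)
      dU/dF        = K (J-1) J F^-T
    """
    F, J = state.F, state.J
    Finv_T = np.linalg.inv(F).T
    I1 = np.trace(state.C)
    P = params.C10 * 2.0 * J ** (-2.0 / 3.0) * (F - (I1 / 3.0) * Finv_T)
    for a in params.fibre_directions:
        I_full = float(a @ state.C @ a)
        I_bar = J ** (-2.0 / 3.0) * I_full
        dpsi = _fibre_dpsi(I_bar, params.k1, params.k2)
        if dpsi != 0.0:
            Fa = F @ a
            # d(Ii_bar)/dF = J^(-2/3) * 2 (Fa) a^T - (2/3) Ii_bar F^-T
            dI_dF = J ** (-2.0 / 3.0) * 2.0 * np.outer(Fa, a) - (2.0 / 3.0) * I_bar * Finv_T
            P = P + dpsi * dI_dF
    if include_volumetric:
        P = P + params.bulk_penalty * (J - 1.0) * J * Finv_T
    sigma = (P @ F.T) / J
    return 0.5 * (sigma + sigma.T)   # symmetrize away roundoff


# --------------------------------------------------------------------------
# incompressible plane-stress membrane specialisation
# --------------------------------------------------------------------------

#: cap on the fibre exponent in the membrane kernel: beyond this the energy
#: keeps growing with a frozen (astronomically steep) slope instead of
#: overflowing, so equilibrium searches that probe unphysical trial states
#: are repelled rather than aborted
_MEMBRANE_EXP_CAP = 200.0


def _membrane_invariants(lam_s, lam_t):
    lam_n = 1.0 / (lam_s * lam_t)          # incompressible through-thickness
    I1 = lam_s ** 2 + lam_t ** 2 + lam_n ** 2
    return I1, lam_n


def membrane_energy(lam_s, lam_t, C10, k1=0.0, k2=1.0, n_mer=0, n_circ=0):
    """Energy density (MPa) of an incompressible plane-stress membrane at
    principal stretches ``lam_s`` (meridional) and ``lam_t``
    (circumferential); vectorized over element arrays.

    ``n_mer``/``n_circ`` count the fibre families aligned with each
    direction (cornea: 1/1, limbus: 0/1, sclera: 0/0).
    """
    lam_s = np.asarray(lam_s, dtype=float)
    lam_t = np.asarray(lam_t, dtype=float)
    I1, _ = _membrane_invariants(lam_s, lam_t)
    psi = C10 * (I1 - 3.0)
    if k1 > 0.0:
        for n_fam, lam in ((n_mer, lam_s), (n_circ, lam_t)):
            if n_fam:
                I = lam ** 2
                e = np.where(I > 1.0, k2 * (I - 1.0) ** 2, 0.0)
                ec = np.minimum(e, _MEMBRANE_EXP_CAP)
                # linear continuation in the exponent beyond the cap keeps the
                # energy finite and its analytic derivative exact
                grow = np.exp(ec) * (1.0 + (e - ec)) - 1.0
                psi = psi + n_fam * np.where(
                    I > 1.0, k1 / (2.0 * k2) * grow, 0.0)
    return psi


def membrane_energy_derivs(lam_s, lam_t, C10, k1=0.0, k2=1.0, n_mer=0, n_circ=0):
    """(psi, dpsi/dlam_s, dpsi/dlam_t) for the membrane law, vectorized."""
    lam_s = np.asarray(lam_s, dtype=float)
    lam_t = np.asarray(lam_t, dtype=float)
    I1, lam_n = _membrane_invariants(lam_s, lam_t)
    psi = C10 * (I1 - 3.0)
    # d(I1)/dlam_s = 2 lam_s - 2 / (lam_s^3 lam_t^2), symmetric for lam_t
    dpsi_s = C10 * (2.0 * lam_s - 2.0 * lam_n ** 2 / lam_s)
    dpsi_t = C10 * (2.0 * lam_t - 2.0 * lam_n ** 2 / lam_t)
    if k1 > 0.0:
        for n_fam, lam, which in ((n_mer, lam_s, "s"), (n_circ, lam_t, "t")):
            if not n_fam:
                continue
            I = lam ** 2
            act = I > 1.0
            e = np.where(act, k2 * (I - 1.0) ** 2, 0.0)
            ec = np.minimum(e, _MEMBRANE_EXP_CAP)
            expe = np.exp(ec)
            grow = expe * (1.0 + (e - ec)) - 1.0
            psi = psi + n_fam * np.where(act, k1 / (2.0 * k2) * grow, 0.0)
            dpsi_dI = np.where(act, k1 * (I - 1.0) * expe, 0.0)
            term = n_fam * dpsi_dI * 2.0 * lam
            if which == "s":
                dpsi_s = dpsi_s + term
            else:
                dpsi_t = dpsi_t + term
    return psi, dpsi_s, dpsi_t
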