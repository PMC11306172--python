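"""Axisymmetric eye geometry: cornea, limbus and sclera.

The eye is modelled as a surface of revolution about the y axis (the
anterior-posterior axis, positive outward through the corneal apex).  The
meridian runs from the corneal apex (r = 0) through the limbus and sclera
down to the scleral equator, where the model is clamped.  The discretized
surface is taken to be the *anterior* surface; tissue thickness is carried
as a nodal field extending inward, so central corneal thickness (CCT) can be
varied without touching the node positions.

Region layout along the meridian:

* ``cornea``  — spherical arc of the anterior corneal radius, out to the
  corneal diameter; two orthogonal collagen-fibre families (nasal-temporal
  and superior-inferior), represented in the axisymmetric reduction by a
  meridional and a circumferential family.
* ``limbus``  — first stretch of the scleral arc, one circumferential
  fibre family, thickness blending CCT -> scleral thickness.
* ``sclera``  — remainder of the scleral arc to the equator, isotropic.

Dimensions not fixed by the model's inputs (anterior radius 7.7 mm, corneal
diameter 11.5 mm, scleral radius 12 mm, limbus width 1 mm, scleral thickness
0.8 mm) are conventional defaults, configurable in :class:`EyeGeometryConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EyeGeometryConfig",
    "EyeMesh",
    "build_eye_mesh",
    "anterior_nodal_areas",
    "write_vtk",
    "REGION_CORNEA",
    "REGION_LIMBUS",
    "REGION_SCLERA",
]

REGION_CORNEA = 0
REGION_LIMBUS = 1
REGION_SCLERA = 2
REGION_NAMES = {REGION_CORNEA: "cornea", REGION_LIMBUS: "limbus", REGION_SCLERA: "sclera"}


@dataclass
class EyeGeometryConfig:
    """Geometric parameters of the axisymmetric eye model (lengths in mm,
    CCT in µm)."""

    anterior_corneal_radius: float = 7.7
    corneal_diameter: float = 11.5
    cct_um: float = 558.0
    limbus_width: float = 1.0
    scleral_radius: float = 12.0
    scleral_thickness: float = 0.8
    mesh_resolution: int = 1
    #: allow CCT outside the physiological [300, 800] µm band
    override_cct_limits: bool = False

    def __post_init__(self) -> None:
        lengths = {
            "anterior_corneal_radius": self.anterior_corneal_radius,
            "corneal_diameter": self.corneal_diameter,
            "cct_um": self.cct_um,
            "limbus_width": self.limbus_width,
            "scleral_radius": self.scleral_radius,
            "scleral_thickness": self.scleral_thickness,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.mesh_resolution < 1:
            raise ValueError("mesh_resolution must be a positive integer")
        if not self.override_cct_limits and not (300.0 <= self.cct_um <= 800.0):
            raise ValueError(
                f"CCT {self.cct_um} µm outside [300, 800] µm; "
                "set override_cct_limits=True to force"
            )
        if self.cct_mm >= self.anterior_corneal_radius:
            raise ValueError("CCT larger than the anterior corneal radius")
        if self.corneal_diameter >= 2.0 * self.scleral_radius:
            raise ValueError("corneal diameter must be smaller than the scleral diameter")
        if self.corneal_diameter >= 2.0 * self.anterior_corneal_radius:
            raise ValueError("corneal diameter exceeds the anterior corneal sphere")

    @property
    def cct_mm(self) -> float:
        return self.cct_um * 1e-3


@dataclass
class EyeMesh:
    """Axisymmetric meridian discretization of the eye.

    ``nodes`` holds reference (r, y) coordinates, ordered from the corneal
    apex (index 0, r = 0) to the scleral equator (clamped).  Elements are the
    meridian segments between consecutive nodes; revolved about the y axis
    each one is a conical frustum.
    """

    nodes: np.ndarray               # (N, 2) reference coordinates (r, y), mm
    elements: np.ndarray            # (E, 2) node index pairs
    region: np.ndarray              # (E,) region code per element
    thickness: np.ndarray           # (E,) tissue thickness per element, mm
    node_thickness: np.ndarray      # (N,) tissue thickness per node, mm
    fibre_meridional: np.ndarray    # (E, 3) unit meridional fibre direction (r, y, z)
    fibre_circumferential: np.ndarray  # (E, 3) unit circumferential direction
    anterior_nodes: np.ndarray      # node indices of the anterior corneal surface
    apex_node: int
    clamped_nodes: np.ndarray
    config: EyeGeometryConfig = field(repr=False, default=None)

    # ------------------------------------------------------------------ areas
    @staticmethod
    def _segment_geometry(coords: np.ndarray, elements: np.ndarray):
        ri, yi = coords[elements[:, 0], 0], coords[elements[:, 0], 1]
        rj, yj = coords[elements[:, 1], 0], coords[elements[:, 1], 1]
        slant = np.hypot(rj - ri, yj - yi)
        return ri, yi, rj, yj, slant

    def element_areas(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Lateral (true) surface area of each revolved frustum, mm^2."""
        coords = self.nodes if coords is None else coords
        ri, _, rj, _, slant = self._segment_geometry(coords, self.elements)
        return np.pi * (ri + rj) * slant

    def _scatter_half(self, values: np.ndarray, element_subset: np.ndarray | None):
        e = self.elements if element_subset is None else self.elements[element_subset]
        v = values if element_subset is None else values[element_subset]
        out = np.zeros(len(self.nodes))
        np.add.at(out, e[:, 0], 0.5 * v)
        np.add.at(out, e[:, 1], 0.5 * v)
        return out

    def nodal_areas(self, coords: np.ndarray | None = None,
                    element_subset: np.ndarray | None = None) -> np.ndarray:
        """True surface area associated with each node (half of each incident
        frustum), recomputed in the configuration ``coords``.  With
        ``element_subset`` only those frustums contribute (used to restrict
        the partition to the anterior corneal surface)."""
        coords = self.nodes if coords is None else coords
        return self._scatter_half(self.element_areas(coords), element_subset)

    def projected_nodal_areas(self, coords: np.ndarray | None = None,
                              element_subset: np.ndarray | None = None) -> np.ndarray:
        """Signed y-projected nodal areas (mm^2): the annulus each frustum
        projects onto the equatorial plane, positive where the outward normal
        points along +y.  These convert a spatially uniform pressure into its
        net y-force per node, the quantity the work bookkeeping integrates."""
        coords = self.nodes if coords is None else coords
        ri = coords[self.elements[:, 0], 0]
        rj = coords[self.elements[:, 1], 0]
        return self._scatter_half(np.pi * (rj ** 2 - ri ** 2), element_subset)

    def anterior_nodal_area_array(self, coords: np.ndarray | None = None,
                                  projected: bool = False) -> np.ndarray:
        """Nodal areas of the anterior corneal surface only (zero elsewhere);
        they partition the corneal cap exactly."""
        if projected:
            return self.projected_nodal_areas(coords, self.corneal_elements)
        return self.nodal_areas(coords, self.corneal_elements)

    # ----------------------------------------------------------------- volume
    def enclosed_volume(self, coords: np.ndarray | None = None) -> float:
        """Volume (mm^3) enclosed between the surface of revolution and the
        equatorial plane (the fluid-cavity volume of the reduced model)."""
        coords = self.nodes if coords is None else coords
        ri, yi, rj, yj, _ = self._segment_geometry(coords, self.elements)
        return float(np.sum(np.pi / 3.0 * (ri * ri + ri * rj + rj * rj) * (yi - yj)))

    def enclosed_volume_gradient(self, coords: np.ndarray | None = None) -> np.ndarray:
        """d(enclosed volume)/d(node coordinates), shape (N, 2)."""
        coords = self.nodes if coords is None else coords
        ri, yi, rj, yj, _ = self._segment_geometry(coords, self.elements)
        grad = np.zeros_like(coords)
        c = np.pi / 3.0
        dVdri = c * (2 * ri + rj) * (yi - yj)
        dVdrj = c * (ri + 2 * rj) * (yi - yj)
        dVdyi = c * (ri * ri + ri * rj + rj * rj)
        dVdyj = -dVdyi
        np.add.at(grad[:, 0], self.elements[:, 0], dVdri)
        np.add.at(grad[:, 0], self.elements[:, 1], dVdrj)
        np.add.at(grad[:, 1], self.elements[:, 0], dVdyi)
        np.add.at(grad[:, 1], self.elements[:, 1], dVdyj)
        return grad

    # ------------------------------------------------------------- properties
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def corneal_elements(self) -> np.ndarray:
        return np.nonzero(self.region == REGION_CORNEA)[0]

    def anterior_surface_area(self, coords: np.ndarray | None = None) -> float:
        """Current area of the anterior corneal surface (mm^2)."""
        return float(self.anterior_nodal_area_array(coords)[self.anterior_nodes].sum())

    def region_names(self) -> list[str]:
        return [REGION_NAMES[int(c)] for c in self.region]


def _arc_points(center_y: float, radius: float, phi: np.ndarray) -> np.ndarray:
    """Points on an arc about (0, center_y); phi is the polar angle from +y."""
    return np.column_stack([radius * np.sin(phi), center_y + radius * np.cos(phi)])


def build_eye_mesh(config: EyeGeometryConfig) -> EyeMesh:
    """Build the axisymmetric meridian mesh from a geometry config.

    The corneal arc (anterior radius, out to the corneal diameter) meets a
    scleral arc whose centre lies on the y axis and whose sphere passes
    through the corneal rim; the first ``limbus_width`` mm of that arc are
    labelled limbus.  The global origin is the scleral centre, so the model
    is clamped at the scleral equator (y = 0, r = scleral radius).
    """
    Rc = config.anterior_corneal_radius
    Rs = config.scleral_radius
    r_rim = 0.5 * config.corneal_diameter

    theta_c = np.arcsin(r_rim / Rc)               # corneal half-angle
    y_rim = np.sqrt(Rs * Rs - r_rim * r_rim)      # rim lies on the scleral sphere
    y_cc = y_rim - Rc * np.cos(theta_c)           # corneal centre on the y axis

    phi_rim = np.arctan2(r_rim, y_rim)            # scleral polar angle at the rim
    scleral_arc = Rs * (np.pi / 2.0 - phi_rim)
    if config.limbus_width >= scleral_arc:
        raise ValueError("limbus_width leaves no room for the sclera")

    res = config.mesh_resolution
    n_c, n_l, n_s = 20 * res, 4 * res, 16 * res

    phi_cornea = np.linspace(0.0, theta_c, n_c + 1)
    pts_cornea = _arc_points(y_cc, Rc, phi_cornea)

    dphi_l = config.limbus_width / Rs
    phi_limb = np.linspace(phi_rim, phi_rim + dphi_l, n_l + 1)[1:]
    phi_scl = np.linspace(phi_rim + dphi_l, np.pi / 2.0, n_s + 1)[1:]
    pts_rest = _arc_points(0.0, Rs, np.concatenate([phi_limb, phi_scl]))

    nodes = np.vstack([pts_cornea, pts_rest])
    nodes[0, 0] = 0.0                             # apex exactly on the axis
    n_nodes = len(nodes)
    n_elem = n_nodes - 1
    elements = np.column_stack([np.arange(n_elem), np.arange(1, n_elem + 1)])
    region = np.concatenate([
        np.full(n_c, REGION_CORNEA),
        np.full(n_l, REGION_LIMBUS),
        np.full(n_s, REGION_SCLERA),
    ])

    # thickness field: uniform CCT over the cornea, linear blend over the
    # limbus, uniform scleral thickness beyond
    cct = config.cct_mm
    node_thick = np.empty(n_nodes)
    node_thick[: n_c + 1] = cct
    blend = np.linspace(cct, config.scleral_thickness, n_l + 1)[1:]
    node_thick[n_c + 1: n_c + 1 + n_l] = blend
    node_thick[n_c + 1 + n_l:] = config.scleral_thickness
    thickness = 0.5 * (node_thick[elements[:, 0]] + node_thick[elements[:, 1]])

    # fibre directions: meridional tangents in the (r, y) plane and the
    # out-of-plane circumferential direction; the corneal NT/SI orthogonal
    # pair maps onto this (meridional, circumferential) pair in the
    # axisymmetric reduction
    tang = nodes[elements[:, 1]] - nodes[elements[:, 0]]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    fibre_mer = np.column_stack([tang, np.zeros(n_elem)])
    fibre_circ = np.tile([0.0, 0.0, 1.0], (n_elem, 1))

    mesh = EyeMesh(
        nodes=nodes,
        elements=elements,
        region=region,
        thickness=thickness,
        node_thickness=node_thick,
        fibre_meridional=fibre_mer,
        fibre_circumferential=fibre_circ,
        anterior_nodes=np.arange(n_c + 1),
        apex_node=0,
        clamped_nodes=np.array([n_nodes - 1]),
        config=config,
    )

    # sanity: discretized anterior area must match the spherical cap closed form
    cap = 2.0 * np.pi * Rc * Rc * (1.0 - np.cos(theta_c))
    if abs(mesh.anterior_surface_area() - cap) > 0.01 * cap:
        raise RuntimeError("anterior surface area deviates >1% from the spherical cap")
    return mesh


def anterior_nodal_areas(mesh: EyeMesh, coords: np.ndarray | None = None) -> dict[int, float]:
    """Per-node area map (mm^2) of the anterior corneal surface, recomputed
    in the configuration ``coords`` (reference configuration by default)."""
    areas = mesh.anterior_nodal_area_array(coords)
    return {int(i): float(areas[i]) for i in mesh.anterior_nodes}


def write_vtk(mesh: EyeMesh, path: str, coords: np.ndarray | None = None) -> None:
    """Export the meridian as legacy ASCII VTK polyline data for inspection."""
    coords = mesh.nodes if coords is None else coords
    n = len(coords)
    lines = [
        "# vtk DataFile Version 3.0",
        "wiop axisymmetric eye meridian",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    for r, y in coords:
        lines.append(f"{r:.6f} {y:.6f} 0.0")
    e = mesh.elements
    lines.append(f"LINES {len(e)} {3 * len(e)}")
    for i, j in e:
        lines.append(f"2 {i} {j}")
    lines.append(f"POINT_DATA {n}")
    lines.append("SCALARS thickness float 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{t:.6f}" for t in mesh.node_thickness)
    lines.append(f"CELL_DATA {len(e)}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(c)) for c in mesh.region)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
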