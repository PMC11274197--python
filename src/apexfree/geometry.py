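"""Idealized left-ventricular geometry and boundary-condition factories.

The LV wall is a truncated prolate ellipsoid parameterized by

* ``xi``  in [0, 1]  — transmural coordinate (0 endocardium, 1 epicardium),
* ``eta`` in [0, 1]  — longitudinal coordinate (0 apex, 1 basal plane),
* ``phi`` in [0, 2pi) — circumferential azimuth,

with semi-axes interpolating linearly between the endocardial and
epicardial ellipsoids and a flat basal truncation plane at ``z = z_base``.
The apex–base axis is +z (apex at negative z); displacements toward the
base are positive along this axis.

Besides the hexahedral export mesh, the module builds

* a rule-based fiber architecture (helix angle linear across the wall),
* the 49 pericardial spring clusters on the epicardium, evenly seeded by
  farthest-point sampling and refined by Lloyd iterations, with stiffness
  decreasing linearly from apex to base,
* the single aortic spring at the aortic-root landmark, resisting axial
  translation only (the root is free to stretch but not rotate).

Lengths in mm, stiffnesses in N/mm, volumes returned in mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError

__all__ = [
    "GeometryParams",
    "LVGeometry",
    "Microstructure",
    "SpringBC",
    "build_ellipsoid_lv",
    "assign_fiber_field",
    "build_pericardial_springs",
    "free_apex",
    "build_aortic_spring",
    "parametric_position",
    "fiber_frame",
    "enclosed_volume",
    "cavity_volume_of_map",
]

MM3_PER_ML = 1000.0


@dataclass(frozen=True)
class GeometryParams:
    """Defining parameters of the truncated-ellipsoid LV (mm)."""

    a_endo: float = 22.0          # endocardial equatorial semi-axis
    c_endo: float = 50.0          # endocardial long semi-axis
    wall_thickness: float = 10.0
    base_frac: float = 0.5        # truncation height z_base = base_frac * c_endo
    scale: float = 1.0            # global similarity scale (calibration knob)
    n_trans: int = 3              # elements across the wall
    n_long: int = 12              # elements apex -> base
    n_circ: int = 16              # elements around the circumference
    root_radial_offset: float = 15.0   # aortic-root landmark offset from annulus center
    root_axial_offset: float = 8.0
    septal_azimuth: float = np.pi      # azimuth of the septum / aortic root

    def __post_init__(self):
        if self.a_endo <= 0 or self.c_endo <= 0 or self.wall_thickness <= 0:
            raise GeometryError("semi-axes and wall thickness must be positive")
        if self.wall_thickness >= min(self.a_endo, self.c_endo):
            raise GeometryError(
                "degenerate geometry: wall thickness must be smaller than the "
                "inner semi-axes")
        if not (0.0 < self.base_frac < 1.0):
            raise GeometryError("base_frac must lie in (0, 1)")
        if self.n_trans < 1 or self.n_long < 2 or self.n_circ < 4:
            raise GeometryError("mesh resolution too coarse")

    # -- derived scalar geometry -------------------------------------------
    @property
    def a_epi(self) -> float:
        return self.a_endo + self.wall_thickness

    @property
    def c_epi(self) -> float:
        return self.c_endo + self.wall_thickness

    @property
    def z_base(self) -> float:
        return self.scale * self.base_frac * self.c_endo

    @property
    def z_apex_epi(self) -> float:
        return -self.scale * self.c_epi

    @property
    def axial_length(self) -> float:
        """Distance from the epicardial apex to the basal plane (mm)."""
        return self.z_base - self.z_apex_epi


def _semi_axes(params: GeometryParams, xi):
    a = params.scale * (params.a_endo + np.asarray(xi) * params.wall_thickness)
    c = params.scale * (params.c_endo + np.asarray(xi) * params.wall_thickness)
    return a, c


def _mu_base(params: GeometryParams, xi):
    _, c = _semi_axes(params, xi)
    return np.arccos(np.clip(-params.z_base / c, -1.0, 1.0))


def parametric_position(params: GeometryParams, xi, eta, phi):
    """Material position X(xi, eta, phi) of the wall (broadcasting, mm)."""
    xi, eta, phi = np.broadcast_arrays(np.asarray(xi, float),
                                       np.asarray(eta, float),
                                       np.asarray(phi, float))
    a, c = _semi_axes(params, xi)
    mu = eta * _mu_base(params, xi)
    return np.stack([a * np.sin(mu) * np.cos(phi),
                     a * np.sin(mu) * np.sin(phi),
                     -c * np.cos(mu)], axis=-1)


def parametric_tangents(params: GeometryParams, xi, eta, phi, h: float = 1e-6):
    """Central-difference tangents dX/d(xi, eta, phi), shape (..., 3, 3)."""
    cols = []
    for d in range(3):
        dp = [np.asarray(xi, float), np.asarray(eta, float), np.asarray(phi, float)]
        dm = [c.copy() for c in dp]
        dp = [c.copy() for c in dp]
        dp[d] = dp[d] + h
        dm[d] = dm[d] - h
        cols.append((parametric_position(params, *dp)
                     - parametric_position(params, *dm)) / (2 * h))
    return np.stack(cols, axis=-1)


def fiber_frame(params: GeometryParams, xi, eta, phi,
                endo_angle: float = 60.0, epi_angle: float = -60.0):
    """Orthonormal (f0, s0, n0) triads with a linear transmural helix angle.

    The helix angle (degrees) rotates linearly from ``endo_angle`` at xi=0
    to ``epi_angle`` at xi=1 in the plane tangent to the wall surface;
    the sheet direction is the outward transmural normal.
    """
    if not (-90.0 < endo_angle < 90.0) or not (-90.0 < epi_angle < 90.0):
        raise GeometryError("helix angles must lie in (-90, 90) degrees")
    xi, eta, phi = np.broadcast_arrays(np.asarray(xi, float),
                                       np.asarray(eta, float),
                                       np.asarray(phi, float))
    T = parametric_tangents(params, xi, eta, phi)
    e_l = T[..., 1]  # longitudinal (apex -> base) surface tangent
    e_c = T[..., 2]  # circumferential tangent
    norm_l = np.linalg.norm(e_l, axis=-1, keepdims=True)
    norm_c = np.linalg.norm(e_c, axis=-1, keepdims=True)
    if np.any(norm_l < 1e-12) or np.any(norm_c < 1e-12):
        raise GeometryError("degenerate surface tangents (apex singularity); "
                            "sample fibers away from eta = 0")
    e_l = e_l / norm_l
    e_c = e_c / norm_c
    # Gram-Schmidt to machine-precision orthonormality
    e_l = e_l - np.sum(e_l * e_c, axis=-1, keepdims=True) * e_c
    e_l = e_l / np.linalg.norm(e_l, axis=-1, keepdims=True)
    e_t = np.cross(e_c, e_l)  # outward transmural normal

    alpha = np.deg2rad(endo_angle + (epi_angle - endo_angle) * xi)[..., None]
    f0 = np.cos(alpha) * e_c + np.sin(alpha) * e_l
    s0 = e_t
    n0 = np.cross(f0, s0)
    return f0, s0, n0


# ---------------------------------------------------------------------------
# cavity volume quadrature
# ---------------------------------------------------------------------------

def enclosed_volume(xs, t_eta, t_phi, ring, w_eta, d_phi):
    """Volume (mm^3) enclosed by a parametric surface closed at a basal ring.

    ``xs`` (n_eta, n_phi, 3) are deformed surface points at Gauss nodes in
    eta and uniform nodes in phi; ``t_eta``/``t_phi`` the corresponding
    tangents; ``ring`` (n_phi, 3) the deformed basal-ring points.  Uses the
    divergence theorem with the flux of (x - x_ref)/3 where x_ref is the
    ring centroid, so the basal cap contributes exactly zero and the result
    is rigid-translation invariant to machine precision.
    """
    x_ref = ring.mean(axis=0)
    n = np.cross(t_eta, t_phi)
    integrand = np.einsum("ijk,ijk->ij", xs - x_ref, n)
    V = (integrand @ np.full(xs.shape[1], d_phi)) @ w_eta / 3.0
    return abs(float(V))


def _surface_quadrature(n_eta: int = 24, n_phi: int = 32):
    g, w = np.polynomial.legendre.leggauss(n_eta)
    eta = 0.5 * (g + 1.0)
    w_eta = 0.5 * w
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    d_phi = 2 * np.pi / n_phi
    return eta, w_eta, phi, d_phi


def cavity_volume_of_map(params: GeometryParams, displacement=None,
                         n_eta: int = 24, n_phi: int = 32, h: float = 1e-5):
    """Cavity volume (mL) of the (optionally deformed) endocardial surface.

    ``displacement`` maps parametric endocardial points
    (xi=0, eta, phi) -> u (mm, same shape + (3,)); None means undeformed.
    """
    eta, w_eta, phi, d_phi = _surface_quadrature(n_eta, n_phi)
    E, P = np.meshgrid(eta, phi, indexing="ij")

    def deformed(e, p):
        x = parametric_position(params, 0.0, e, p)
        if displacement is not None:
            x = x + displacement(np.zeros_like(e), e, p)
        return x

    xs = deformed(E, P)
    t_eta = (deformed(E + h, P) - deformed(E - h, P)) / (2 * h)
    t_phi = (deformed(E, P + h) - deformed(E, P - h)) / (2 * h)
    ring = deformed(np.ones_like(phi), phi)
    return enclosed_volume(xs, t_eta, t_phi, ring, w_eta, d_phi) / MM3_PER_ML


# ---------------------------------------------------------------------------
# mesh / geometry container
# ---------------------------------------------------------------------------

@dataclass
class LVGeometry:
    """Idealized LV mesh with landmarks and surface sets.

    ``nodes`` are coordinates (mm); ``node_params`` the (xi, eta, phi)
    parametric coordinates of each node; ``elements`` hexahedral
    connectivity (apex cells degenerate).  Surface sets are node-index
    arrays.  The apex–base axis is the unit vector from the epicardial apex
    landmark to the mitral-annulus-plane center.
    """

    params: GeometryParams
    nodes: np.ndarray
    node_params: np.ndarray
    elements: np.ndarray
    endo_nodes: np.ndarray
    epi_nodes: np.ndarray
    basal_nodes: np.ndarray
    apex_point: np.ndarray
    annulus_center: np.ndarray
    aortic_root_point: np.ndarray
    axis: np.ndarray
    cavity_volume_unloaded: float  # mL

    def element_centroids_param(self) -> np.ndarray:
        """Mean (xi, eta, phi) per element, with circular phi averaging."""
        p = self.node_params[self.elements]
        xi = p[..., 0].mean(axis=1)
        eta = p[..., 1].mean(axis=1)
        ang = np.angle(np.exp(1j * p[..., 2]).mean(axis=1)) % (2 * np.pi)
        return np.column_stack([xi, eta, ang])


def build_ellipsoid_lv(params: GeometryParams | None = None, **overrides) -> LVGeometry:
    """Generate the synthetic truncated-ellipsoid LV.

    Returns the mesh, surface sets, landmarks (epicardial apex,
    mitral-annulus-plane center, aortic-root attachment), the apex–base
    unit axis and the unloaded cavity volume.  Deterministic: identical
    parameters yield bit-identical geometry.
    """
    if params is None:
        params = GeometryParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)

    nt, nl, nc = params.n_trans, params.n_long, params.n_circ
    xi_g = np.linspace(0.0, 1.0, nt + 1)
    eta_g = np.linspace(0.0, 1.0, nl + 1)
    phi_g = 2 * np.pi * np.arange(nc) / nc

    index = {}
    coords, pcoords = [], []

    def node_id(i, j, k):
        key = (i, 0, 0) if j == 0 else (i, j, k % nc)
        if key not in index:
            xi, eta, phi = xi_g[key[0]], eta_g[key[1]], phi_g[key[2]]
            index[key] = len(coords)
            coords.append(parametric_position(params, xi, eta, phi))
            pcoords.append((xi, eta, phi))
        return index[key]

    elements = []
    for i in range(nt):
        for j in range(nl):
            for k in range(nc):
                n000 = node_id(i, j, k)
                n100 = node_id(i + 1, j, k)
                n010 = node_id(i, j + 1, k)
                n110 = node_id(i + 1, j + 1, k)
                n001 = node_id(i, j, k + 1)
                n101 = node_id(i + 1, j, k + 1)
                n011 = node_id(i, j + 1, k + 1)
                n111 = node_id(i + 1, j + 1, k + 1)
                # VTK hexahedron ordering (degenerate at the apex ring j=0)
                elements.append([n000, n001, n011, n010, n100, n101, n111, n110])

    nodes = np.asarray(coords)
    node_params = np.asarray(pcoords)
    elements = np.asarray(elements, dtype=int)

    endo = np.flatnonzero(node_params[:, 0] == 0.0)
    epi = np.flatnonzero(node_params[:, 0] == 1.0)
    basal = np.flatnonzero(node_params[:, 1] == 1.0)

    apex_point = parametric_position(params, 1.0, 0.0, 0.0)
    annulus_center = np.array([0.0, 0.0, params.z_base])
    root = annulus_center + np.array([
        params.root_radial_offset * np.cos(params.septal_azimuth),
        params.root_radial_offset * np.sin(params.septal_azimuth),
        params.root_axial_offset])
    axis = annulus_center - apex_point
    axis = axis / np.linalg.norm(axis)

    v0 = cavity_volume_of_map(params)
    if v0 <= 0:
        raise GeometryError("unloaded cavity volume must be positive")

    return LVGeometry(params=params, nodes=nodes, node_params=node_params,
                      elements=elements, endo_nodes=endo, epi_nodes=epi,
                      basal_nodes=basal, apex_point=apex_point,
                      annulus_center=annulus_center, aortic_root_point=root,
                      axis=axis, cavity_volume_unloaded=v0)


# ---------------------------------------------------------------------------
# microstructure
# ---------------------------------------------------------------------------

@dataclass
class Microstructure:
    """Per-element orthonormal fiber/sheet/normal frames."""

    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray
    transmural: np.ndarray
    endo_angle: float
    epi_angle: float


def assign_fiber_field(geometry: LVGeometry, endo_angle: float = 60.0,
                       epi_angle: float = -60.0) -> Microstructure:
    """Rule-based fiber field: helix angle linear in the transmural
    coordinate between the configured endocardial and epicardial angles,
    evaluated at element centroids.  Triads are orthonormal to machine
    precision and the fiber direction is tangent to the wall surface.
    """
    cen = geometry.element_centroids_param()
    eta = np.maximum(cen[:, 1], 1e-3)  # keep clear of the apex singularity
    f0, s0, n0 = fiber_frame(geometry.params, cen[:, 0], eta, cen[:, 2],
                             endo_angle, epi_angle)
    return Microstructure(f0=f0, s0=s0, n0=n0, transmural=cen[:, 0].copy(),
                          endo_angle=endo_angle, epi_angle=epi_angle)


# ---------------------------------------------------------------------------
# spring boundary conditions
# ---------------------------------------------------------------------------

@dataclass
class SpringBC:
    """One spring constraint (pericardial cluster or aortic root).

    ``direction`` None means the spring acts isotropically on the
    attachment-point displacement; a unit vector restricts its action to
    that axis (the aortic spring resists axial translation only).
    ``attach_param`` is the (xi, eta, phi) material coordinate used by the
    mechanics model to evaluate the attachment displacement.
    """

    cluster_id: int
    node_set: np.ndarray
    anchor: np.ndarray
    stiffness: float
    axial_position: float
    active: bool = True
    direction: np.ndarray | None = None
    attach_param: tuple = None

    def __post_init__(self):
        if self.stiffness < 0:
            raise GeometryError("spring stiffness must be >= 0")


def _farthest_point_seeds(points: np.ndarray, k: int, first: int) -> np.ndarray:
    seeds = [first]
    d = np.linalg.norm(points - points[first], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.asarray(seeds)


def build_pericardial_springs(geometry: LVGeometry, k_apex: float = 0.6,
                              k_base: float = 0.005, n_clusters: int = 49,
                              seed: int = 0, n_lloyd: int = 25) -> list[SpringBC]:
    """Cluster the epicardial nodes into ``n_clusters`` evenly distributed
    pericardial spring attachments.

    Seeding is by farthest-point sampling starting from the epicardial apex
    (deterministic), refined with Lloyd iterations; the clusters partition
    the epicardial node set.  Stiffness interpolates linearly from
    ``k_apex`` at normalized axial position 0 (apex) to ``k_base`` at 1
    (base); anchors sit at the unloaded cluster centroids.
    """
    if not (k_apex >= k_base >= 0):
        raise GeometryError("require k_apex >= k_base >= 0")
    epi = geometry.epi_nodes
    pts = geometry.nodes[epi]
    if len(epi) < n_clusters:
        raise GeometryError(
            f"only {len(epi)} epicardial nodes for {n_clusters} clusters")
    apex_local = int(np.argmin(geometry.node_params[epi, 1]))
    centers = pts[_farthest_point_seeds(pts, n_clusters, apex_local)]
    for _ in range(n_lloyd):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        for c in range(n_clusters):
            members = labels == c
            if members.any():
                centers[c] = pts[members].mean(axis=0)
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)

    z0 = geometry.params.z_apex_epi
    L = geometry.params.axial_length
    springs = []
    for c in range(n_clusters):
        members = epi[labels == c]
        centroid = geometry.nodes[members].mean(axis=0)
        axpos = float(np.clip((centroid[2] - z0) / L, 0.0, 1.0))
        k = k_apex + (k_base - k_apex) * axpos
        p = geometry.node_params[members]
        phi_mean = float(np.angle(np.exp(1j * p[:, 2]).mean()) % (2 * np.pi))
        eta_mean = max(float(p[:, 1].mean()), 1e-3)
        # pericardial constraint acts along the local epicardial surface
        # normal: it restrains normal motion but lets the wall slide
        # tangentially inside the sack (at the apex cap the normal is
        # axial, so the apical clusters do hold the apex)
        _, n_out, _ = fiber_frame(geometry.params, 1.0, eta_mean, phi_mean,
                                  endo_angle=0.0, epi_angle=0.0)
        springs.append(SpringBC(
            cluster_id=c, node_set=members, anchor=centroid, stiffness=k,
            axial_position=axpos, active=True,
            direction=np.asarray(n_out, float),
            attach_param=(1.0, eta_mean, phi_mean)))
    return springs


def free_apex(springs: list[SpringBC], freed_fraction: float = 0.5) -> list[SpringBC]:
    """Deactivate pericardial clusters in the apical ``freed_fraction`` of
    the normalized axial extent (the distal part of the pericardial sack);
    the input list is not mutated.
    """
    if not springs:
        raise GeometryError("empty spring list")
    if not (0.0 <= freed_fraction <= 1.0):
        raise GeometryError("freed_fraction must lie in [0, 1]")
    out = []
    for s in springs:
        freed = s.axial_position < freed_fraction or (
            freed_fraction >= 1.0)
        out.append(replace(s, active=False) if freed else replace(s))
    return out


def build_aortic_spring(geometry: LVGeometry, stiffness: float = 0.5) -> SpringBC:
    """Single spring representing ascending-aortic stiffness.

    Attached at the aortic-root landmark, anchored at its unloaded
    position, and acting along the apex–base axis only (the root is
    constrained from rotation but allowed to stretch).  0.5 N/mm models
    the elastic baseline aorta, 10 N/mm the stiff aorta.
    """
    if stiffness <= 0:
        raise GeometryError("aortic spring stiffness must be > 0")
    p = geometry.params
    # material attachment: mid-wall point on the basal plane at the root azimuth
    return SpringBC(cluster_id=-1, node_set=np.array([], dtype=int),
                    anchor=geometry.aortic_root_point.copy(),
                    stiffness=stiffness, axial_position=1.0, active=True,
                    direction=geometry.axis.copy(),
                    attach_param=(0.5, 1.0, float(p.septal_azimuth)))
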