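"""Idealised left-ventricular geometry and hexahedral meshing.

The LV wall is the region between two truncated ellipsoids of revolution
sharing the major (z) axis: the endocardial (inner) surface and the
epicardial (outer) surface, cut by the basal plane z = h perpendicular to
the major axis.  The wall is discretised into ``n_layers`` transmural
layers of trilinear hexahedra (the layer closest to the cavity is layer 1).
Muscle-fibre directions are tangent to the local layer surface, at a helix
angle to the circumferential direction that ramps linearly from +60 deg
(subendocardium) to -60 deg (subepicardium).

Units: lengths in mm, volumes reported in ml (1 ml = 1000 mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ML_PER_MM3 = 1e-3

# trilinear hexahedron: local corner coordinates (VTK ordering)
_XI_CORNERS = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

_G1 = 1.0 / np.sqrt(3.0)
#: 2x2x2 Gauss points for the hexahedron
HEX_GAUSS = np.array(
    [[sx * _G1, sy * _G1, sz * _G1]
     for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)],
    dtype=float,
)


def hex_shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi for the 8-node hexahedron at points ``xi`` (G,3) -> (G,8,3)."""
    xi = np.atleast_2d(xi)
    grads = np.empty((xi.shape[0], 8, 3))
    for a, ca in enumerate(_XI_CORNERS):
        for k in range(3):
            term = 0.125 * ca[k]
            for m in range(3):
                if m != k:
                    term = term * (1.0 + ca[m] * xi[:, m])
            grads[:, a, k] = term
    return grads


def hex_shape_functions(xi: np.ndarray) -> np.ndarray:
    """N_a at points ``xi`` (G,3) -> (G,8)."""
    xi = np.atleast_2d(xi)
    vals = np.ones((xi.shape[0], 8)) * 0.125
    for a, ca in enumerate(_XI_CORNERS):
        for m in range(3):
            vals[:, a] *= 1.0 + ca[m] * xi[:, m]
    return vals


@dataclass(frozen=True)
class LVDimensions:
    """Geometric parameters of the idealised LV.

    ``base_plane_height`` is the z-coordinate of the basal plane relative to
    the ellipsoid centre; the apex sits at negative z.  The outer surface is
    the inner one offset by ``wall_thickness_equator`` on both semi-axes,
    which yields a uniform wall thickness along radial parameter lines.
    """

    inner_short_semiaxis: float = 30.0
    inner_long_semiaxis: float = 65.0
    wall_thickness_equator: float = 9.0
    base_plane_height: float = 0.0

    def validate(self) -> None:
        if min(self.inner_short_semiaxis, self.inner_long_semiaxis) <= 0:
            raise ValueError("ellipsoid semi-axes must be positive")
        if self.wall_thickness_equator <= 0:
            raise ValueError("outer ellipsoid must strictly enclose the inner one")
        if abs(self.base_plane_height) >= self.inner_long_semiaxis:
            raise ValueError("base plane lies outside the inner ellipsoid")


def analytic_cavity_volume(dims: LVDimensions) -> float:
    """Volume (ml) of the inner ellipsoid below the basal plane z = h."""
    dims.validate()
    a = dims.inner_short_semiaxis
    c = dims.inner_long_semiaxis
    h = dims.base_plane_height
    v = np.pi * a * a * (h - h**3 / (3.0 * c * c) + 2.0 * c / 3.0)
    return float(v) * ML_PER_MM3


@dataclass
class LVMesh:
    """Hexahedral mesh of the LV wall with fibre and layer metadata."""

    nodes: np.ndarray            # (N, 3) mm
    hexes: np.ndarray            # (E, 8) node ids, VTK ordering
    layer: np.ndarray            # (E,) 1..n_layers, 1 = subendocardial
    centroids: np.ndarray        # (E, 3)
    depth_mm: np.ndarray         # (E,) distance centroid -> endocardial surface
    depth_fraction: np.ndarray   # (E,) in (0, 1)
    wall_thickness: np.ndarray   # (E,) local wall thickness mm
    helix_deg: np.ndarray        # (E,) helix angle
    fibres: np.ndarray           # (E, 3) unit fibre direction
    surface_normals: np.ndarray  # (E, 3) local transmural direction
    endo_faces: np.ndarray       # (Ef, 4) node ids, outward-oriented
    basal_nodes: np.ndarray      # node ids on the basal plane
    elem_volumes: np.ndarray     # (E,)
    dims: LVDimensions
    n_layers: int
    scale_factor: float = 1.0    # applied isotropic volume-matching scale
    # bookkeeping for refinement / rebuilds
    n_circ: int = 0
    n_long: int = 0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.hexes.shape[0]

    def with_nodes(self, nodes: np.ndarray) -> "LVMesh":
        """Copy of the mesh with new nodal coordinates (topology/fibres kept)."""
        m = LVMesh(
            nodes=np.asarray(nodes, float).copy(),
            hexes=self.hexes,
            layer=self.layer,
            centroids=_centroids(nodes, self.hexes),
            depth_mm=self.depth_mm,
            depth_fraction=self.depth_fraction,
            wall_thickness=self.wall_thickness,
            helix_deg=self.helix_deg,
            fibres=self.fibres / np.linalg.norm(self.fibres, axis=1, keepdims=True),
            surface_normals=self.surface_normals,
            endo_faces=self.endo_faces,
            basal_nodes=self.basal_nodes,
            elem_volumes=_element_volumes(nodes, self.hexes),
            dims=self.dims,
            n_layers=self.n_layers,
            scale_factor=self.scale_factor,
            n_circ=self.n_circ,
            n_long=self.n_long,
        )
        return m


def _centroids(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    return np.asarray(nodes)[hexes].mean(axis=1)


def _jacobians(nodes: np.ndarray, hexes: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """det of the isoparametric Jacobian at points xi for every element."""
    dN = hex_shape_gradients(xi)                      # (G,8,3)
    Xe = np.asarray(nodes)[hexes]                     # (E,8,3)
    J = np.einsum("eak,gal->egkl", Xe, dN)
    return np.linalg.det(J)


def _element_volumes(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    det = _jacobians(nodes, hexes, HEX_GAUSS)
    return det.sum(axis=1)  # unit Gauss weights


def _point_triangle_sq_distance(p, a, b, c):
    """Squared distance from points p (M,1,3) to triangles a,b,c (1,T,3)."""
    ab, ac = b - a, c - a
    ap = p - a
    d1 = np.einsum("...i,...i->...", np.broadcast_to(ab, ap.shape), ap)
    d2 = np.einsum("...i,...i->...", np.broadcast_to(ac, ap.shape), ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", np.broadcast_to(ab, bp.shape), bp)
    d4 = np.einsum("...i,...i->...", np.broadcast_to(ac, bp.shape), bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", np.broadcast_to(ab, cp.shape), cp)
    d6 = np.einsum("...i,...i->...", np.broadcast_to(ac, cp.shape), cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    def safe_div(num, den):
        return num / np.where(np.abs(den) < 1e-300, 1.0, den)

    # barycentric candidates for each Voronoi region
    t_ab = np.clip(safe_div(d1, d1 - d3), 0.0, 1.0)
    t_ac = np.clip(safe_div(d2, d2 - d6), 0.0, 1.0)
    t_bc = np.clip(safe_div(d4 - d3, (d4 - d3) + (d5 - d6)), 0.0, 1.0)
    denom = va + vb + vc
    v_in = safe_div(vb, denom)
    w_in = safe_div(vc, denom)

    q_in = a + v_in[..., None] * ab + w_in[..., None] * ac
    q_ab = a + t_ab[..., None] * ab
    q_ac = a + t_ac[..., None] * ac
    q_bc = b + t_bc[..., None] * (c - b)

    q = q_in
    cond_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    q = np.where(cond_bc[..., None], q_bc, q)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    q = np.where(cond_ac[..., None], q_ac, q)
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    q = np.where(cond_ab[..., None], q_ab, q)
    cond_c = (d6 >= 0) & (d5 <= d6)
    q = np.where(cond_c[..., None], np.broadcast_to(c, q.shape), q)
    cond_b = (d3 >= 0) & (d4 <= d3)
    q = np.where(cond_b[..., None], np.broadcast_to(b, q.shape), q)
    cond_a = (d1 <= 0) & (d2 <= 0)
    q = np.where(cond_a[..., None], np.broadcast_to(a, q.shape), q)
    diff = p - q
    return np.einsum("...i,...i->...", diff, diff)


def _distance_to_faces(points, nodes, faces):
    """Shortest distance from each point to a triangulated quad-face set."""
    x = np.asarray(nodes, float)
    quads = x[faces]                                 # (F,4,3)
    tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)
    area2 = np.linalg.norm(np.cross(tris[:, 1] - tris[:, 0],
                                    tris[:, 2] - tris[:, 0]), axis=1)
    tris = tris[area2 > 1e-12]                       # drop collapsed triangles
    p = np.asarray(points, float)[:, None, :]
    a = tris[None, :, 0]
    b = tris[None, :, 1]
    c = tris[None, :, 2]
    d2 = _point_triangle_sq_distance(p, a, b, c)
    return np.sqrt(d2.min(axis=1))


def build_lv_mesh(
    dims: LVDimensions = LVDimensions(),
    n_circ: int = 12,
    n_long: int = 6,
    n_layers: int = 7,
    helix_endo_deg: float = 60.0,
    helix_epi_deg: float = -60.0,
    volume_match: bool = True,
) -> LVMesh:
    """Build the truncated-ellipsoid LV wall mesh.

    Nodes are placed on ``n_layers + 1`` interpolated ellipsoidal surfaces
    between endo- and epicardium, with ``n_long`` strips from apex to base
    and ``n_circ`` circumferential sectors.  The apex strip uses collapsed
    (wedge-degenerate) hexahedra.  With ``volume_match`` the whole mesh is
    scaled isotropically so the discrete cavity volume equals the analytic
    truncated-ellipsoid volume of ``dims`` (the polygonal surface of a
    coarse mesh otherwise under-estimates the enclosed volume).
    """
    dims.validate()
    if n_circ < 8 or n_long < 4:
        raise ValueError("resolution too coarse: need n_circ >= 8, n_long >= 4")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")

    a_in = dims.inner_short_semiaxis
    c_in = dims.inner_long_semiaxis
    t = dims.wall_thickness_equator
    h = dims.base_plane_height

    L = n_layers
    per_surface = 1 + n_long * n_circ

    def node_id(m: int, j: int, i: int) -> int:
        base = m * per_surface
        if j == 0:
            return base
        return base + 1 + (j - 1) * n_circ + (i % n_circ)

    nodes = np.zeros(((L + 1) * per_surface, 3))
    phis = 2.0 * np.pi * np.arange(n_circ) / n_circ
    for m in range(L + 1):
        s = m / L
        a_m = a_in + s * t
        c_m = c_in + s * t
        th_top = np.arcsin(np.clip(h / c_m, -1.0, 1.0))
        thetas = -np.pi / 2 + (np.arange(n_long + 1) / n_long) * (th_top + np.pi / 2)
        nodes[node_id(m, 0, 0)] = (0.0, 0.0, -c_m)
        for j in range(1, n_long + 1):
            th = thetas[j]
            ring = np.stack(
                [a_m * np.cos(th) * np.cos(phis),
                 a_m * np.cos(th) * np.sin(phis),
                 np.full(n_circ, c_m * np.sin(th))],
                axis=1,
            )
            nodes[node_id(m, j, 0):node_id(m, j, 0) + n_circ] = ring

    hexes = []
    layer = []
    for k in range(L):
        for j in range(n_long):
            for i in range(n_circ):
                bot = [node_id(k, j, i), node_id(k, j + 1, i),
                       node_id(k, j + 1, i + 1), node_id(k, j, i + 1)]
                top = [node_id(k + 1, j, i), node_id(k + 1, j + 1, i),
                       node_id(k + 1, j + 1, i + 1), node_id(k + 1, j, i + 1)]
                hexes.append(bot + top)
                layer.append(k + 1)
    hexes = np.array(hexes, dtype=np.int64)
    layer = np.array(layer, dtype=np.int64)

    # fix hexahedron orientation if the parametrisation came out left-handed
    det_c = _jacobians(nodes, hexes[:1], np.zeros((1, 3)))
    if det_c[0, 0] < 0:
        hexes = hexes[:, [3, 2, 1, 0, 7, 6, 5, 4]]
    det = _jacobians(nodes, hexes, HEX_GAUSS)
    if np.any(det <= 0):
        raise ValueError("mesh build produced non-positive Jacobians")

    # endocardial faces (surface m=0), ordered consistently with the hexes
    endo_faces = []
    for j in range(n_long):
        for i in range(n_circ):
            endo_faces.append([node_id(0, j, i), node_id(0, j + 1, i),
                               node_id(0, j + 1, i + 1), node_id(0, j, i + 1)])
    endo_faces = np.array(endo_faces, dtype=np.int64)

    basal = np.array(sorted({node_id(m, n_long, i)
                             for m in range(L + 1) for i in range(n_circ)}),
                     dtype=np.int64)

    epi_faces = []
    for j in range(n_long):
        for i in range(n_circ):
            epi_faces.append([node_id(L, j, i), node_id(L, j + 1, i),
                              node_id(L, j + 1, i + 1), node_id(L, j, i + 1)])
    epi_faces = np.array(epi_faces, dtype=np.int64)

    # orient endocardial faces so the enclosed-volume integral is positive
    vol0 = _surface_volume(nodes, endo_faces)
    if vol0 < 0:
        endo_faces = endo_faces[:, ::-1].copy()
        vol0 = -vol0

    scale = 1.0
    if volume_match:
        target = analytic_cavity_volume(dims) / ML_PER_MM3
        scale = float((target / (vol0 / 1.0)) ** (1.0 / 3.0))
        nodes = nodes * scale

    centroids = _centroids(nodes, hexes)
    rho = np.hypot(centroids[:, 0], centroids[:, 1])
    # depth against the discretised surfaces (the cavity surface the model
    # actually has): shortest distance to the triangulated endo/epi faces
    depth_in = _distance_to_faces(centroids, nodes, endo_faces)
    depth_out = _distance_to_faces(centroids, nodes, epi_faces)
    thickness = depth_in + depth_out
    depth_fraction = depth_in / thickness

    # fibre field: helix angle per layer, directions on the centroid's
    # interpolated layer surface
    helix = helix_endo_deg + (layer - 1) / max(L - 1, 1) * (helix_epi_deg - helix_endo_deg)
    s_lay = (layer - 0.5) / L
    a_s = (a_in + s_lay * t) * scale
    c_s = (c_in + s_lay * t) * scale
    phi_c = np.arctan2(centroids[:, 1], centroids[:, 0])
    theta_c = np.arctan2(centroids[:, 2] / c_s, rho / a_s)
    e_c = np.stack([-np.sin(phi_c), np.cos(phi_c), np.zeros_like(phi_c)], axis=1)
    t_th = np.stack([-a_s * np.sin(theta_c) * np.cos(phi_c),
                     -a_s * np.sin(theta_c) * np.sin(phi_c),
                     c_s * np.cos(theta_c)], axis=1)
    e_l = t_th / np.linalg.norm(t_th, axis=1, keepdims=True)
    normals = np.cross(e_c, e_l)
    alpha = np.deg2rad(helix)
    fibres = np.cos(alpha)[:, None] * e_c + np.sin(alpha)[:, None] * e_l
    fibres /= np.linalg.norm(fibres, axis=1, keepdims=True)

    mesh = LVMesh(
        nodes=nodes,
        hexes=hexes,
        layer=layer,
        centroids=centroids,
        depth_mm=depth_in,
        depth_fraction=depth_fraction,
        wall_thickness=thickness,
        helix_deg=helix,
        fibres=fibres,
        surface_normals=normals,
        endo_faces=endo_faces,
        basal_nodes=basal,
        elem_volumes=_element_volumes(nodes, hexes),
        dims=dims,
        n_layers=L,
        scale_factor=scale,
        n_circ=n_circ,
        n_long=n_long,
    )
    _check_cavity_closure(mesh)
    return mesh


# -- cavity volume ----------------------------------------------------------

_G2 = 1.0 / np.sqrt(3.0)
QUAD_GAUSS = np.array([[-_G2, -_G2], [_G2, -_G2], [_G2, _G2], [-_G2, _G2]])


def quad_shape(xi: np.ndarray):
    """Bilinear quad shape functions and gradients at (G,2) points."""
    corners = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    N = 0.25 * (1 + corners[None, :, 0] * xi[:, None, 0]) * \
        (1 + corners[None, :, 1] * xi[:, None, 1])
    dN = np.empty((xi.shape[0], 4, 2))
    dN[:, :, 0] = 0.25 * corners[None, :, 0] * (1 + corners[None, :, 1] * xi[:, None, 1])
    dN[:, :, 1] = 0.25 * corners[None, :, 1] * (1 + corners[None, :, 0] * xi[:, None, 0])
    return N, dN


_QN, _QdN = quad_shape(QUAD_GAUSS)


def _boundary_ring(faces) -> np.ndarray:
    """Ordered node loop of the open boundary of a quad-face set.

    The loop direction follows the face winding, so a cap built on the
    REVERSED loop closes the surface with consistent outward orientation.
    """
    from collections import defaultdict

    count = defaultdict(int)
    directed = {}
    for f in faces:
        for k in range(4):
            a, b = int(f[k]), int(f[(k + 1) % 4])
            if a == b:
                continue
            count[tuple(sorted((a, b)))] += 1
    succ = {}
    for f in faces:
        for k in range(4):
            a, b = int(f[k]), int(f[(k + 1) % 4])
            if a == b or count[tuple(sorted((a, b)))] != 1:
                continue
            succ[a] = b
    if not succ:
        raise ValueError("endocardial surface has no open boundary ring")
    start = next(iter(succ))
    ring = [start]
    while True:
        nxt = succ.get(ring[-1])
        if nxt is None:
            raise ValueError("endocardial boundary is not a single closed ring")
        if nxt == start:
            break
        ring.append(nxt)
        if len(ring) > len(succ):
            raise ValueError("endocardial boundary is not a single closed ring")
    return np.array(ring, dtype=np.int64)


def _cap_volume(x_ring: np.ndarray) -> float:
    """(1/3) int x . n dA over the triangle-fan cap on the REVERSED ring."""
    r = x_ring[::-1]
    c0 = r.mean(axis=0)
    a = r
    b = np.roll(r, -1, axis=0)
    nA = 0.5 * np.cross(b - a, c0 - a)          # triangle (a, b, c0)
    xbar = (a + b + c0) / 3.0
    return float(np.einsum("ti,ti->", xbar, nA)) / 3.0


def _surface_volume(nodes, faces, displacement=None, ring=None):
    """(1/3) oint x . n dA over the face set closed by the basal-ring cap."""
    x = np.asarray(nodes, float)
    if displacement is not None:
        x = x + displacement
    xf = x[faces]                                   # (Ef,4,3)
    xg = np.einsum("ga,fai->fgi", _QN, xf)
    tg = np.einsum("gak,fai->fgik", _QdN, xf)
    n = np.cross(tg[..., 0], tg[..., 1])
    vol = np.einsum("fgi,fgi->", xg, n) / 3.0
    if ring is None:
        ring = _boundary_ring(faces)
    return vol + _cap_volume(x[ring])


def _check_cavity_closure(mesh: LVMesh) -> None:
    ring = _boundary_ring(mesh.endo_faces)
    z = mesh.nodes[ring, 2]
    zb = mesh.dims.base_plane_height * mesh.scale_factor
    if not np.allclose(z, zb, atol=1e-6 * max(1.0, abs(zb) + 1.0)):
        raise ValueError("endocardial surface is not closed by the basal cap")


def cavity_volume(mesh: LVMesh, displacement: np.ndarray | None = None) -> float:
    """Cavity volume (ml) enclosed by the (deformed) endocardial surface and
    the basal cap, by divergence-theorem surface integration."""
    if displacement is not None:
        displacement = np.asarray(displacement, float)
        if displacement.shape != mesh.nodes.shape:
            raise ValueError("displacement must be defined on all nodes")
    v = _surface_volume(mesh.nodes, mesh.endo_faces, displacement)
    return float(v) * ML_PER_MM3


def wall_depth(mesh: LVMesh):
    """Per-element depth below the endocardial surface.

    Returns ``(depth_mm, depth_fraction)``: the shortest distance from each
    element centroid to the endocardial surface and that distance divided by
    the local wall thickness.
    """
    return mesh.depth_mm.copy(), mesh.depth_fraction.copy()
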