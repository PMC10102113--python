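"""Synthetic cardiac geometry: cables, slabs and an idealized left-atrial shell.

All meshes are linear tetrahedral meshes with per-element region labels,
orthonormal fiber/sheet/normal frames and named landmark sets.  The
left-atrial shell is an ellipsoidal thin wall with four pulmonary-vein
ostia, a mitral-annulus opening, an appendage bulge and interatrial entry
sites, standing in for a subject-specific anatomy.  Mechanics and
electrophysiology meshes are nested: the EP mesh is a uniform 1:8
refinement of the mechanics mesh, so every EP element lies in exactly one
mechanics element and the parent map is exact by construction.

Coordinates are in mm, indices are 0-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# region label codes
REGIONS = {
    "LA": 0,
    "RA": 1,
    "LV": 2,
    "RV": 3,
    "valve_plug": 4,
    "vessel": 5,
    "pericardial_layer": 6,
    "scar": 7,
}

# Kuhn subdivision of a hexahedron (corner order: bit0=x, bit1=y, bit2=z)
_HEX_TO_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 3, 2, 7],
        [0, 2, 6, 7],
        [0, 6, 4, 7],
        [0, 4, 5, 7],
        [0, 5, 1, 7],
    ]
)


@dataclass
class LabeledMesh:
    """Tetrahedral mesh with labels, frames and landmark sets."""

    vertices: np.ndarray  # (n_v, 3) float, mm
    tets: np.ndarray  # (n_e, 4) int
    region: np.ndarray  # (n_e,) int, REGIONS codes
    frames: np.ndarray  # (n_e, 3, 3); columns are f0, s0, n0
    vertex_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    surface_sets: dict[str, np.ndarray] = field(default_factory=dict)  # (k,3) tris
    transmural: np.ndarray | None = None  # (n_e,) in [0,1], endo=0
    column: np.ndarray | None = None  # (n_e,) transmural column id
    ep_to_mech: np.ndarray | None = None  # (n_e,) parent element (EP meshes)
    ep: "LabeledMesh | None" = None  # nested EP mesh (mechanics meshes)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def element_volumes(self) -> np.ndarray:
        return tet_volumes(self.vertices, self.tets)

    def centroids(self) -> np.ndarray:
        return self.vertices[self.tets].mean(axis=1)

    def fibers(self) -> np.ndarray:
        return self.frames[:, :, 0]


def tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed ordering)."""
    p = vertices[tets]
    a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def _fix_orientation(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap last two indices of inverted tets so all volumes are positive."""
    vol = tet_volumes(vertices, tets)
    bad = vol < 0
    tets = tets.copy()
    tets[bad, 2], tets[bad, 3] = tets[bad, 3].copy(), tets[bad, 2].copy()
    return tets


def check_frames(frames: np.ndarray, tol: float = 1e-10) -> None:
    """Raise if any frame is not a proper orthonormal triad."""
    gram = np.einsum("eij,eik->ejk", frames, frames)
    err = np.abs(gram - np.eye(3)).max()
    if err > tol:
        raise ValueError(f"frames not orthonormal: max deviation {err:.2e}")
    det = np.linalg.det(frames)
    if np.abs(det - 1.0).max() > 1e-8:
        raise ValueError("frames are not right-handed")


def _box_mesh(nx: int, ny: int, nz: int, hx: float, hy: float, hz: float):
    """Structured box of hexahedra split into 6 tets each (conforming)."""
    xs = np.arange(nx + 1) * hx
    ys = np.arange(ny + 1) * hy
    zs = np.arange(nz + 1) * hz
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    verts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    cells = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corners = [vid(i + (b & 1), j + ((b >> 1) & 1), k + ((b >> 2) & 1))
                           for b in range(8)]
                cells.append(corners)
    cells = np.asarray(cells)
    tets = cells[:, _HEX_TO_TETS].reshape(-1, 4)
    tets = _fix_orientation(verts, tets)
    return verts, tets


def make_cable(length: float, resolution: float, axis: str = "f",
               region: str = "LV") -> LabeledMesh:
    """Quasi-1D strand of tetrahedra with uniform frames along the x axis.

    ``axis`` selects which frame direction (f, s or n) is aligned with the
    strand so planar propagation probes that conductivity component.
    """
    if length <= 0 or resolution <= 0:
        raise ValueError("length and resolution must be positive")
    nx = int(round(length / resolution))
    verts, tets = _box_mesh(nx, 1, 1, length / nx, resolution, resolution)
    n_e = len(tets)
    ex, ey, ez = np.eye(3)
    # align the requested frame direction with the strand (+x) axis
    if axis == "f":
        f0, s0 = ex, ey
    elif axis == "s":
        f0, s0 = ey, ex
    elif axis == "n":
        f0, s0 = ey, ez  # n0 = f0 x s0 = +x
    else:
        raise ValueError("axis must be 'f', 's' or 'n'")
    cols = np.stack([f0, s0, np.cross(f0, s0)], axis=1)
    frames = np.broadcast_to(cols, (n_e, 3, 3)).copy()
    mesh = LabeledMesh(
        vertices=verts,
        tets=tets,
        region=np.full(n_e, REGIONS[region], dtype=int),
        frames=frames,
    )
    x = verts[:, 0]
    mesh.vertex_sets["x0"] = np.where(x < 1e-9)[0]
    mesh.vertex_sets["x1"] = np.where(x > length - 1e-9)[0]
    mesh.element_sets["all"] = np.arange(n_e)
    return mesh


def make_slab(lx: float, ly: float, lz: float, resolution: float,
              region: str = "LV") -> LabeledMesh:
    """Slab with endo (z=0) and epi (z=lz) surface sets; frames unset (identity)."""
    if min(lx, ly, lz) <= 0 or resolution <= 0:
        raise ValueError("dimensions and resolution must be positive")
    nx, ny, nz = (max(1, int(round(d / resolution))) for d in (lx, ly, lz))
    verts, tets = _box_mesh(nx, ny, nz, lx / nx, ly / ny, lz / nz)
    n_e = len(tets)
    mesh = LabeledMesh(
        vertices=verts,
        tets=tets,
        region=np.full(n_e, REGIONS[region], dtype=int),
        frames=np.broadcast_to(np.eye(3), (n_e, 3, 3)).copy(),
    )
    z = verts[:, 2]
    mesh.vertex_sets["endo"] = np.where(z < 1e-9)[0]
    mesh.vertex_sets["epi"] = np.where(z > lz - 1e-9)[0]
    zc = mesh.centroids()[:, 2]
    mesh.transmural = zc / lz
    mesh.element_sets["fast_layer"] = np.where(zc < lz / max(nz, 1) + 1e-9)[0]
    return mesh


# ---------------------------------------------------------------------------
# icosphere-based left-atrial shell


def _icosphere(level: int):
    """Unit icosphere: vertices and triangles after `level` 1:4 subdivisions."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(level):
        edge_mid: dict[tuple[int, int], int] = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in edge_mid:
                m = verts_list[a] + verts_list[b]
                m = m / np.linalg.norm(m)
                edge_mid[key] = len(verts_list)
                verts_list.append(m)
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces)
    return verts, faces


def _prism_tets(tri: np.ndarray, n_layer: int) -> np.ndarray:
    """Split the prism over triangle `tri` (bottom indices) into 3 tets.

    The quad-face diagonals follow the global-index rule (diagonal from the
    smallest bottom index), which makes the decomposition conforming across
    neighboring prisms and stacked layers.
    """
    i, j, k = sorted(tri)
    N = n_layer
    return np.array([
        [i, j, k, k + N],
        [i, j, k + N, j + N],
        [i, j + N, k + N, i + N],
    ])


# anatomical directions on the unit sphere (posterior = +y, superior = +z)
def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


_LANDMARK_DIRS = {
    "lspv": _unit([-0.527, 0.627, 0.574]),
    "rspv": _unit([0.527, 0.627, 0.574]),
    "lipv": _unit([-0.672, 0.672, -0.309]),
    "ripv": _unit([0.672, 0.672, -0.309]),
    "appendage": _unit([-0.75, -0.45, 0.55]),
    # interatrial entries sit on the septal (right) aspect, outside the
    # posterior box bounded by the PV rings and roof/inferior lines
    "bachmann": _unit([0.25, -0.80, 0.55]),
    "posterior_sup": _unit([0.90, 0.30, 0.31]),
    "posterior_mid": _unit([0.97, 0.22, -0.10]),
    "coronary_sinus": _unit([0.10, 0.82, -0.56]),
    "roof": _unit([0.0, 0.15, 1.0]),
    "anterior_annulus": _unit([0.0, -0.85, -0.55]),
    "posterior_annulus": _unit([0.0, 0.85, -0.55]),
    "lateral_annulus": _unit([-0.85, 0.0, -0.55]),
}

PV_NAMES = ("lspv", "rspv", "lipv", "ripv")

_ELLIPSOID_AXES = np.array([1.0, 0.9, 0.8])  # x, y, z semi-axis scale
_MITRAL_LAT_CUT = -0.62  # remove columns with direction z below this (annulus)
_OSTIUM_ANGLE = 0.24  # rad, angular radius of each PV ostium opening
_LAA_ANGLE = 0.45  # rad, appendage bulge extent
_LAA_BULGE = 0.35  # relative radial bulge amplitude


def make_la_shell(radius: float = 20.0, wall_thickness: float = 4.5,
                  resolution: float = 3.0, seed: int = 0,
                  n_layers: int = 2) -> LabeledMesh:
    """Idealized left-atrial shell (mechanics mesh with nested EP refinement).

    Parameters
    ----------
    radius : mean midsurface radius in mm (free fixture parameter).
    wall_thickness : transmural wall thickness, mm; the default follows the
        ~4.5 mm mean atrial wall of the reference anatomy.
    resolution : target in-plane edge length of the *mechanics* mesh, mm.
        The EP mesh is one uniform refinement finer.
    seed : deterministic tangential jitter of midsurface vertices, making
        distinct fixtures reproducible.
    n_layers : transmural element layers of the mechanics mesh (>= 2).
    """
    if not 0 < wall_thickness < radius:
        raise ValueError("need 0 < wall_thickness < radius")
    if n_layers < 2:
        raise ValueError("mechanics wall needs at least two element layers")
    # subdivision level from target edge length (base icosahedron edge ~1.05 r)
    level = max(1, int(np.ceil(np.log2(1.05 * radius / resolution))))
    sphere_v, sphere_f = _icosphere(level)
    edge_len = 1.05 * radius / 2**level
    if edge_len > 1.8 * _OSTIUM_ANGLE * radius:
        raise ValueError(
            f"resolution {resolution} mm too coarse to resolve PV ostia "
            f"(edge {edge_len:.1f} mm > ostium radius "
            f"{_OSTIUM_ANGLE * radius:.1f} mm)")

    rng = np.random.default_rng(seed)
    jitter = rng.normal(scale=0.02 * resolution / radius, size=sphere_v.shape)
    v = sphere_v + jitter - sphere_v * np.einsum("ij,ij->i", jitter, sphere_v)[:, None]
    v /= np.linalg.norm(v, axis=1, keepdims=True)

    # drop columns inside the mitral opening or a PV ostium
    tri_dir = v[sphere_f].mean(axis=1)
    tri_dir /= np.linalg.norm(tri_dir, axis=1, keepdims=True)
    keep = tri_dir[:, 2] > _MITRAL_LAT_CUT
    for name in PV_NAMES:
        ang = np.arccos(np.clip(tri_dir @ _LANDMARK_DIRS[name], -1, 1))
        keep &= ang > _OSTIUM_ANGLE
    faces = sphere_f[keep]
    used = np.unique(faces)
    remap = -np.ones(len(v), dtype=int)
    remap[used] = np.arange(len(used))
    faces = remap[faces]
    v = v[used]

    # radial profile with appendage bulge
    ang_laa = np.arccos(np.clip(v @ _LANDMARK_DIRS["appendage"], -1, 1))
    bulge = 1.0 + _LAA_BULGE * np.exp(-((ang_laa / _LAA_ANGLE) ** 2))
    n_mid = len(v)
    radii = radius + wall_thickness * (np.arange(n_layers + 1) / n_layers - 0.5)
    layers = [v * (r * bulge)[:, None] * _ELLIPSOID_AXES for r in radii]
    verts = np.concatenate(layers, axis=0)

    tets, col, trans = [], [], []
    for li in range(n_layers):
        off = li * n_mid
        for ci, tri in enumerate(faces):
            t = _prism_tets(tri + off, n_mid)
            tets.append(t)
            col += [ci] * 3
            trans += [(li + 0.5) / n_layers] * 3
    tets = np.concatenate(tets, axis=0)
    tets = _fix_orientation(verts, tets)
    n_e = len(tets)

    mesh = LabeledMesh(
        vertices=verts,
        tets=tets,
        region=np.full(n_e, REGIONS["LA"], dtype=int),
        frames=np.zeros((n_e, 3, 3)),
        transmural=np.asarray(trans),
        column=np.asarray(col),
    )

    # landmark vertex sets on the midsurface directions, all layers included
    vdir = verts / _ELLIPSOID_AXES
    vdir /= np.linalg.norm(vdir, axis=1, keepdims=True)

    def within(name, angle):
        ang = np.arccos(np.clip(vdir @ _LANDMARK_DIRS[name], -1, 1))
        return np.where(ang < angle)[0]

    for name in PV_NAMES:
        mesh.vertex_sets[f"pv_ostium_{name}"] = within(name, _OSTIUM_ANGLE + 0.14)
    mesh.vertex_sets["appendage"] = within("appendage", _LAA_ANGLE)
    mesh.vertex_sets["roof"] = within("roof", 0.35)
    mesh.vertex_sets["bachmann"] = within("bachmann", 0.18)
    mesh.vertex_sets["posterior_sup"] = within("posterior_sup", 0.18)
    mesh.vertex_sets["posterior_mid"] = within("posterior_mid", 0.18)
    mesh.vertex_sets["coronary_sinus"] = within("coronary_sinus", 0.20)
    mesh.vertex_sets["mitral_annulus"] = np.where(
        (vdir[:, 2] > _MITRAL_LAT_CUT - 0.08) & (vdir[:, 2] < _MITRAL_LAT_CUT + 0.10)
    )[0]

    # endo / epi surfaces: boundary triangles of innermost/outermost layers
    endo_v = np.arange(n_mid)
    epi_v = np.arange(n_layers * n_mid, (n_layers + 1) * n_mid)
    mesh.vertex_sets["endo"] = endo_v
    mesh.vertex_sets["epi"] = epi_v
    mesh.surface_sets["endo"] = faces[:, ::-1].copy()  # inward -> cavity-facing
    mesh.surface_sets["epi"] = faces + n_layers * n_mid

    _assign_shell_frames(mesh)
    ep = refine_uniform(mesh)
    mesh.ep = ep
    return mesh


def _surface_normal(points: np.ndarray) -> np.ndarray:
    """Outward ellipsoid-surface normal at points (bulge ignored)."""
    n = points / _ELLIPSOID_AXES**2
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def _assign_shell_frames(mesh: LabeledMesh) -> None:
    """Circumferential fibers with a roof-to-annulus rotation gradient."""
    c = mesh.centroids()
    n_hat = _surface_normal(c)
    zax = np.array([0.0, 0.0, 1.0])
    f = np.cross(np.broadcast_to(zax, n_hat.shape), n_hat)
    nrm = np.linalg.norm(f, axis=1, keepdims=True)
    nrm[nrm < 1e-12] = 1.0
    f /= nrm
    # rotate fibers in the tangent plane, 0 deg at annulus to 40 deg at roof
    lat = np.clip(c[:, 2] / np.linalg.norm(c, axis=1), -1, 1)
    chi = np.deg2rad(40.0) * (lat + 1.0) / 2.0
    s_in = np.cross(n_hat, f)
    f_rot = np.cos(chi)[:, None] * f + np.sin(chi)[:, None] * s_in
    s_rot = np.cross(n_hat, f_rot)
    mesh.frames = np.stack([f_rot, s_rot, n_hat], axis=2)


def refine_uniform(mesh: LabeledMesh) -> LabeledMesh:
    """Uniform 1:8 subdivision; children carry a parent map (nested EP mesh)."""
    verts = mesh.vertices
    tets = mesh.tets
    edges = {}
    verts_new = list(verts)

    def mid(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        if key not in edges:
            edges[key] = len(verts_new)
            verts_new.append(0.5 * (verts[a] + verts[b]))
        return edges[key]

    children = []
    parent = []
    for ei, (v0, v1, v2, v3) in enumerate(tets):
        m01, m02, m03 = mid(v0, v1), mid(v0, v2), mid(v0, v3)
        m12, m13, m23 = mid(v1, v2), mid(v1, v3), mid(v2, v3)
        kids = [
            [v0, m01, m02, m03], [v1, m01, m12, m13],
            [v2, m02, m12, m23], [v3, m03, m13, m23],
            [m01, m23, m02, m12], [m01, m23, m12, m13],
            [m01, m23, m13, m03], [m01, m23, m03, m02],
        ]
        children += kids
        parent += [ei] * 8
    verts_new = np.asarray(verts_new)
    children = np.asarray(children)
    children = _fix_orientation(verts_new, children)
    parent = np.asarray(parent)

    ep = LabeledMesh(
        vertices=verts_new,
        tets=children,
        region=mesh.region[parent].copy(),
        frames=mesh.frames[parent].copy(),
        transmural=None if mesh.transmural is None else mesh.transmural[parent],
        column=None if mesh.column is None else mesh.column[parent],
        ep_to_mech=parent,
    )
    # vertex landmark sets: original indices carry over unchanged
    for name, vs in mesh.vertex_sets.items():
        ep.vertex_sets[name] = vs.copy()
    for name, tris in mesh.surface_sets.items():
        sub = []
        for a, b, c in tris:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            sub += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        ep.surface_sets[name] = np.asarray(sub)
    return ep


def assign_fibers(mesh: LabeledMesh, rule: str) -> LabeledMesh:
    """Assign per-element frames by a named rule (in place, returns mesh).

    Rules
    -----
    ``axis``: fiber along +x everywhere (cable fixture).
    ``ventricular_slab``: transmural interpolation of the fiber angle from
        +60 deg (endo) to -60 deg (epi) and the sheet angle from -65 deg to
        +25 deg, the classic rule-based ventricular prescription.
    ``la_circumferential``: surface-tangent circumferential fibers with a
        roof-to-annulus gradient (the shell default).
    """
    if rule == "axis":
        mesh.frames = np.broadcast_to(np.eye(3), (mesh.n_elements, 3, 3)).copy()
        return mesh
    if rule == "ventricular_slab":
        if mesh.transmural is None:
            raise ValueError("slab rule needs a transmural coordinate")
        t = mesh.transmural
        alpha = np.deg2rad(60.0 - 120.0 * t)
        beta = np.deg2rad(-65.0 + 90.0 * t)
        f = np.stack([np.cos(alpha), np.sin(alpha), np.zeros_like(alpha)], axis=1)
        e3 = np.array([0.0, 0.0, 1.0])
        e2 = np.cross(np.broadcast_to(e3, f.shape), f)
        s = np.cos(beta)[:, None] * np.broadcast_to(e3, f.shape) \
            + np.sin(beta)[:, None] * e2
        n = np.cross(f, s)
        mesh.frames = np.stack([f, s, n], axis=2)
        return mesh
    if rule == "la_circumferential":
        _assign_shell_frames(mesh)
        return mesh
    raise ValueError(f"unknown fiber rule {rule!r}")


def fiber_angle_slab(transmural: float) -> float:
    """Slab-rule fiber angle in degrees at a transmural coordinate in [0, 1]."""
    return 60.0 - 120.0 * transmural


def check_nested(ep: LabeledMesh, mech: LabeledMesh, tol: float = 1e-9) -> bool:
    """Verify every EP element centroid lies inside its mapped parent tet."""
    if ep.ep_to_mech is None:
        raise ValueError("EP mesh has no parent map")
    cents = ep.centroids()
    p = mech.vertices[mech.tets[ep.ep_to_mech]]
    # barycentric coordinates of the centroid in the parent tet
    T = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=2)
    rhs = cents - p[:, 0]
    lam = np.linalg.solve(T, rhs[:, :, None])[:, :, 0]
    lam0 = 1.0 - lam.sum(axis=1)
    bary = np.concatenate([lam0[:, None], lam], axis=1)
    return bool((bary > -tol).all())


def probe_transmural_counts(mesh: LabeledMesh) -> np.ndarray:
    """Elements per transmural column (probe-line element counts)."""
    if mesh.column is None:
        raise ValueError("mesh has no column bookkeeping")
    # each column has 3 tets per layer; count layers by distinct transmural values
    counts = []
    for ci in np.unique(mesh.column):
        sel = mesh.column == ci
        counts.append(len(np.unique(np.round(mesh.transmural[sel], 9))))
    return np.asarray(counts)


def geodesic_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Great-circle angle between two unit directions."""
    return float(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0)))


def direction_of(points: np.ndarray) -> np.ndarray:
    """Unit sphere parameter direction of shell points (inverts ellipsoid map)."""
    d = points / _ELLIPSOID_AXES
    return d / np.linalg.norm(d, axis=-1, keepdims=True)
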