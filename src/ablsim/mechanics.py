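"""Passive and active solid mechanics of the atrial wall.

Constitutive models: an orthotropic exponential (Fung-type) strain energy
for myocardium with quadratic-log volumetric penalty, and a compressible
Neo-Hookean law for passive support tissue.  Scar tissue uses the
myocardial law with isotropized anisotropy coefficients, doubled shear
modulus and a five-fold exponent.

Discretization: total Lagrangian, linear tetrahedra with one-point
quadrature, lumped mass.  Dynamics: Newmark-beta (beta=0.3, gamma=0.6 by
default, 1 ms steps) with Rayleigh damping built from the lumped mass and
the tangent stiffness frozen at the reference state.  External loads:
follower pressure on endocardial surfaces, penalty tethering to a
pericardium-like surface through a piecewise smooth gap function, nodal
boundary springs, zero-displacement Dirichlet sets.

Internal units: mm, ms, g -> stress in MPa, force in N.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import LabeledMesh, REGIONS

MMHG_TO_MPA = 133.322e-6
PA_TO_MPA = 1e-6
KG_M3_TO_G_MM3 = 1e-6


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive parameters; stresses stored in Pa for readability."""

    mu: float                  # Pa
    alpha: float               # dimensionless exponent (orthotropic model)
    kappa: float               # Pa
    rho0: float = 1082.0       # kg/m^3
    b: tuple = (1.0, 0.4, 0.3, 0.7, 0.6, 0.2)  # bff bss bnn bfs bfn bns
    model: str = "orthotropic-exponential"

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.kappa < self.mu:
            raise ValueError("need kappa >= mu for near-incompressibility")
        if any(x < 0 for x in self.b):
            raise ValueError("b coefficients must be nonnegative")

    def b_matrix(self) -> np.ndarray:
        bff, bss, bnn, bfs, bfn, bns = self.b
        return np.array([[bff, bfs, bfn], [bfs, bss, bns], [bfn, bns, bnn]])


MYOCARDIUM = MaterialParams(mu=325.56, alpha=22.0, kappa=1e6)


def scar_params(base: MaterialParams = MYOCARDIUM) -> MaterialParams:
    """Scar: isotropized b, two-fold mu, five-fold alpha."""
    return replace(base, mu=2.0 * base.mu, alpha=5.0 * base.alpha,
                   b=(1.0, 1.0, 1.0, 0.5, 0.5, 0.5))


SCAR = scar_params()
VESSEL = MaterialParams(mu=14.9e3, alpha=0.0, kappa=1e6, model="neo-hookean")
VALVE_PLUG = MaterialParams(mu=1e6, alpha=0.0, kappa=1e6, model="neo-hookean")
PERI_APICAL = MaterialParams(mu=2e3, alpha=0.0, kappa=1e6, model="neo-hookean")
PERI_BASAL = MaterialParams(mu=2e3, alpha=0.0, kappa=5e4, model="neo-hookean")

DEFAULT_MATERIALS = {
    REGIONS["LA"]: MYOCARDIUM, REGIONS["RA"]: MYOCARDIUM,
    REGIONS["LV"]: MYOCARDIUM, REGIONS["RV"]: MYOCARDIUM,
    REGIONS["scar"]: SCAR, REGIONS["vessel"]: VESSEL,
    REGIONS["valve_plug"]: VALVE_PLUG,
    REGIONS["pericardial_layer"]: PERI_BASAL,
}


# ---------------------------------------------------------------------------
# constitutive laws (vectorized over leading axes)


def strain_energy(E: np.ndarray, J: np.ndarray, params: MaterialParams,
                  frame: np.ndarray | None = None) -> np.ndarray:
    """Strain energy density in Pa.

    `E` in global coordinates; `frame` columns (f0, s0, n0) rotate it into
    material axes (identity frame assumed when omitted).
    """
    E = np.asarray(E, dtype=float)
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise ValueError("J must be positive")
    if params.model == "neo-hookean":
        C = 2.0 * E + np.eye(3)
        trC_hat = J ** (-2.0 / 3.0) * np.trace(C, axis1=-2, axis2=-1)
        return (params.mu / 2.0 * (trC_hat - 3.0)
                + params.kappa / 2.0 * (J - 1.0) ** 2)
    if frame is not None:
        E = np.einsum("...ia,...ij,...jb->...ab", frame, E, frame)
    bm = params.b_matrix()
    Q = np.einsum("ab,...ab,...ab->...", bm, E, E)
    return (params.mu / 2.0 * (np.exp(params.alpha * Q) - 1.0)
            + params.kappa / 2.0 * np.log(J) ** 2)


def _kinematics(F: np.ndarray):
    C = np.einsum("...ki,...kj->...ij", F, F)
    E = 0.5 * (C - np.eye(3))
    J = np.linalg.det(F)
    return C, E, J


def pk2_stress(F: np.ndarray, frame: np.ndarray | None,
               params: MaterialParams) -> np.ndarray:
    """Passive second Piola-Kirchhoff stress (Pa), analytic derivative of Psi."""
    F = np.asarray(F, dtype=float)
    C, E, J = _kinematics(F)
    if np.any(J <= 0):
        raise ValueError("element inversion: det F <= 0")
    Cinv = np.linalg.inv(C)
    if params.model == "neo-hookean":
        trC = np.trace(C, axis1=-2, axis2=-1)
        S_iso = params.mu * J[..., None, None] ** (-2.0 / 3.0) * (
            np.broadcast_to(np.eye(3), C.shape)
            - (trC / 3.0)[..., None, None] * Cinv)
        S_vol = (params.kappa * (J - 1.0) * J)[..., None, None] * Cinv
        return S_iso + S_vol
    if frame is None:
        frame = np.broadcast_to(np.eye(3), F.shape)
    Et = np.einsum("...ia,...ij,...jb->...ab", frame, E, frame)
    bm = params.b_matrix()
    Q = np.einsum("ab,...ab,...ab->...", bm, Et, Et)
    St = (params.mu * params.alpha * np.exp(Q * params.alpha))[..., None, None] \
        * (bm * Et)
    S_iso = np.einsum("...ia,...ab,...jb->...ij", frame, St, frame)
    S_vol = (params.kappa * np.log(J))[..., None, None] * Cinv
    return S_iso + S_vol


def material_tangent(F: np.ndarray, frame: np.ndarray | None,
                     params: MaterialParams) -> np.ndarray:
    """dS/dE (Pa), minor/major symmetric, shape (..., 3, 3, 3, 3)."""
    F = np.asarray(F, dtype=float)
    C, E, J = _kinematics(F)
    Cinv = np.linalg.inv(C)
    CC = np.einsum("...ij,...kl->...ijkl", Cinv, Cinv)
    Csym = 0.5 * (np.einsum("...ik,...jl->...ijkl", Cinv, Cinv)
                  + np.einsum("...il,...jk->...ijkl", Cinv, Cinv))
    if params.model == "neo-hookean":
        trC = np.trace(C, axis1=-2, axis2=-1)
        I3 = np.broadcast_to(np.eye(3), C.shape)
        Jm23 = J ** (-2.0 / 3.0)
        A = I3 - (trC / 3.0)[..., None, None] * Cinv
        dSdC = (params.mu * (-1.0 / 3.0) * Jm23[..., None, None, None, None]
                * (np.einsum("...ij,...kl->...ijkl", A, Cinv)
                   + np.einsum("...ij,...kl->...ijkl", Cinv, I3))
                + params.mu * Jm23[..., None, None, None, None]
                * (trC / 3.0)[..., None, None, None, None] * Csym
                + params.kappa / 2.0 * ((2 * J - 1.0) * J)[..., None, None, None, None] * CC
                - params.kappa * ((J - 1.0) * J)[..., None, None, None, None] * Csym)
        return 2.0 * dSdC
    if frame is None:
        frame = np.broadcast_to(np.eye(3), F.shape)
    Et = np.einsum("...ia,...ij,...jb->...ab", frame, E, frame)
    bm = params.b_matrix()
    Q = np.einsum("ab,...ab,...ab->...", bm, Et, Et)
    expQ = np.exp(params.alpha * Q)
    bE = bm * Et
    Isym = 0.5 * (np.einsum("ik,jl->ijkl", np.eye(3), np.eye(3))
                  + np.einsum("il,jk->ijkl", np.eye(3), np.eye(3)))
    bI = bm[:, :, None, None] * Isym
    Ct = params.mu * params.alpha * expQ[..., None, None, None, None] * (
        bI + 2.0 * params.alpha
        * np.einsum("...ij,...kl->...ijkl", bE, bE))
    C_iso = np.einsum("...ia,...jb,...abcd,...kc,...ld->...ijkl",
                      frame, frame, Ct, frame, frame)
    lnJ = np.log(J)
    C_vol = (params.kappa * (CC - 2.0 * lnJ[..., None, None, None, None] * Csym))
    return C_iso + C_vol


# ---------------------------------------------------------------------------
# contact gap function


@dataclass
class SphereSurface:
    """Analytic pericardium-like target surface (sphere)."""

    center: np.ndarray
    radius: float

    def project(self, x: np.ndarray):
        rel = np.atleast_2d(x) - self.center
        r = np.linalg.norm(rel, axis=1, keepdims=True)
        r = np.where(r < 1e-12, 1e-12, r)
        n = rel / r
        return self.center + self.radius * n, n


@dataclass
class ContactSpec:
    k_epi: float = 10.0       # MPa/mm penalty stiffness
    d: float = 0.1            # mm quadratic-to-linear transition
    d_M: float = 8.0          # mm maximal tether distance
    surface: SphereSurface | None = None
    surface_set: str = "epi"  # Gamma_P

    def __post_init__(self):
        if not 0 < self.d < self.d_M:
            raise ValueError("need 0 < d < d_M")


def gap(x: np.ndarray, surface: SphereSurface, spec: ContactSpec) -> np.ndarray:
    """Piecewise gap g(x) in mm: quadratic below d, linear to d_M, 0 beyond."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    proj, _ = surface.project(x)
    dist = np.linalg.norm(x - proj, axis=1)
    return gap_of_distance(dist, spec)


def gap_of_distance(dist: np.ndarray, spec: ContactSpec) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    g = np.where(dist < spec.d, dist**2 / (2.0 * spec.d), dist - spec.d / 2.0)
    return np.where(dist > spec.d_M, 0.0, g)


# ---------------------------------------------------------------------------
# FEM model


@dataclass
class DynamicsSpec:
    beta: float = 0.3
    gamma: float = 0.6
    dt: float = 1.0           # ms
    alpha1: float = 0.5       # 1/ms  (500 1/s)
    alpha2: float = 5.0       # ms    (0.005 s)
    newton_tol: float = 1e-8
    max_newton: int = 25

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def unconditionally_stable(self) -> bool:
        return self.beta >= 0.25 * (0.5 + self.gamma) ** 2


@dataclass
class MechState:
    u: np.ndarray             # (n, 3) mm
    v: np.ndarray
    a: np.ndarray
    t: float = 0.0            # ms
    cavity_volumes: dict = field(default_factory=dict)  # mL


def _tri_area_normals(verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Half cross products: area-weighted normals per triangle."""
    p = verts[tris]
    return 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])


def boundary_loops(tris: np.ndarray) -> list[np.ndarray]:
    """Ordered vertex loops of the open boundaries of a triangle surface."""
    from collections import defaultdict

    count: dict[tuple, int] = defaultdict(int)
    for a, b, c in tris:
        for u_, v_ in ((a, b), (b, c), (c, a)):
            count[(min(u_, v_), max(u_, v_))] += 1
    out: dict[int, list[int]] = defaultdict(list)
    n_edges = 0
    for a, b, c in tris:
        for u_, v_ in ((a, b), (b, c), (c, a)):
            if count[(min(u_, v_), max(u_, v_))] == 1:
                out[u_].append(v_)
                n_edges += 1
    # consume each directed boundary edge exactly once; openings that pinch
    # at a shared vertex simply yield merged loops, which cap correctly
    loops = []
    consumed = 0
    while consumed < n_edges:
        start = next(u_ for u_, vs in out.items() if vs)
        loop = [start]
        cur = out[start].pop()
        consumed += 1
        while cur != start:
            loop.append(cur)
            cur = out[cur].pop()
            consumed += 1
        if len(loop) >= 3:
            loops.append(np.asarray(loop))
    return loops


def surface_volume(verts: np.ndarray, tris: np.ndarray,
                   loops: list[np.ndarray] | None = None) -> float:
    """Enclosed volume by divergence theorem; open boundaries capped by
    centroid fans (caps follow the deforming boundary rings)."""
    p = verts[tris]
    vol = np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum() / 6.0
    if loops is None:
        loops = boundary_loops(tris)
    for loop in loops:
        ring = verts[loop]
        c = ring.mean(axis=0)
        # boundary loops run along the surface orientation; the cap must
        # traverse each boundary edge the opposite way to close the manifold
        a = np.roll(ring, -1, axis=0)
        b = ring
        vol += np.einsum("ij,ij->i", a, np.cross(b, np.broadcast_to(c, a.shape))
                         ).sum() / 6.0
    return float(vol)


class MechModel:
    """Total-Lagrangian FEM on a labeled tetrahedral mesh.

    Parameters
    ----------
    mesh : mechanics mesh with frames and surface sets.
    materials : mapping region code -> MaterialParams.
    dirichlet : names of vertex sets with u = 0.
    pressure_surface : surface-set name receiving the cavity pressure
        (follower load), oriented so positive pressure inflates.
    springs : (vertex set name, stiffness N/mm) nodal tethers, or None.
    contact : ContactSpec with an analytic target surface, or None.
    """

    def __init__(self, mesh: LabeledMesh, materials: dict | None = None,
                 dirichlet: tuple[str, ...] = (), pressure_surface: str = "endo",
                 springs: tuple[str, float] | None = None,
                 contact: ContactSpec | None = None):
        self.mesh = mesh
        self.materials = dict(DEFAULT_MATERIALS if materials is None else materials)
        self.n = mesh.n_vertices
        p = mesh.vertices[mesh.tets]
        Tm = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0],
                       p[:, 3] - p[:, 0]], axis=2)
        self.vol0 = np.abs(np.linalg.det(Tm)) / 6.0
        Tinv = np.linalg.inv(Tm)
        self.grads = np.zeros((mesh.n_elements, 4, 3))
        self.grads[:, 1:, :] = Tinv
        self.grads[:, 0, :] = -Tinv.sum(axis=1)
        # group elements by material for vectorized constitutive calls
        self.groups = {}
        for code in np.unique(mesh.region):
            mat = self.materials[int(code)]
            self.groups.setdefault(mat, []).append(mesh.region == code)
        self.groups = {m: np.logical_or.reduce(sels)
                       for m, sels in self.groups.items()}
        # lumped mass (g): rho0 [kg/m^3] * 1e-6 -> g/mm^3
        self.mass = np.zeros(self.n)
        for mat, sel in self.groups.items():
            rho = mat.rho0 * KG_M3_TO_G_MM3
            np.add.at(self.mass, mesh.tets[sel].ravel(),
                      np.repeat(rho * self.vol0[sel] / 4.0, 4))
        self.fixed = np.zeros(self.n, dtype=bool)
        for name in dirichlet:
            self.fixed[mesh.vertex_sets[name]] = True
        self.free_dof = np.repeat(~self.fixed, 3)
        self.pressure_surface = pressure_surface
        self.surf_tris = mesh.surface_sets.get(pressure_surface)
        self.cavity_loops = (boundary_loops(self.surf_tris)
                             if self.surf_tris is not None else None)
        self.springs = springs
        if springs is not None:
            name, k = springs
            self.spring_nodes = mesh.vertex_sets[name]
            self.spring_k = float(k)
        self.contact = contact
        if contact is not None:
            tris = mesh.surface_sets[contact.surface_set]
            areas = np.linalg.norm(_tri_area_normals(mesh.vertices, tris), axis=1)
            self.contact_nodes = np.unique(tris)
            node_area = np.zeros(self.n)
            np.add.at(node_area, tris.ravel(), np.repeat(areas / 3.0, 3))
            self.contact_area = node_area[self.contact_nodes]
        # active tension support
        self.active_fn = None     # callable (t, lam_f) -> S_A (kPa) per element
        self._K0 = None

    # -- constitutive assembly ------------------------------------------------

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        du = u[self.mesh.tets]  # (e, 4, 3)
        return np.eye(3) + np.einsum("eai,eaj->eij", du, self.grads)

    def internal_force(self, u: np.ndarray, t: float = 0.0,
                       want_tangent: bool = False):
        mesh = self.mesh
        F = self.deformation_gradients(u)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            bad = int(np.argmin(J))
            raise RuntimeError(f"element inversion in element {bad}")
        S = np.zeros((mesh.n_elements, 3, 3))
        Cmat = np.zeros((mesh.n_elements, 3, 3, 3, 3)) if want_tangent else None
        # overly large trial steps can overflow exp(alpha*Q); the resulting
        # inf residual is rejected by the Newton line search
        with np.errstate(over="ignore"):
            for mat, sel in self.groups.items():
                S[sel] = pk2_stress(F[sel], mesh.frames[sel], mat) * PA_TO_MPA
                if want_tangent:
                    Cmat[sel] = material_tangent(F[sel], mesh.frames[sel], mat) \
                        * PA_TO_MPA
        if self.active_fn is not None:
            f0 = mesh.frames[:, :, 0]
            lam = np.linalg.norm(np.einsum("eij,ej->ei", F, f0), axis=1)
            S_A = self.active_fn(t, lam) * 1e-3  # kPa -> MPa
            outer = f0[:, :, None] * f0[:, None, :]
            S = S + (S_A / lam)[:, None, None] * outer
            if want_tangent:
                # geometric part of the active stress derivative
                dlam = -(S_A / lam**3)
                Cmat = Cmat + dlam[:, None, None, None, None] \
                    * np.einsum("eij,ekl->eijkl", outer, outer)
        P = np.einsum("eij,ejk->eik", F, S)
        fe = np.einsum("e,eik,eak->eai", self.vol0, P, self.grads)
        f = np.zeros((self.n, 3))
        np.add.at(f, mesh.tets.ravel(), fe.reshape(-1, 3))
        if not want_tangent:
            return f, None
        # element tangent: geometric + material
        geo = np.einsum("e,eaj,ejl,ebl->eab", self.vol0, self.grads, S, self.grads)
        matp = np.einsum("e,eaJ,eiM,eMJLN,ekN,ebL->eaibk",
                         self.vol0, self.grads, F, Cmat, F, self.grads,
                         optimize=True)
        Ke = matp + np.einsum("eab,ik->eaibk", geo, np.eye(3))
        return f, Ke

    # -- external loads -------------------------------------------------------

    def external_force(self, u: np.ndarray, pressure_mmhg: float,
                       want_tangent: bool = False):
        """Follower pressure + springs + contact; returns (f_ext, K_ext_coo)."""
        f = np.zeros((self.n, 3))
        rows, cols, vals = [], [], []
        x = self.mesh.vertices + u
        if self.surf_tris is not None and pressure_mmhg != 0.0:
            p = pressure_mmhg * MMHG_TO_MPA
            tris = self.surf_tris
            an = _tri_area_normals(x, tris)  # oriented into the cavity
            # force pushes the wall away from the cavity: -p * n_cavity
            for a in range(3):
                np.add.at(f, tris[:, a], -(p / 3.0) * an)
            if want_tangent:
                pts = x[tris]
                for a in range(3):
                    for b in range(3):
                        # d(area normal)/dx_b = 0.5 skew(edge opposite pair)
                        o1, o2 = (b + 1) % 3, (b + 2) % 3
                        dn = 0.5 * _skew(pts[:, o1] - pts[:, o2])
                        block = -(p / 3.0) * dn
                        rows.append(np.repeat(tris[:, a] * 3, 9)
                                    + np.tile(np.repeat(np.arange(3), 3),
                                              len(tris)))
                        cols.append(np.repeat(tris[:, b] * 3, 9)
                                    + np.tile(np.arange(3), 3 * len(tris)))
                        vals.append(block.reshape(len(tris), 9).ravel())
        if self.springs is not None:
            nodes = self.spring_nodes
            f[nodes] -= self.spring_k * u[nodes]
            if want_tangent:
                for i in range(3):
                    rows.append(nodes * 3 + i)
                    cols.append(nodes * 3 + i)
                    vals.append(np.full(len(nodes), -self.spring_k))
        if self.contact is not None and self.contact.surface is not None:
            fc, Kc = self._contact_force(x, want_tangent)
            f += fc
            if want_tangent and Kc is not None:
                r, c, v = Kc
                rows.append(r)
                cols.append(c)
                vals.append(v)
        K = None
        if want_tangent and rows:
            K = sp.coo_matrix((np.concatenate(vals),
                               (np.concatenate(rows), np.concatenate(cols))),
                              shape=(3 * self.n, 3 * self.n))
        return f, K

    def _contact_node_force(self, xs: np.ndarray) -> np.ndarray:
        spec = self.contact
        proj, _ = spec.surface.project(xs)
        rel = proj - xs
        dist = np.linalg.norm(rel, axis=1)
        g = gap_of_distance(dist, spec)
        direction = rel / np.where(dist < 1e-12, 1.0, dist)[:, None]
        return (spec.k_epi * g * self.contact_area)[:, None] * direction

    def _contact_force(self, x: np.ndarray, want_tangent: bool):
        nodes = self.contact_nodes
        fc_nodes = self._contact_node_force(x[nodes])
        f = np.zeros((self.n, 3))
        f[nodes] = fc_nodes
        K = None
        if want_tangent:
            # per-node central differences; the force is local per node
            h = 1e-6
            blocks = np.zeros((len(nodes), 3, 3))
            for k in range(3):
                xp = x[nodes].copy()
                xp[:, k] += h
                xm = x[nodes].copy()
                xm[:, k] -= h
                blocks[:, :, k] = (self._contact_node_force(xp)
                                   - self._contact_node_force(xm)) / (2 * h)
            r = (np.repeat(nodes * 3, 9)
                 + np.tile(np.repeat(np.arange(3), 3), len(nodes)))
            c = (np.repeat(nodes * 3, 9)
                 + np.tile(np.arange(3), 3 * len(nodes)))
            K = (r, c, blocks.reshape(-1))
        return f, K

    # -- assembly helpers -----------------------------------------------------

    def _assemble(self, Ke: np.ndarray) -> sp.csc_matrix:
        mesh = self.mesh
        n_e = mesh.n_elements
        dof = (mesh.tets[:, :, None] * 3 + np.arange(3)).reshape(n_e, 12)
        KeM = Ke.transpose(0, 1, 2, 3, 4).reshape(n_e, 12, 12)
        rows = np.repeat(dof, 12, axis=1).ravel()
        cols = np.tile(dof, (1, 12)).ravel()
        return sp.coo_matrix((KeM.ravel(), (rows, cols)),
                             shape=(3 * self.n, 3 * self.n)).tocsc()

    def stiffness(self, u: np.ndarray, t: float = 0.0) -> sp.csc_matrix:
        _, Ke = self.internal_force(u, t, want_tangent=True)
        return self._assemble(Ke)

    def reference_stiffness(self) -> sp.csc_matrix:
        if self._K0 is None:
            active_fn = self.active_fn
            self.active_fn = None
            self._K0 = self.stiffness(np.zeros((self.n, 3)))
            self.active_fn = active_fn
        return self._K0

    def residual(self, u, v=None, a=None, pressure: float = 0.0,
                 t: float = 0.0, spec: DynamicsSpec | None = None,
                 want_tangent: bool = False):
        """R = M a + D v + f_int(u) - f_ext(u); tangent w.r.t. u for statics."""
        f_int, Ke = self.internal_force(u, t, want_tangent)
        f_ext, K_ext = self.external_force(u, pressure, want_tangent)
        R = f_int - f_ext
        if v is not None and spec is not None:
            D = self.damping(spec)
            R = R + (D @ v.ravel()).reshape(-1, 3)
        if a is not None:
            R = R + self.mass[:, None] * a
        R[self.fixed] = 0.0
        if not want_tangent:
            return R, None
        K = self._assemble(Ke)
        if K_ext is not None:
            K = K - K_ext.tocsc()
        return R, K

    def damping(self, spec: DynamicsSpec) -> sp.csc_matrix:
        M = sp.diags(np.repeat(self.mass, 3))
        return (spec.alpha1 * M + spec.alpha2 * self.reference_stiffness()).tocsc()

    def _solve_linear(self, K: sp.csc_matrix, R: np.ndarray) -> np.ndarray:
        free = self.free_dof
        Kff = K[free][:, free]
        du = np.zeros(3 * self.n)
        du[free] = splu(Kff.tocsc()).solve(-R.ravel()[free])
        return du.reshape(-1, 3)

    # -- solvers --------------------------------------------------------------

    def static_solve(self, pressure_mmhg: float, u0: np.ndarray | None = None,
                     t: float = 0.0, n_steps: int = 4, tol: float = 1e-8,
                     max_newton: int = 25) -> np.ndarray:
        """Quasi-static solution under a follower pressure.

        A supplied initial guess is used for a direct Newton solve first;
        otherwise (or on failure) the load is ramped in `n_steps`.
        """
        if u0 is not None:
            try:
                return self._newton(u0.copy(), pressure_mmhg, t, tol,
                                    max_newton)
            except RuntimeError:
                pass
        u = np.zeros((self.n, 3))
        for frac in np.linspace(1.0 / n_steps, 1.0, n_steps):
            p = pressure_mmhg * frac
            u = self._newton(u, p, t, tol, max_newton)
        return u

    def _newton(self, u, pressure, t, tol, max_newton):
        R, K = self.residual(u, pressure=pressure, t=t, want_tangent=True)
        scale = max(np.linalg.norm(R), 1e-12)
        for it in range(max_newton):
            if np.linalg.norm(R) <= tol * scale or np.linalg.norm(R) < 1e-14:
                return u
            du = self._solve_linear(K, R)
            # damped update guarding against element inversion
            step = 1.0
            R_new = K_new = None
            for _ in range(10):
                try:
                    R_new, K_new = self.residual(u + step * du, pressure=pressure,
                                                 t=t, want_tangent=True)
                except RuntimeError:
                    step *= 0.5
                    continue
                if np.linalg.norm(R_new) < np.linalg.norm(R) or step < 0.2:
                    break
                step *= 0.5
            if R_new is None:
                raise RuntimeError("line search failed (element inversion)")
            u = u + step * du
            R, K = R_new, K_new
        if np.linalg.norm(R) > 100 * tol * scale:
            raise RuntimeError(
                f"Newton did not converge: |R| {np.linalg.norm(R):.2e}")
        return u

    def newmark_step(self, state: MechState, spec: DynamicsSpec,
                     pressure_mmhg: float = 0.0) -> MechState:
        """One implicit Newmark step solved by Newton on the displacement."""
        dt, beta, gamma = spec.dt, spec.beta, spec.gamma
        un, vn, an = state.u, state.v, state.a
        t1 = state.t + dt

        def kinematics(u1):
            a1 = (u1 - un - dt * vn - (0.5 - beta) * dt**2 * an) / (beta * dt**2)
            v1 = vn + (1 - gamma) * dt * an + gamma * dt * a1
            return v1, a1

        u1 = un + dt * vn + 0.5 * dt**2 * an  # predictor
        D = self.damping(spec)
        M3 = np.repeat(self.mass, 3)
        for it in range(spec.max_newton):
            v1, a1 = kinematics(u1)
            R, K = self.residual(u1, v1, a1, pressure=pressure_mmhg, t=t1,
                                 want_tangent=True)
            nrm = np.linalg.norm(R)
            if it == 0:
                scale = max(nrm, 1e-12)
            if nrm <= spec.newton_tol * scale or nrm < 1e-14:
                break
            Keff = (K + gamma / (beta * dt) * D
                    + sp.diags(M3 / (beta * dt**2))).tocsc()
            du = self._solve_linear(Keff, R)
            u1 = u1 + du
        else:
            raise RuntimeError("Newmark Newton did not converge")
        v1, a1 = kinematics(u1)
        u1c = u1.copy()
        u1c[self.fixed] = 0.0
        vols = {}
        if self.surf_tris is not None:
            vols["LA"] = self.cavity_volume(u1c)
        return MechState(u=u1c, v=v1, a=a1, t=t1, cavity_volumes=vols)

    # -- derived quantities ---------------------------------------------------

    def cavity_volume(self, u: np.ndarray, surface: str | None = None) -> float:
        """Chamber cavity volume (mL) enclosed by a surface set (capped)."""
        name = surface or self.pressure_surface
        tris = self.mesh.surface_sets[name]
        loops = self.cavity_loops if name == self.pressure_surface else None
        x = self.mesh.vertices + u
        v_mm3 = surface_volume(x, tris, loops)
        return abs(v_mm3) / 1e3

    def annulus_displacement(self, u: np.ndarray,
                             ring_set: str = "mitral_annulus") -> float:
        """AVPD analogue: mean axial (z) displacement of the annulus ring."""
        nodes = self.mesh.vertex_sets[ring_set]
        return float(u[nodes, 2].mean())


def _skew(v: np.ndarray) -> np.ndarray:
    """Skew matrices for an (n,3) array: (n,3,3) with S@w = v x w."""
    n = len(v)
    S = np.zeros((n, 3, 3))
    S[:, 0, 1] = -v[:, 2]
    S[:, 0, 2] = v[:, 1]
    S[:, 1, 0] = v[:, 2]
    S[:, 1, 2] = -v[:, 0]
    S[:, 2, 0] = -v[:, 1]
    S[:, 2, 1] = v[:, 0]
    return S


# ---------------------------------------------------------------------------
# unloading and inflation


def unload(model_factory, X_imaged: np.ndarray, pressure_mmhg: float,
           max_iter: int = 20, tol: float = 0.1, relax: float = 0.9):
    """Backward-displacement recovery of the pressure-free configuration.

    `model_factory(vertices)` must return a MechModel built on the given
    reference vertex positions.  Iterates
    X_unloaded <- X_unloaded - relax * (X_unloaded + u(X_unloaded; p) - X_imaged)
    until inflating the unloaded geometry reproduces the imaged geometry
    within `tol` (mm, max nodal error).  Returns (unloaded vertices, error
    history); raises with the history attached if the fixed point diverges.
    """
    X = X_imaged.copy()
    history = []
    for _ in range(max_iter):
        m = model_factory(X)
        u = m.static_solve(pressure_mmhg)
        err = np.linalg.norm(X + u - X_imaged, axis=1).max()
        history.append(err)
        if err < tol:
            return X, np.asarray(history)
        X = X - relax * (X + u - X_imaged)
        if len(history) > 3 and history[-1] > 2.0 * history[0]:
            raise RuntimeError(f"backward displacement diverged: {history}")
    return X, np.asarray(history)


def newmark_march_linear(M: np.ndarray, C: np.ndarray, K: np.ndarray,
                         f_ext, u0: np.ndarray, v0: np.ndarray,
                         spec: DynamicsSpec, n_steps: int):
    """Newmark time marching for a dense linear system M a + C v + K u = f(t).

    Reference implementation of the same update formulas used by the FEM
    stepper; returns arrays (t, u, v, a) including the initial state.
    """
    M, C, K = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (M, C, K))
    u = np.atleast_1d(np.asarray(u0, dtype=float)).copy()
    v = np.atleast_1d(np.asarray(v0, dtype=float)).copy()
    a = np.linalg.solve(M, f_ext(0.0) - C @ v - K @ u)
    dt, beta, gamma = spec.dt, spec.beta, spec.gamma
    Keff = K + gamma / (beta * dt) * C + M / (beta * dt**2)
    ts, us, vs, accs = [0.0], [u.copy()], [v.copy()], [a.copy()]
    for n in range(n_steps):
        t1 = (n + 1) * dt
        rhs = (f_ext(t1)
               + M @ ((u + dt * v + (0.5 - beta) * dt**2 * a) / (beta * dt**2))
               + C @ (gamma / (beta * dt) * u
                      - (1 - gamma / beta) * v
                      - dt * (1 - gamma / (2 * beta)) * a))
        u1 = np.linalg.solve(Keff, rhs)
        a1 = (u1 - u - dt * v - (0.5 - beta) * dt**2 * a) / (beta * dt**2)
        v1 = v + (1 - gamma) * dt * a + gamma * dt * a1
        u, v, a = u1, v1, a1
        ts.append(t1)
        us.append(u.copy())
        vs.append(v.copy())
        accs.append(a.copy())
    return (np.asarray(ts), np.asarray(us), np.asarray(vs), np.asarray(accs))


def edpvr(model_factory, pressures_mmhg) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-static inflation curve (p, V) from the supplied model factory."""
    vols = []
    model = model_factory()
    u = None
    for p in pressures_mmhg:
        u = model.static_solve(p, u0=u)
        vols.append(model.cavity_volume(u))
    return np.asarray(pressures_mmhg, dtype=float), np.asarray(vols)
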