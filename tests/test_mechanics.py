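"""Constitutive laws, FEM residual/Jacobian, contact, dynamics, unloading."""
import numpy as np
import pytest

from ablsim import lesions as les
from ablsim import mechanics as mech
from ablsim import mesh as msh


def _random_F(rng, scale=0.08):
    while True:
        F = np.eye(3) + scale * rng.normal(size=(3, 3))
        if np.linalg.det(F) > 0.5:
            return F


def _random_frame(rng):
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 2] *= -1
    return Q


def _fd_stress(E, params, frame, h=1e-6):
    S = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            dE = np.zeros((3, 3))
            dE[i, j] += h / 2
            dE[j, i] += h / 2
            Jp = np.sqrt(np.linalg.det(2 * (E + dE) + np.eye(3)))
            Jm = np.sqrt(np.linalg.det(2 * (E - dE) + np.eye(3)))
            S[i, j] = (mech.strain_energy(E + dE, Jp, params, frame)
                       - mech.strain_energy(E - dE, Jm, params, frame)) / (2 * h)
    return S


class TestConstitutive:
    def test_energy_zero_at_reference(self):
        for p in (mech.MYOCARDIUM, mech.SCAR, mech.VESSEL):
            assert mech.strain_energy(np.zeros((3, 3)), 1.0, p) == 0.0

    def test_scar_parameters_exact_ratios(self):
        assert mech.SCAR.mu == 2.0 * mech.MYOCARDIUM.mu == 651.12
        assert mech.SCAR.alpha == 5.0 * mech.MYOCARDIUM.alpha == 110.0
        assert mech.SCAR.b == (1.0, 1.0, 1.0, 0.5, 0.5, 0.5)
        assert mech.MYOCARDIUM.b == (1.0, 0.4, 0.3, 0.7, 0.6, 0.2)

    def test_scar_energy_isotropic_under_frame_permutation(self):
        rng = np.random.default_rng(0)
        E = 0.05 * rng.normal(size=(3, 3))
        E = 0.5 * (E + E.T)
        J = 1.02
        base = mech.strain_energy(E, J, mech.SCAR, np.eye(3))
        for perm in ([1, 0, 2], [2, 1, 0], [1, 2, 0]):
            frame = np.eye(3)[:, perm]
            assert np.isclose(mech.strain_energy(E, J, mech.SCAR, frame),
                              base, rtol=1e-12)
        # the anisotropic myocardium is NOT permutation invariant
        frame = np.eye(3)[:, [1, 0, 2]]
        assert not np.isclose(
            mech.strain_energy(E, J, mech.MYOCARDIUM, frame),
            mech.strain_energy(E, J, mech.MYOCARDIUM, np.eye(3)), rtol=1e-3)

    @pytest.mark.parametrize("params", [mech.MYOCARDIUM, mech.SCAR,
                                        mech.VESSEL, mech.PERI_BASAL])
    def test_stress_matches_energy_gradient(self, params):
        rng = np.random.default_rng(7)
        F = _random_F(rng)
        frame = _random_frame(rng)
        E = 0.5 * (F.T @ F - np.eye(3))
        S = mech.pk2_stress(F, frame, params)
        assert np.abs(S - _fd_stress(E, params, frame)).max() \
            <= 1e-6 * np.abs(S).max()
        assert np.allclose(S, S.T, atol=1e-9 * np.abs(S).max())

    def test_stress_free_reference(self):
        for p in (mech.MYOCARDIUM, mech.VESSEL):
            S = mech.pk2_stress(np.eye(3), np.eye(3), p)
            assert np.abs(S).max() < 1e-10

    def test_fiber_stiffer_than_sheet(self):
        lam = 1.15
        S_f = mech.pk2_stress(np.diag([lam, 1, 1]), np.eye(3), mech.MYOCARDIUM)
        S_s = mech.pk2_stress(np.diag([1, lam, 1]), np.eye(3), mech.MYOCARDIUM)
        assert S_f[0, 0] > S_s[1, 1]  # b_ff > b_ss

    def test_objectivity_under_rigid_rotation(self):
        rng = np.random.default_rng(3)
        F = _random_F(rng)
        R = _random_frame(rng)
        frame = _random_frame(rng)
        for p in (mech.MYOCARDIUM, mech.VESSEL):
            E = 0.5 * (F.T @ F - np.eye(3))
            J = np.linalg.det(F)
            assert np.isclose(mech.strain_energy(E, J, p, frame),
                              mech.strain_energy(0.5 * ((R @ F).T @ (R @ F)
                                                        - np.eye(3)),
                                                 np.linalg.det(R @ F), p,
                                                 frame), rtol=1e-9)
            S1 = mech.pk2_stress(F, frame, p)
            S2 = mech.pk2_stress(R @ F, frame, p)
            assert np.isclose(np.linalg.norm(S1), np.linalg.norm(S2),
                              rtol=1e-9)

    def test_inverted_configuration_rejected(self):
        with pytest.raises(ValueError):
            mech.pk2_stress(np.diag([-1.0, 1.0, 1.0]), np.eye(3),
                            mech.MYOCARDIUM)
        with pytest.raises(ValueError):
            mech.strain_energy(np.zeros((3, 3)), -1.0, mech.MYOCARDIUM)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            mech.MaterialParams(mu=-1.0, alpha=1.0, kappa=1.0)
        with pytest.raises(ValueError):
            mech.MaterialParams(mu=10.0, alpha=1.0, kappa=1.0)  # kappa < mu


class TestGapFunction:
    SPEC = mech.ContactSpec()

    def test_branch_continuity_at_transition(self):
        d = self.SPEC.d
        assert np.isclose(mech.gap_of_distance(d, self.SPEC), d / 2.0)
        below = mech.gap_of_distance(d - 1e-9, self.SPEC)
        above = mech.gap_of_distance(d + 1e-9, self.SPEC)
        assert abs(below - above) < 1e-8

    def test_zero_beyond_maximal_distance(self):
        assert mech.gap_of_distance(8.1, self.SPEC) == 0.0
        assert mech.gap_of_distance(100.0, self.SPEC) == 0.0

    def test_linear_branch_value(self):
        assert np.isclose(mech.gap_of_distance(0.2, self.SPEC), 0.15)

    def test_quadratic_branch(self):
        assert np.isclose(mech.gap_of_distance(0.05, self.SPEC),
                          0.05**2 / (2 * 0.1))

    def test_gap_via_projection_on_sphere(self):
        surf = mech.SphereSurface(center=np.zeros(3), radius=10.0)
        g = mech.gap(np.array([[10.2, 0.0, 0.0]]), surf, self.SPEC)
        assert np.isclose(g[0], 0.15)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            mech.ContactSpec(d=9.0, d_M=8.0)

    def test_contact_force_vanishes_out_of_range(self, shell):
        far = mech.ContactSpec(surface=mech.SphereSurface(np.zeros(3), 60.0))
        model = mech.MechModel(shell, contact=far)
        f, _ = model._contact_force(shell.vertices, want_tangent=False)
        assert np.abs(f).max() == 0.0
        near = mech.ContactSpec(surface=mech.SphereSurface(np.zeros(3), 26.0))
        model2 = mech.MechModel(shell, contact=near)
        f2, _ = model2._contact_force(shell.vertices, want_tangent=False)
        assert np.abs(f2).max() > 0.0


@pytest.fixture(scope="module")
def tiny_model():
    slab = msh.make_slab(1.0, 1.0, 1.0, 1.0)
    return mech.MechModel(slab, dirichlet=("endo",))


class TestResidualAndJacobian:
    def test_zero_residual_at_reference(self, tiny_model):
        R, _ = tiny_model.residual(np.zeros((tiny_model.n, 3)))
        assert np.abs(R).max() == 0.0

    def test_jacobian_matches_finite_difference(self, tiny_model):
        rng = np.random.default_rng(1)
        u = 0.01 * rng.normal(size=(tiny_model.n, 3))
        u[tiny_model.fixed] = 0.0
        R0, K = tiny_model.residual(u, want_tangent=True)
        Kd = K.toarray()
        free = tiny_model.free_dof
        h = 1e-7
        worst = 0.0
        for dof in np.where(free)[0]:
            du = np.zeros(3 * tiny_model.n)
            du[dof] = h
            Rp, _ = tiny_model.residual(u + du.reshape(-1, 3))
            Rm, _ = tiny_model.residual(u - du.reshape(-1, 3))
            fd = (Rp - Rm).ravel()[free] / (2 * h)
            worst = max(worst, np.abs(fd - Kd[free, dof]).max())
        assert worst <= 1e-5 * np.abs(Kd).max()

    def test_closed_cavity_pressure_has_zero_net_force(self, shell):
        """Pressure on a closed surface integrates to zero net force: the
        endocardium plus its opening caps is closed, so summing follower
        forces over endo triangles and cap fans must cancel."""
        tris = shell.surface_sets["endo"].copy()
        verts = shell.vertices.copy()
        loops = mech.boundary_loops(tris)
        extra_pts = []
        extra_tris = []
        nv = len(verts)
        for loop in loops:
            c = verts[loop].mean(axis=0)
            ci = nv + len(extra_pts)
            extra_pts.append(c)
            # caps traverse boundary edges opposite to the surface winding
            for a, b in zip(loop, np.roll(loop, -1)):
                extra_tris.append([b, a, ci])
        allverts = np.vstack([verts, np.asarray(extra_pts)])
        alltris = np.vstack([tris, np.asarray(extra_tris)])
        an = mech._tri_area_normals(allverts, alltris)
        net = np.zeros(3)
        for a in range(3):
            np.add.at(np.zeros((len(allverts), 3)), alltris[:, a], an / 3)
        net = an.sum(axis=0)  # closed-surface identity: sum of area normals
        scale = np.abs(an).sum()
        assert np.abs(net).max() < 1e-9 * scale


class TestNewmark:
    def test_matches_damped_oscillator_closed_form(self):
        m, c, k = 1.0, 0.4, 25.0
        spec = mech.DynamicsSpec(beta=0.25, gamma=0.5, dt=0.01)
        ts, us, _, _ = mech.newmark_march_linear(
            [[m]], [[c]], [[k]], lambda t: np.zeros(1), [1.0], [0.0],
            spec, 2000)
        wn = np.sqrt(k / m)
        zeta = c / (2 * np.sqrt(k * m))
        wd = wn * np.sqrt(1 - zeta**2)
        exact = np.exp(-zeta * wn * ts) * (np.cos(wd * ts)
                                           + zeta * wn / wd * np.sin(wd * ts))
        err_coarse = np.abs(us[:, 0] - exact).max()
        assert err_coarse < 5e-3
        # second-order accuracy: error drops ~25x when dt drops 5x
        spec_f = mech.DynamicsSpec(beta=0.25, gamma=0.5, dt=0.002)
        ts2, us2, _, _ = mech.newmark_march_linear(
            [[m]], [[c]], [[k]], lambda t: np.zeros(1), [1.0], [0.0],
            spec_f, 10000)
        exact2 = np.exp(-zeta * wn * ts2) * (np.cos(wd * ts2)
                                             + zeta * wn / wd * np.sin(wd * ts2))
        assert np.abs(us2[:, 0] - exact2).max() < err_coarse / 15

    def test_gamma_above_half_dissipates(self):
        spec = mech.DynamicsSpec(beta=0.3, gamma=0.6, dt=0.05)
        _, us, vs, _ = mech.newmark_march_linear(
            [[1.0]], [[0.0]], [[25.0]], lambda t: np.zeros(1), [1.0], [0.0],
            spec, 2000)
        E = 0.5 * 25.0 * us[:, 0]**2 + 0.5 * vs[:, 0]**2
        assert E[-1] < 1e-3 * E[0]

    def test_trapezoidal_conserves_energy(self):
        spec = mech.DynamicsSpec(beta=0.25, gamma=0.5, dt=0.01)
        _, us, vs, _ = mech.newmark_march_linear(
            [[1.0]], [[0.0]], [[25.0]], lambda t: np.zeros(1), [1.0], [0.0],
            spec, 5000)
        E = 0.5 * 25.0 * us[:, 0]**2 + 0.5 * vs[:, 0]**2
        assert np.abs(E - E[0]).max() < 1e-10 * E[0]

    def test_fem_zero_load_fixed_point(self, tiny_model):
        state = mech.MechState(u=np.zeros((tiny_model.n, 3)),
                               v=np.zeros((tiny_model.n, 3)),
                               a=np.zeros((tiny_model.n, 3)))
        out = tiny_model.newmark_step(state, mech.DynamicsSpec())
        assert np.abs(out.u).max() < 1e-12
        assert np.abs(out.a).max() < 1e-12

    def test_stability_bound_check(self):
        assert mech.DynamicsSpec(beta=0.25, gamma=0.5).unconditionally_stable()
        assert not mech.DynamicsSpec(beta=0.1, gamma=0.5).unconditionally_stable()


@pytest.fixture(scope="module")
def shell_model(shell):
    dirich = tuple(f"pv_ostium_{n}" for n in msh.PV_NAMES)
    return mech.MechModel(shell, dirichlet=dirich,
                          springs=("mitral_annulus", 0.05))


@pytest.fixture(scope="module")
def inflated(shell_model):
    u = shell_model.static_solve(8.0)
    return u


class TestInflation:
    def test_volume_increases_with_pressure(self, shell_model, inflated):
        V0 = shell_model.cavity_volume(np.zeros((shell_model.n, 3)))
        V8 = shell_model.cavity_volume(inflated)
        assert V8 > V0

    def test_annulus_displacement_analogue(self, shell_model, inflated):
        # the AVPD analogue reports the mean axial motion of the annulus ring
        avpd = shell_model.annulus_displacement(inflated)
        assert np.isfinite(avpd)
        assert abs(avpd) > 1e-4  # the spring-tethered ring moves under load
        assert shell_model.annulus_displacement(
            np.zeros((shell_model.n, 3))) == 0.0

    def test_near_incompressibility(self, shell_model, inflated):
        """|J - 1| < 0.05 at quadrature points away from the artificially
        pinned vein rings (stress concentrations at the idealized Dirichlet
        rings are fixture artifacts)."""
        F = shell_model.deformation_gradients(inflated)
        J = np.linalg.det(F)
        mesh = shell_model.mesh
        constrained = shell_model.fixed.copy()
        constrained[mesh.vertex_sets["mitral_annulus"]] = True
        interior = ~constrained[mesh.tets].any(axis=1)
        assert np.abs(J[interior] - 1.0).max() < 0.05
        assert np.abs(J - 1.0).max() < 0.1

    def test_edpvr_monotone(self, shell):
        dirich = tuple(f"pv_ostium_{n}" for n in msh.PV_NAMES)

        def factory():
            return mech.MechModel(shell, dirichlet=dirich,
                                  springs=("mitral_annulus", 0.05))

        p, V = mech.edpvr(factory, [0.0, 4.0, 8.0])
        assert np.all(np.diff(V) > 0)

    def test_stiff_scars_reduce_inflated_volume(self, shell_model, inflated):
        sh = msh.make_la_shell(resolution=6.0, seed=1)
        les.apply_to_mesh(sh, les.combine(sh, "PVI+AL+BL"))
        dirich = tuple(f"pv_ostium_{n}" for n in msh.PV_NAMES)
        scarred = mech.MechModel(sh, dirichlet=dirich,
                                 springs=("mitral_annulus", 0.05))
        u = scarred.static_solve(8.0)
        assert scarred.cavity_volume(u) < shell_model.cavity_volume(inflated)


class TestUnload:
    def test_zero_pressure_identity(self, shell):
        dirich = tuple(f"pv_ostium_{n}" for n in msh.PV_NAMES)

        def factory(X):
            m = msh.LabeledMesh(vertices=X, tets=shell.tets,
                                region=shell.region, frames=shell.frames,
                                vertex_sets=shell.vertex_sets,
                                surface_sets=shell.surface_sets)
            return mech.MechModel(m, dirichlet=dirich,
                                  springs=("mitral_annulus", 0.05))

        X, hist = mech.unload(factory, shell.vertices, 0.0, max_iter=3)
        assert np.allclose(X, shell.vertices)
        assert hist[0] < 1e-10

    def test_roundtrip_and_decreasing_error(self, shell):
        dirich = tuple(f"pv_ostium_{n}" for n in msh.PV_NAMES)

        def factory(X):
            m = msh.LabeledMesh(vertices=X, tets=shell.tets,
                                region=shell.region, frames=shell.frames,
                                vertex_sets=shell.vertex_sets,
                                surface_sets=shell.surface_sets)
            return mech.MechModel(m, dirichlet=dirich,
                                  springs=("mitral_annulus", 0.05))

        X, hist = mech.unload(factory, shell.vertices, 2.0, tol=0.1)
        # defining property: inflating the unloaded state recovers the
        # imaged geometry
        u = factory(X).static_solve(2.0)
        assert np.linalg.norm(X + u - shell.vertices, axis=1).max() < 0.1
        if len(hist) >= 3:
            assert hist[1] < hist[0] and hist[2] < hist[1]
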