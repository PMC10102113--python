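"""Closed-loop 0D circulation, 3D-0D coupling, stopping criterion."""
import numpy as np
import pytest

from ablsim import circulation as circ


@pytest.fixture(scope="module")
def limit_cycle():
    spec = circ.CouplingSpec(stopping_threshold=0.2)
    st, tr = circ.simulate(n_cycles=60, dt=1e-3, spec=spec)
    return st, tr


class TestRHS:
    def test_equal_pressures_no_flow(self):
        params = circ.CircParams()
        # choose volumes so every compartment and chamber sits at 5 mmHg
        p_t = 5.0
        vols = {
            "SysArt": params.V0_SysArt + p_t * params.C_SysArt,
            "SysVen": params.V0_SysVen + p_t * params.C_SysVen,
            "PulArt": params.V0_PulArt + p_t * params.C_PulArt,
            "PulVen": params.V0_PulVen + p_t * params.C_PulVen,
        }
        for name, ch in params.chambers.items():
            E = float(ch.elastance(0.0, params.cycle_length))
            vols[name] = ch.V0 + p_t / E
        v = np.array([vols[k] for k in circ.STATE_ORDER])
        dv, flows = circ.circulation_rhs(v, 0.0, params)
        assert np.abs(dv).max() < 1e-9

    def test_closed_loop_sums_to_zero(self):
        params = circ.CircParams()
        v = circ.initial_state(params).volumes
        for t in (0.0, 0.1, 0.3, 0.7):
            dv, _ = circ.circulation_rhs(v, t, params)
            assert abs(dv.sum()) < 1e-10 * np.abs(dv).max()

    def test_negative_volume_rejected(self):
        params = circ.CircParams()
        v = circ.initial_state(params).volumes.copy()
        v[0] = -1.0
        with pytest.raises(ValueError):
            circ.circulation_rhs(v, 0.0, params)


class TestLimitCycle:
    def test_blood_volume_conserved(self, limit_cycle):
        _, tr = limit_cycle
        total = sum(tr[f"V_{c}"] for c in circ.STATE_ORDER)
        assert total.max() - total.min() < 1e-6  # mL over the whole run

    def test_converges_and_mean_flows_balance(self, limit_cycle):
        st, tr = limit_cycle
        assert st.converged
        n = int(round(1.2 / 1e-3))
        q_sys = tr["Q_SysArt"][-n:].mean()
        q_pul = tr["Q_PulArt"][-n:].mean()
        assert abs(q_sys - q_pul) < 0.01 * abs(q_sys)

    def test_pressures_periodic_at_limit_cycle(self, limit_cycle):
        _, tr = limit_cycle
        n = int(round(1.2 / 1e-3))
        p = tr["p_LV"]
        last, prev = p[-n:], p[-2 * n:-n]
        pulse = last.max() - last.min()
        assert np.abs(last - prev).max() < 0.01 * pulse

    def test_physiological_ranges(self, limit_cycle):
        _, tr = limit_cycle
        n = int(round(1.2 / 1e-3))
        assert 25.0 < tr["V_LV"][-n:].min() < tr["V_LV"][-n:].max() < 160.0
        assert 40.0 < tr["p_LV"][-n:].max() < 160.0
        assert 0.0 < tr["p_LA"][-n:].max() < 25.0


class TestStoppingCriterion:
    def test_zero_difference_converges(self):
        converged, acc = circ.stopping_criterion(0.0)
        assert converged and acc == 0.0

    def test_constant_imbalance_integrates_over_cycle(self):
        # 1 mL/s imbalance for one 1.2 s cycle accumulates 1.2 mL
        sv_diff = 1.0 * 1.2
        converged, acc = circ.stopping_criterion(sv_diff)
        assert not converged and acc == 0.0  # reset when not met

    def test_remains_converged_under_unchanged_forcing(self):
        st, _ = circ.simulate(n_cycles=30, dt=1e-3)
        assert st.converged
        st2, _ = circ.simulate(n_cycles=2, dt=1e-3, state=st, record=False)
        assert st2.converged


class TestCoupling:
    def test_consistent_models_converge_immediately(self):
        v_of_p = lambda p: 30.0 + 2.0 * p
        p = circ.couple_chamber(v_of_p, v_of_p, p_lo=0.0, p_hi=10.0)
        assert np.isfinite(p)

    def test_linear_intersection_matches_closed_form(self):
        v3d = lambda p: 30.0 + 2.0 * p      # compliant 3D chamber
        v0d = lambda p: 50.0 - 1.5 * p      # 0D volume falls with pressure
        p = circ.couple_chamber(v3d, v0d)
        assert np.isclose(p, 20.0 / 3.5, rtol=1e-9)
        assert abs(v3d(p) - v0d(p)) < 1e-7  # the stated tolerance

    def test_bracket_expansion(self):
        v3d = lambda p: 10.0 + 0.1 * p
        v0d = lambda p: 200.0 - 0.1 * p     # root near p = 950
        p = circ.couple_chamber(v3d, v0d, p_lo=-1.0, p_hi=1.0)
        assert np.isclose(p, 950.0, rtol=1e-6)

    def test_unbracketable_root_raises(self):
        with pytest.raises(RuntimeError):
            circ.couple_chamber(lambda p: 10.0, lambda p: 20.0,
                                p_lo=0.0, p_hi=1.0)

    def test_coupling_against_fem_chamber(self, shell):
        """The 3D shell's inflation curve couples to a linear 0D law at the
        pressure where the two volumes agree to the Eq-type tolerance."""
        from ablsim import mechanics as mech
        from ablsim import mesh as msh

        dirich = tuple(f"pv_ostium_{n}" for n in msh.PV_NAMES)
        model = mech.MechModel(shell, dirichlet=dirich,
                               springs=("mitral_annulus", 0.05))
        cache = {}
        warm = {"u": None}

        def v3d(p):
            key = round(float(p), 10)
            if key not in cache:
                u = model.static_solve(float(p), u0=warm["u"], n_steps=3)
                warm["u"] = u
                cache[key] = model.cavity_volume(u)
            return cache[key]

        v0d = lambda p: 16.5 - 0.05 * p
        p = circ.couple_chamber(v3d, v0d, p_lo=0.5, p_hi=12.0)
        assert abs(v3d(p) - v0d(p)) < 1e-7

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ValueError):
            circ.CouplingSpec(tolerance=0.0)
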