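"""Feedback ODE model: fixed point, stability, transients, reduction."""

import numpy as np
import pytest

import cgtension as cg
import cgtension.feedback as fb
from cgtension.errors import ModelConfigurationError, ParameterError


class TestFluxesAndRhs:
    def test_no_gbf1_means_no_endocytic_flux(self, params):
        j_endo, _ = cg.fluxes(cg.FeedbackState(gamma=1.0, v=0.5, g=0.0), params)
        assert j_endo == 0.0

    def test_no_tension_means_no_exocytic_flux(self, params):
        _, j_exo = cg.fluxes(cg.FeedbackState(gamma=0.0, v=0.5, g=0.5), params)
        assert j_exo == 0.0

    def test_endocytosis_decreasing_in_tension_at_fixed_gbf1(self, params):
        gammas = np.linspace(0.1, 8.0, 40)
        js = [
            cg.fluxes(cg.FeedbackState(gamma=g, v=0.5, g=0.5), params)[0]
            for g in gammas
        ]
        assert np.all(np.diff(js) < 0)

    def test_negative_feedback_loop_sign(self, params):
        """gamma -> v (+), v -> g (-), g -> J_endo (+), J_endo -> gamma (+)."""
        st = cg.steady_state(params)
        J = fb.jacobian(st, params)
        sign_product = (
            np.sign(J[1, 0])  # d(dv)/dgamma
            * np.sign(J[2, 1])  # d(dg)/dv
            * np.sign(J[0, 2])  # d(dgamma)/dg via J_endo
        )
        assert sign_product == -1.0

    def test_clamped_variable_has_zero_derivative(self, params):
        st = cg.FeedbackState(gamma=2.0, v=0.3, g=0.7)
        d = cg.rhs(st, params, clamps={"v": 0.3})
        assert d[1] == 0.0
        d = cg.rhs(st, params, clamps={"g": 0.7})
        assert d[2] == 0.0


class TestSteadyState:
    def test_fixed_point_unique_and_tight(self, params):
        st = cg.steady_state(params)
        assert np.linalg.norm(cg.rhs(st, params)) < 1e-10
        # dense-grid oracle: exactly one sign change of the reduced equation
        grid = np.linspace(1e-6, 10.0, 20001)
        vals = np.array([fb._scalar_residual(x, params, {}) for x in grid])
        assert int(np.count_nonzero(np.diff(np.signbit(vals)))) == 1

    def test_gbf1_clamp_lowers_set_point(self, params):
        wt = cg.steady_state(params).gamma
        assert cg.steady_state(params, {"g": 0.0}).gamma < wt

    def test_vinculin_clamp_raises_set_point(self, params):
        wt = cg.steady_state(params).gamma
        assert cg.steady_state(params, {"v": 0.0}).gamma > wt

    def test_impossible_configuration_raises(self, params):
        # enormous endocytic capacity with feeble exocytosis: no balance
        bad = params.replace(k_e=500.0, J_x=1e-6, tau_m=1e9)
        with pytest.raises(ModelConfigurationError):
            cg.steady_state(bad, {"v": 0.0})


class TestStability:
    def test_default_fixed_point_is_stable(self, params):
        assert np.all(cg.stability(params) < 0)

    def test_analytic_jacobian_matches_finite_differences(self, params):
        st = cg.steady_state(params)
        J = fb.jacobian(st, params)
        x0 = st.as_array()
        eps = 1e-7
        J_fd = np.zeros((3, 3))
        for j in range(3):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += eps
            xm[j] -= eps
            sp = cg.FeedbackState(*xp)
            sm = cg.FeedbackState(*xm)
            J_fd[:, j] = (cg.rhs(sp, params) - cg.rhs(sm, params)) / (2 * eps)
        assert np.allclose(J, J_fd, atol=1e-6)

    def test_perturbation_decay_confirms_eigenvalues(self, params):
        """A 1% tension kick relaxes back, as the spectrum predicts."""
        proto = cg.Protocol(events=[(0.0, cg.tension_step(1.01))], t_end=400.0)
        traj = cg.simulate(params, proto)
        dev = np.abs(traj.gamma - traj.gamma_s) / traj.gamma_s
        assert dev[-1] < 1e-4

    def test_double_clamp_reduces_to_scalar_eigenvalue(self, params):
        st = cg.steady_state(params, {"v": 0.2, "g": 0.5})
        eigs = cg.stability(params, {"v": 0.2, "g": 0.5})
        assert eigs.shape == (1,)
        J = fb.jacobian(st, params, {"v": 0.2, "g": 0.5})
        assert eigs[0] == pytest.approx(J[0, 0])


class TestSimulate:
    def test_empty_protocol_stays_at_set_point(self, params):
        traj = cg.simulate(params, cg.Protocol(events=[], t_end=100.0))
        assert np.max(np.abs(traj.gamma - traj.gamma_s)) < 1e-9

    def test_tension_drop_triggers_transient_endocytic_overshoot(self, params):
        proto = cg.Protocol(events=[(0.0, cg.tension_step(0.7))], t_end=500.0)
        traj = cg.simulate(params, proto)
        st = cg.steady_state(params)
        j_base, _ = cg.fluxes(st, params)
        assert traj.J_endo.max() > 1.05 * j_base  # rises above baseline
        assert traj.J_endo[-1] == pytest.approx(j_base, rel=0.05)  # returns
        assert traj.gamma[-1] == pytest.approx(traj.gamma_s, rel=0.02)

    def test_rk4_step_halving_converges_at_fourth_order(self, params):
        x0 = cg.FeedbackState(gamma=0.8 * cg.steady_state(params).gamma,
                              v=0.3, g=0.6)
        ends = {}
        for dt in (0.4, 0.2, 0.1):
            traj = cg.simulate(
                params, cg.Protocol(events=[], t_end=40.0), dt=dt, x0=x0
            )
            ends[dt] = traj.gamma[-1]
        e1 = abs(ends[0.4] - ends[0.1])
        e2 = abs(ends[0.2] - ends[0.1])
        order = np.log2(e1 / e2) if e2 > 0 else 4.0
        assert order > 3.0  # ~4 expected; >3 guards discretization noise
        # absolute endpoint shift under halving is tiny
        assert abs(ends[0.2] - ends[0.1]) / ends[0.1] < 1e-6

    def test_clamp_event_freezes_variable(self, params):
        proto = cg.protocol_preset("lg186", t_end=50.0)
        traj = cg.simulate(params, proto)
        assert np.all(traj.g[traj.time_s > 0] == 0.0)
        assert np.all(traj.J_endo[traj.time_s > 0] == 0.0)

    def test_scale_event_changes_parameter_midrun(self, params):
        proto = cg.Protocol(events=[(10.0, cg.scale("k_e", 1.5))], t_end=200.0)
        traj = cg.simulate(params, proto)
        assert traj.gamma[-1] > traj.gamma_s  # upregulated endocytosis


class TestPresets:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ParameterError):
            cg.protocol_preset("nocodazole")

    @pytest.mark.parametrize(
        "name,direction",
        [("lg186", -1), ("bfa", +1), ("dyn_tko", +1), ("vinculin_null", +1)],
    )
    def test_preset_steady_state_direction(self, params, name, direction):
        proto = cg.protocol_preset(name, t_end=2000.0)
        traj = cg.simulate(params, proto)
        wt = traj.gamma_s
        assert np.sign(traj.gamma[-1] - wt) == direction

    def test_stretch_relax_has_marked_transient_then_resets(self, params):
        proto = cg.protocol_preset("stretch_relax")
        traj = cg.simulate(params, proto)
        t_relax = proto.marks["relax"]
        early = cg.uptake_proxy(traj, (t_relax, t_relax + 90.0))
        late = cg.uptake_proxy(traj, (t_relax + 90.0, t_relax + 180.0))
        assert early > 1.0
        assert late == pytest.approx(1.0, abs=0.1)

    def test_uptake_suppressed_during_stretch(self, params):
        proto = cg.protocol_preset("stretch_relax")
        traj = cg.simulate(params, proto)
        t_on, t_relax = proto.marks["stretch"], proto.marks["relax"]
        during = cg.uptake_proxy(traj, (t_on, t_relax))
        assert during < 1.0


class TestReadouts:
    def test_uptake_proxy_is_exactly_one_unperturbed(self, params):
        traj = cg.simulate(params, cg.Protocol(events=[], t_end=200.0))
        assert cg.uptake_proxy(traj, (0.0, 90.0)) == pytest.approx(1.0, abs=1e-9)

    def test_uptake_proxy_bad_window_rejected(self, params):
        traj = cg.simulate(params, cg.Protocol(events=[], t_end=100.0))
        with pytest.raises(ParameterError):
            cg.uptake_proxy(traj, (50.0, 50.0))

    def test_response_gain_signs_flip_with_step_direction(self, params):
        down_t, down_s = cg.response_gain(params, 0.7)
        up_t, up_s = cg.response_gain(params, 1.4)
        assert down_t > 0 and up_t < 0
        assert down_s > 0 and up_s < 0

    def test_clamped_vinculin_keeps_gbf1_constant_after_step(self, params):
        st = cg.steady_state(params, {"v": 0.0})
        proto = cg.Protocol(
            events=[(0.0, cg.clamp_v(0.0)), (0.0, cg.tension_step(0.7))],
            t_end=100.0,
        )
        traj = cg.simulate(params, proto, x0=st)
        assert np.allclose(traj.g, traj.g[0])


class TestQSSA:
    def test_reduced_matches_full_at_extreme_separation(self, params):
        p = params.replace(tau_v=0.03)  # tau_v/tau_g = 1/1000
        proto = cg.Protocol(events=[(0.0, cg.tension_step(0.7))], t_end=120.0)
        full = cg.simulate(p, proto, dt=0.01)
        red = cg.qssa_reduce(p)
        t_r, gamma_r, _ = red.simulate(proto, dt=0.01)
        gamma_full = np.interp(t_r, full.time_s, full.gamma)
        sup = np.max(np.abs(gamma_r - gamma_full)) / np.max(np.abs(gamma_full))
        assert sup < 0.005

    def test_fixed_points_coincide_exactly(self, params):
        red = cg.qssa_reduce(params)
        g_red, _ = red.steady_state()
        assert g_red == cg.steady_state(params).gamma

    def test_agreement_degrades_as_timescales_merge(self, params):
        import warnings as _w

        sups = []
        for tau_v in (0.03, 0.3, 3.0):
            with _w.catch_warnings():
                _w.simplefilter("ignore", UserWarning)
                p = params.replace(tau_v=tau_v)
            proto = cg.Protocol(events=[(0.0, cg.tension_step(0.7))], t_end=120.0)
            full = cg.simulate(p, proto, dt=0.01)
            t_r, gamma_r, _ = cg.qssa_reduce(p).simulate(proto, dt=0.01)
            gamma_full = np.interp(t_r, full.time_s, full.gamma)
            sups.append(np.max(np.abs(gamma_r - gamma_full)))
        assert sups[0] < sups[1] < sups[2]

    def test_warns_for_poor_separation(self, params):
        with pytest.warns(UserWarning):
            cg.qssa_reduce(params.replace(tau_v=10.0, tau_g=30.0))


class TestParams:
    def test_nonpositive_parameter_rejected(self, params):
        with pytest.raises(ParameterError):
            params.replace(k_e=-1.0)

    def test_timescale_violation_warns(self, params):
        with pytest.warns(UserWarning):
            params.replace(tau_v=5.0, tau_g=30.0)

    def test_yaml_round_trip(self, params, tmp_path):
        import yaml

        path = tmp_path / "p.yaml"
        path.write_text(yaml.safe_dump({"params": params.as_dict()}))
        assert cg.ModelParams.from_yaml(path) == params
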