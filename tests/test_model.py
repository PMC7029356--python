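"""Base-model unit and property tests: currents, RyR release, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioinv.model import (
    ModelState, Protocol, compute_currents, compute_fluxes,
    default_initial_state, integrate, rhs, ryr_fluxes,
)
from cardioinv.parameters import CURRENT_NAMES, STATE_INDEX


def _apd(t, v, pct):
    v_rest, v_peak = v.min(), v.max()
    level = v_peak - pct / 100.0 * (v_peak - v_rest)
    idx = np.flatnonzero(v >= level)
    return t[idx[-1]] - t[idx[0]]


class TestCurrents:
    def test_closed_channel_carries_no_current(self, hipsc_params):
        state = default_initial_state(hipsc_params, v=0.0)
        for gates, name in [(("m",), "Na"), (("mL",), "NaL"), (("d",), "CaL"),
                            (("r_to",), "to"), (("xr1",), "Kr"), (("xs",), "Ks"),
                            (("xf",), "f")]:
            s = state.copy()
            for g in gates:
                setattr(s, g, 0.0)
            cur = compute_currents(s, hipsc_params)
            assert cur.values[name] == 0.0

    def test_ohmic_current_vanishes_at_reversal(self, hipsc_params):
        import cardioinv._engine as eng
        p = hipsc_params
        e_k = eng.RTF * np.log(p.K_o / p.K_i)
        state = default_initial_state(p, v=float(e_k))
        cur = compute_currents(state, p)
        assert cur.values["to"] == pytest.approx(0.0, abs=1e-12)
        assert cur.values["Kr"] == pytest.approx(0.0, abs=1e-12)
        state_cl = default_initial_state(p, v=p.E_Cl)
        assert compute_currents(state_cl, p).values["bCl"] == pytest.approx(0.0, abs=1e-12)

    def test_nonfinite_state_is_rejected_by_name(self, hipsc_params):
        state = default_initial_state(hipsc_params)
        state.values[STATE_INDEX["c_sl"]] = np.nan
        with pytest.raises(ValueError, match="c_sl"):
            compute_currents(state, hipsc_params)

    def test_current_sum_matches_trajectory_derivative(self, hipsc_beat):
        """-dv/dt from a finite difference of the integrated trajectory must
        agree with the recorded current sum away from the stimulus."""
        tr = hipsc_beat
        dvdt = np.gradient(tr.v, tr.t)
        total = tr.currents[:, :13].sum(axis=1) + tr.currents[:, 13]
        # exclude the stimulus window and the steep upstroke, where the
        # centered finite difference itself is inaccurate
        mask = (tr.t > 10.0) & (np.abs(dvdt) < 5.0)
        assert mask.sum() > 500
        err = np.abs(dvdt[mask] + total[mask])
        assert np.quantile(err, 0.95) < 0.05  # A/F


class TestRyR:
    def test_half_activation_at_kappa(self, hipsc_params):
        state = default_initial_state(hipsc_params)
        state.c_d = hipsc_params.kappa_RyR
        _, _, p_open = ryr_fluxes(state, hipsc_params)
        assert p_open == pytest.approx(0.5, rel=1e-12)

    def test_full_depletion_stops_release_but_not_leak(self, hipsc_params):
        state = default_initial_state(hipsc_params)
        state.c_d = 0.05
        j_ryr1, j_leak1, _ = ryr_fluxes(state, hipsc_params)
        assert j_ryr1 > 0
        state.r = 0.0
        j_ryr0, j_leak0, _ = ryr_fluxes(state, hipsc_params)
        assert j_ryr0 == 0.0
        assert j_leak0 == j_leak1

    @settings(max_examples=200, deadline=None)
    @given(c_d=st.floats(0.0, 0.5), c_s=st.floats(0.0, 2.0),
           c_sl=st.floats(0.0, 0.5), r=st.floats(0.0, 1.0))
    def test_matches_literal_transcription(self, hipsc_params, c_d, c_s, c_sl, r):
        """Release/leak/open-probability against an independently coded
        transcription of the availability-limited release model."""
        p = hipsc_params
        state = default_initial_state(p)
        state.c_d, state.c_s, state.c_sl, state.r = c_d, c_s, c_sl, r
        j_ryr, j_leak, p_open = ryr_fluxes(state, p)
        # oracle: literal formulas
        p_oracle = c_d ** 3 / (c_d ** 3 + p.kappa_RyR ** 3)
        j_ryr_oracle = p_oracle * r * p.alpha_RyR * (c_s - c_sl)
        j_leak_oracle = p.gamma_RyR * p.alpha_RyR * (c_s - c_sl)
        assert p_open == pytest.approx(p_oracle, rel=1e-12, abs=1e-300)
        assert j_ryr == pytest.approx(j_ryr_oracle, rel=1e-12, abs=1e-300)
        assert j_leak == pytest.approx(j_leak_oracle, rel=1e-12, abs=1e-300)

    def test_flux_sum_identity(self, hipsc_beat):
        """J_ssl = J_RyR + J_leak exactly, on every recorded sample."""
        np.testing.assert_allclose(
            hipsc_beat.flux("J_ssl"),
            hipsc_beat.flux("J_RyR") + hipsc_beat.flux("J_leak"), rtol=1e-12)


class TestRhs:
    def test_quiescent_state_has_zero_concentration_derivatives(self, hipsc_params):
        """With all channels shut, no pumps/leaks and equilibrated buffers,
        every concentration derivative vanishes."""
        p = hipsc_params.replace(
            g_CaL=0.0, g_bCa=0.0, g_pCa=0.0, g_NaCa=0.0, g_SERCA=0.0,
            gamma_RyR=0.0)
        state = default_initial_state(p, v=-80.0)
        c0 = 1e-4
        for name in ("c_d", "c_sl", "c_c", "c_s", "c_n"):
            setattr(state, name, c0)
        for comp in ("d", "sl", "c", "s"):
            kd = getattr(p, f"k_off_{comp}") / getattr(p, f"k_on_{comp}")
            setattr(state, f"b_{comp}",
                    getattr(p, f"B_tot_{comp}") * c0 / (c0 + kd))
        dy = rhs(0.0, state, p, Protocol(mode="free-running", beats=1))
        for name in ("c_d", "b_d", "c_sl", "b_sl", "c_c", "b_c",
                     "c_s", "b_s", "c_n"):
            # rounding in the buffer equilibrium is amplified by 1/V_i;
            # typical beat-time derivatives are O(0.1) mM/ms
            assert dy[STATE_INDEX[name]] == pytest.approx(0.0, abs=1e-10)

    def test_zero_gradient_means_no_sr_release(self, hipsc_params):
        state = default_initial_state(hipsc_params)
        state.c_s = state.c_sl
        j_ryr, j_leak, _ = ryr_fluxes(state, hipsc_params)
        assert j_ryr == 0.0 and j_leak == 0.0

    def test_clamp_mode_freezes_voltage(self, hipsc_params):
        state = default_initial_state(hipsc_params)
        proto = Protocol(mode="voltage-clamp", clamp_v=0.0)
        dy = rhs(0.0, state, hipsc_params, proto)
        assert dy[STATE_INDEX["v"]] == 0.0

    def test_whole_cell_calcium_bookkeeping(self, hipsc_params, hipsc_initial):
        """The change of total cell Ca2+ (free + buffered, volume-weighted)
        over a paced beat equals the integrated net membrane Ca2+ flux."""
        # block part of the Ca2+ entry so the beat has a clearly nonzero
        # net membrane flux (at steady state influx and efflux cancel)
        p = hipsc_params.replace(g_CaL=0.3 * hipsc_params.g_CaL)
        proto = Protocol(mode="paced", hz=1.0, beats=1, dt=0.02, sample_dt=0.1)
        tr = integrate(p, proto, hipsc_initial)
        vols = {c: p.compartment_volume(c) for c in ("d", "sl", "c", "s", "n")}
        si = STATE_INDEX
        total = (vols["d"] * (tr.states[:, si["c_d"]] + tr.states[:, si["b_d"]])
                 + vols["sl"] * (tr.states[:, si["c_sl"]] + tr.states[:, si["b_sl"]])
                 + vols["c"] * (tr.states[:, si["c_c"]] + tr.states[:, si["b_c"]])
                 + vols["s"] * (tr.states[:, si["c_s"]] + tr.states[:, si["b_s"]])
                 + vols["n"] * tr.states[:, si["c_n"]])
        net_in = np.trapezoid(tr.flux("J_CaL") + tr.flux("J_esl"), tr.t)
        delta = total[-1] - total[0]
        turnover = np.trapezoid(np.abs(tr.flux("J_CaL"))
                                + np.abs(tr.flux("J_esl")), tr.t)
        assert abs(net_in) > 0.01 * turnover   # genuinely non-steady beat
        assert delta == pytest.approx(net_in, abs=0.02 * turnover)


class TestIntegrate:
    def test_zero_beats_returns_initial_state_once(self, hipsc_params):
        state = default_initial_state(hipsc_params)
        proto = Protocol(mode="paced", beats=0)
        tr = integrate(hipsc_params, proto, state)
        assert len(tr) == 1
        np.testing.assert_array_equal(tr.states[0], state.values)

    def test_step_refinement_barely_moves_apd80(self, hipsc_params, hipsc_initial):
        apds = []
        for dt in (0.02, 0.01):
            proto = Protocol(mode="paced", beats=1, dt=dt, sample_dt=0.5)
            tr = integrate(hipsc_params, proto, hipsc_initial)
            apds.append(_apd(tr.t, tr.v, 80))
        assert abs(apds[0] - apds[1]) < 0.5

    def test_deterministic(self, hipsc_params, hipsc_initial):
        proto = Protocol(mode="paced", beats=2, dt=0.05)
        a = integrate(hipsc_params, proto, hipsc_initial)
        b = integrate(hipsc_params, proto, hipsc_initial)
        np.testing.assert_array_equal(a.states, b.states)

    def test_clamp_at_rest_triggers_no_calcium_entry(self, hipsc_params,
                                                     hipsc_initial):
        peaks = {}
        for vc in (-81.0, -40.0, 0.0):
            proto = Protocol(mode="voltage-clamp", clamp_v=vc,
                             clamp_duration=100.0, sample_dt=0.5, dt=0.02)
            tr = integrate(hipsc_params, proto, hipsc_initial)
            peaks[vc] = tr.flux("J_CaL").max()
        assert peaks[-81.0] < 0.01 * max(peaks.values())

    def test_gates_and_availability_stay_in_unit_interval(self, hipsc_params,
                                                          rng):
        """r and all gates remain in [0, 1] under randomized initial states."""
        for _ in range(5):
            state = default_initial_state(hipsc_params,
                                          v=float(rng.uniform(-90, 20)))
            state.r = float(rng.uniform(0, 1))
            state.c_s = float(rng.uniform(0, 1.5))
            state.c_d = float(rng.uniform(0, 0.05))
            proto = Protocol(mode="paced", beats=1, dt=0.05)
            tr = integrate(hipsc_params, proto, state)
            gates = tr.states[:, 1:14]
            assert gates.min() >= 0.0 and gates.max() <= 1.0
            r = tr.states[:, STATE_INDEX["r"]]
            assert r.min() >= 0.0 and r.max() <= 1.0

    def test_matches_independent_ode_solution(self, hipsc_params, hipsc_initial):
        """Dual-route check: the compiled fixed-step integrator against
        scipy's adaptive solver running the plain-Python right-hand side."""
        from scipy.integrate import solve_ivp

        proto = Protocol(mode="paced", beats=1, dt=0.02, sample_dt=1.0)
        tr = integrate(hipsc_params, proto, hipsc_initial)

        def f(t, y):
            return rhs(t, ModelState(y), hipsc_params, proto)

        sol = solve_ivp(f, (0.0, 1000.0), hipsc_initial.values.copy(),
                        method="LSODA", t_eval=tr.t, rtol=1e-6, atol=1e-9,
                        max_step=1.0)
        assert sol.success
        v_ref = sol.y[0]
        assert abs(_apd(tr.t, tr.v, 80) - _apd(tr.t, v_ref, 80)) < 4.0
        assert abs(tr.v.min() - v_ref.min()) < 1.0
        assert abs(tr.v.max() - v_ref.max()) < 5.0


class TestFluxBalance:
    def test_compartment_closure_along_trajectory(self, hipsc_params,
                                                  hipsc_initial):
        """Change in V_n * c_n equals the integral of its net fluxes (the
        nSR has no buffer, making the closure exact up to quadrature)."""
        proto = Protocol(mode="paced", hz=1.0, beats=1, dt=0.02, sample_dt=0.1)
        tr = integrate(hipsc_params, proto, hipsc_initial)
        v_n = hipsc_params.compartment_volume("n")
        si = STATE_INDEX
        delta = v_n * (tr.states[-1, si["c_n"]] - tr.states[0, si["c_n"]])
        net = np.trapezoid(tr.flux("J_cn") - tr.flux("J_ns"), tr.t)
        assert delta == pytest.approx(net, rel=0.01, abs=1e-18)
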