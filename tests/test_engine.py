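"""Engine: RHS assembly, conservation, event handling, solvers, V_m coupling."""

import numpy as np
import pytest

from socesim import (
    Protocol,
    ProtocolEvent,
    SolverSettings,
    WholeCellCurrentHook,
    assemble_rhs,
    find_steady_state,
    initial_state,
    integrate,
    integrate_with_vm,
    load_parameters,
)
from socesim.state import STATE_NAMES, pack_state

# overrides that freeze every channel, pump, buffer and gating rate
ZERO_RATES = {
    "serca.R_serca": 0.0,
    "pmca.R_pmca": 0.0,
    "leak.R_leak": 0.0,
    "ip3r.R_ip3r": 0.0,
    "ryr.R_ryr": 0.0,
    "crac.n_crac_per_junction": 0.0,
    "diffusion_coefficient": 0.0,
    "buffer_cyt.k_on": 0.0,
    "buffer_cyt.k_off": 0.0,
    "buffer_csq.k_on": 0.0,
    "buffer_csq.k_off": 0.0,
    "crac.f_s": 0.0,
    "crac.b_s": 0.0,
    "crac.f_o": 0.0,
    "crac.b_o": 0.0,
    "ip3.R_ip_ca": 0.0,
    "ip3.R_ip_d": 0.0,
    **{f"ip3r.{k}": 0.0 for k in ("k1", "km1", "k2", "km2", "k3", "km3", "k4", "km4",
                                   "j2", "jm2", "j4", "jm4", "j6", "jm6")},
    **{f"ryr.{k}": 0.0 for k in ("k2", "km2", "k4", "km4", "k6", "k11")},
}


def total_calcium(states: np.ndarray, params) -> np.ndarray:
    """Total cell calcium amount (µM·L): free + buffered over all compartments."""
    g = params.geometry
    csq_bound = params.buffer_csq.csq_total - states[:, 4]
    return (
        g.cytosol_volume * (states[:, 0] + states[:, 3])
        + g.er_volume * (states[:, 1] + csq_bound)
        + g.n_junctions * g.junction_volume * states[:, 2]
    )


class TestAssembleRhs:
    def test_zeroed_rates_give_zero_derivatives(self, params):
        frozen = params.copy_with(ZERO_RATES)
        cal, gat = initial_state(frozen)
        dy = assemble_rhs(0.0, pack_state(cal, gat), frozen)
        assert np.allclose(dy, 0.0)

    def test_relaxed_state_has_small_derivatives(self, ss_summary, params):
        y = ss_summary.trace.states[-1]
        dy = assemble_rhs(0.0, y, params)
        scale = np.maximum(np.abs(y), 1.0)
        assert np.all(np.abs(dy) < 1e-3 * scale)

    def test_serca_amount_conservation_between_cytosol_and_er(self, params):
        # calcium pumped out of the cytosol reappears in the ER scaled by the
        # volume ratio: with only SERCA_Cyt active, V_Cyt·dc = −V_ER·dE
        only_serca = params.copy_with({**ZERO_RATES, "serca.R_serca": 100.0})
        cal, gat = initial_state(only_serca)
        dy = assemble_rhs(0.0, pack_state(cal, gat), only_serca)
        g = params.geometry
        amount_cyt = g.cytosol_volume * dy[0]
        amount_er = g.er_volume * dy[1]
        amount_jun = g.n_junctions * g.junction_volume * dy[2]
        assert amount_cyt + amount_er + amount_jun == pytest.approx(0.0, abs=1e-25)


class TestIntegration:
    def test_constant_trace_with_zero_rates(self, params):
        frozen = params.copy_with(ZERO_RATES)
        cal, gat = initial_state(frozen)
        trace = integrate(cal, gat, frozen, Protocol(t_end=5.0, record_interval=0.5))
        assert np.allclose(trace.states, trace.states[0])
        assert trace.states[0, 1] == pytest.approx(250.0)

    def test_closed_system_mass_conservation(self, params):
        # with PMCA and CRAC disabled the cell is a closed calcium system
        closed = params.copy_with({"pmca.R_pmca": 0.0, "crac.n_crac_per_junction": 0.0})
        cal, gat = initial_state(closed)
        trace = integrate(cal, gat, closed, Protocol(t_end=600.0, record_interval=2.0))
        total = total_calcium(trace.states, closed)
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-3

    def test_event_atomicity(self, tg_summary):
        trace = tg_summary.trace
        pre = trace.window(0.0, 66.0)
        post = trace.time >= 66.0
        assert np.all(trace.column("j_serca_cyt")[pre] > 0)
        assert np.all(trace.column("j_serca_cyt")[post] == 0.0)
        # bath calcium switched at 231 s: no CRAC influx before, influx after
        assert np.all(trace.column("j_crac")[trace.window(0.0, 231.0)] == 0.0)
        assert trace.column("j_crac")[trace.window(232.0, 429.0)].min() > 0

    def test_determinism_bit_for_bit(self, params):
        proto = Protocol(
            events=(ProtocolEvent(1.0, "serca.R_serca", 0.0),),
            t_end=3.0,
            record_interval=0.1,
        )
        cal, gat = initial_state(params)
        a = integrate(cal, gat, params, proto)
        b = integrate(cal, gat, params, proto)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.fluxes, b.fluxes)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            Protocol(events=(ProtocolEvent(2.0, "x", 1.0), ProtocolEvent(1.0, "y", 1.0)), t_end=5.0)
        with pytest.raises(ValueError):
            Protocol(events=(ProtocolEvent(10.0, "x", 1.0),), t_end=5.0)

    def test_unknown_event_path_raises(self, params):
        cal, gat = initial_state(params)
        proto = Protocol(events=(ProtocolEvent(0.5, "serca.R_sarca", 0.0),), t_end=1.0)
        with pytest.raises(KeyError):
            integrate(cal, gat, params, proto)


class TestSolvers:
    def test_euler_matches_adaptive_on_compressed_protocol(self, params):
        # the TG event sequence compressed onto a short horizon; the fixed-step
        # validation mode must agree with the stiff adaptive solver
        proto = Protocol(
            events=(
                ProtocolEvent(0.10, "serca.R_serca", 0.0),
                ProtocolEvent(0.25, "ca_ext", 2000.0),
                ProtocolEvent(0.40, "crac.n_crac_per_junction", 0.001),
            ),
            t_end=0.5,
            record_interval=0.05,
        )
        cal, gat = initial_state(params.copy_with({"ca_ext": 0.0}))
        ref = integrate(cal, gat, params.copy_with({"ca_ext": 0.0}), proto)
        eul = integrate(
            cal, gat, params.copy_with({"ca_ext": 0.0}), proto,
            SolverSettings(method="euler", step_size=5e-6),
        )
        scale = np.maximum(np.abs(ref.states[-1]), 1e-9)
        rel = np.abs(eul.states[-1] - ref.states[-1]) / scale
        assert np.max(rel) < 0.01

    def test_euler_first_order_convergence(self, params):
        proto = Protocol(t_end=0.01, record_interval=0.005)
        cal, gat = initial_state(params)
        ref = integrate(
            cal, gat, params, proto, SolverSettings(rel_tol=1e-11, abs_tol=1e-14)
        ).states[-1]

        def err(dt):
            out = integrate(
                cal, gat, params, proto, SolverSettings(method="euler", step_size=dt)
            ).states[-1]
            return np.max(np.abs(out - ref) / np.maximum(np.abs(ref), 1e-9))

        e1, e2 = err(2e-6), err(1e-6)
        assert 1.5 < e1 / e2 < 2.6  # halving the step halves the error


class TestSteadyState:
    def test_zero_rate_system_converges_immediately(self, params):
        frozen = params.copy_with(ZERO_RATES)
        cal, gat, converged = find_steady_state(frozen, t_max=1.0, tolerance=1e-9)
        assert converged
        assert cal.ca_er == pytest.approx(250.0)

    def test_insufficient_time_reports_nonconvergence(self, params):
        _, _, converged = find_steady_state(params, t_max=0.001, tolerance=1e-9)
        assert not converged

    def test_relaxed_state_agrees_with_root_finding_oracle(self, params):
        from scipy.optimize import fsolve

        cal, gat, converged = find_steady_state(params, t_max=600.0, tolerance=1e-7)
        assert converged
        y_ss = pack_state(cal, gat)

        def residual(y):
            dy = assemble_rhs(0.0, np.abs(y), params)
            # replace one redundant occupancy equation per receptor with the
            # conservation constraint to give the root a unique solution
            dy[13] = np.sum(y[8:14]) - 1.0
            dy[17] = np.sum(y[14:18]) - 1.0
            return dy

        guess = y_ss.copy()
        guess[:8] *= 1.05  # perturb concentrations; occupancies stay a valid distribution
        root = np.abs(fsolve(residual, guess, xtol=1e-12))
        big = np.abs(y_ss) > 1e-6  # compare variables that are meaningfully populated
        assert np.allclose(root[big], y_ss[big], rtol=0.01)


class TestMembranePotentialCoupling:
    def test_null_hook_reproduces_soce_only_run(self, params):
        hook = WholeCellCurrentHook(current=lambda vm, cal, gat, t: 0.0, capacitance=1e-11)
        proto = Protocol(t_end=2.0, record_interval=0.2)
        cal, gat = initial_state(params)
        plain = integrate(cal, gat, params, proto)
        coupled = integrate_with_vm(cal, gat, 5.0, hook, params, proto)
        assert np.allclose(coupled.v_m, 5.0)
        assert np.allclose(coupled.states, plain.states, rtol=1e-5, atol=1e-10)

    def test_linear_leak_hook_relaxes_like_rc_circuit(self, params):
        g, c_m, e_rev = 1e-9, 1e-11, -50.0
        hook = WholeCellCurrentHook(
            current=lambda vm, cal, gat, t: g * (vm - e_rev) * 1e-3, capacitance=c_m
        )
        proto = Protocol(t_end=0.05, record_interval=0.002)
        cal, gat = initial_state(params)
        out = integrate_with_vm(cal, gat, 5.0, hook, params, proto)
        tau = c_m / g
        expected = e_rev + (5.0 - e_rev) * np.exp(-out.time / tau)
        assert np.allclose(out.v_m, expected, rtol=1e-4, atol=1e-3)

    def test_outward_current_hyperpolarizes(self, params):
        hook = WholeCellCurrentHook(current=lambda vm, cal, gat, t: 1e-12, capacitance=1e-11)
        proto = Protocol(t_end=0.01, record_interval=0.002)
        cal, gat = initial_state(params)
        out = integrate_with_vm(cal, gat, 5.0, hook, params, proto)
        assert out.v_m[-1] < 5.0

    def test_non_finite_hook_current_aborts(self, params):
        hook = WholeCellCurrentHook(current=lambda vm, cal, gat, t: float("nan"), capacitance=1e-11)
        cal, gat = initial_state(params)
        with pytest.raises(FloatingPointError):
            integrate_with_vm(cal, gat, 5.0, hook, params, Protocol(t_end=0.01, record_interval=0.005))


def test_state_names_cover_the_vector():
    assert len(STATE_NAMES) == 18
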