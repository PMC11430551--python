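"""LR91 cell model: resting equilibrium, currents, derivatives, accounting.

The independent oracle for the membrane currents is a pure-Python
``math.exp`` implementation of the published formulas (kept separate from
the package's vectorized kernels).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiotet.cell_lr91 import (
    CellConstants,
    CellStateArrays,
    STATE_FIELDS,
    StimulusProtocol,
    init_resting,
    ionic_currents,
    ode_rhs,
    parameter_accounting,
    resting_state,
    reaction_rhs,
    CONSTANT_PARAMETERS,
    VARYING_PARAMETERS,
)
from cardiotet.errors import NumericStateError
from cardiotet.stepping import advance_reaction


# ---------------------------------------------------------------------------
# pure-python oracle (independent route: math.exp, scalar arithmetic)
# ---------------------------------------------------------------------------


def oracle_currents(V, m, h, j, d, f, X, Cai, c: CellConstants):
    exp, log, sqrt = math.exp, math.log, math.sqrt
    RTF = 1000.0 * c.R * c.T / c.F
    E_Na = RTF * log(c.Na_o / c.Na_i)
    E_K = RTF * log((c.K_o + c.PR_NaK * c.Na_o) / (c.K_i + c.PR_NaK * c.Na_i))
    E_K1 = RTF * log(c.K_o / c.K_i)
    I_Na = c.g_Na * m**3 * h * j * (V - E_Na)
    E_si = 7.7 - 13.0287 * log(Cai)
    I_si = c.g_si * d * f * (V - E_si)
    if V <= -100.0:
        Xi = 1.0
    elif abs(V + 77.0) < 1e-7:
        Xi = 2.837 * 0.04 / exp(0.04 * (V + 35.0))
    else:
        Xi = 2.837 * (exp(0.04 * (V + 77.0)) - 1.0) / (
            (V + 77.0) * exp(0.04 * (V + 35.0))
        )
    I_K = c.g_K_bar * sqrt(c.K_o / 5.4) * X * Xi * (V - E_K)
    aK1 = 1.02 / (1.0 + exp(0.2385 * (V - E_K1 - 59.215)))
    bK1 = (
        0.49124 * exp(0.08032 * (V - E_K1 + 5.476))
        + exp(0.06175 * (V - E_K1 - 594.31))
    ) / (1.0 + exp(-0.5143 * (V - E_K1 + 4.753)))
    I_K1 = c.g_K1_bar * sqrt(c.K_o / 5.4) * aK1 / (aK1 + bK1) * (V - E_K1)
    Kp = 1.0 / (1.0 + exp((7.488 - V) / 5.98))
    I_Kp = c.g_Kp * Kp * (V - E_K1)
    I_b = c.g_b * (V - c.E_b)
    return I_Na + I_si + I_K + I_K1 + I_Kp + I_b


# ---------------------------------------------------------------------------
# resting state
# ---------------------------------------------------------------------------


class TestRestingState:
    def test_resting_voltage_near_minus_84(self, default_consts):
        eq = resting_state(default_consts)
        assert -86.0 < eq[0] < -83.0

    def test_gates_in_unit_interval(self, default_consts):
        state = init_resting(5, default_consts)
        gates = state.data[1:7]
        assert gates.min() >= 0.0 and gates.max() <= 1.0
        assert state.Cai.min() > 0.0

    def test_two_calls_identical(self, default_consts):
        a = init_resting(3, default_consts)
        b = init_resting(3, default_consts)
        assert np.array_equal(a.data, b.data)

    def test_rest_is_equilibrium_over_1000_ms(self, default_consts):
        # long unstimulated integration: voltage must not drift
        Y = resting_state(default_consts)[:, None].copy()
        V0 = Y[0, 0]
        dt, n = 0.01, 100_000  # 1000 ms
        drift = 0.0
        stim = np.zeros(1)
        for _ in range(n):
            Y = Y + dt * reaction_rhs(Y, default_consts, stim)
            drift = max(drift, abs(Y[0, 0] - V0))
        assert drift < 0.5

    def test_invalid_node_count(self, default_consts):
        with pytest.raises(ValueError):
            init_resting(0, default_consts)


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------


class TestIonicCurrents:
    def test_near_zero_at_rest(self, default_consts):
        state = init_resting(4, default_consts)
        total, _ = ionic_currents(state, default_consts)
        assert np.abs(total).max() < 1.0

    def test_breakdown_sums_to_total(self, default_consts):
        rng = np.random.default_rng(3)
        state = CellStateArrays.from_fields(
            V=rng.uniform(-90, 30, 16),
            m=rng.uniform(0, 1, 16), h=rng.uniform(0, 1, 16),
            j=rng.uniform(0, 1, 16), d=rng.uniform(0, 1, 16),
            f=rng.uniform(0, 1, 16), X=rng.uniform(0, 1, 16),
            Cai=rng.uniform(1e-5, 1e-2, 16),
        )
        total, ch = ionic_currents(state, default_consts)
        assert np.array_equal(total, sum(ch.values()))

    def test_sodium_current_inward_on_depolarization(self, default_consts):
        # V jumped to +20 mV with gates still at their resting values:
        # the open sodium channels conduct a large inward current
        eq = resting_state(default_consts)
        state = CellStateArrays.from_fields(
            V=20.0, m=0.99, h=eq[2], j=eq[3], d=eq[4], f=eq[5], X=eq[6],
            Cai=eq[7],
        )
        _, ch = ionic_currents(state, default_consts)
        assert ch["I_Na"][0] < -100.0

    def test_matches_pure_python_oracle(self, default_consts):
        rng = np.random.default_rng(11)
        n = 50
        fields = dict(
            V=rng.uniform(-95, 35, n),
            m=rng.uniform(0, 1, n), h=rng.uniform(0, 1, n),
            j=rng.uniform(0, 1, n), d=rng.uniform(0, 1, n),
            f=rng.uniform(0, 1, n), X=rng.uniform(0, 1, n),
            Cai=rng.uniform(1e-5, 1e-2, n),
        )
        state = CellStateArrays.from_fields(**fields)
        total, _ = ionic_currents(state, default_consts)
        for i in range(n):
            ref = oracle_currents(*(fields[k][i] for k in STATE_FIELDS),
                                  default_consts)
            assert total[i] == pytest.approx(ref, rel=1e-12, abs=1e-12)

    def test_singular_voltages_are_finite(self, default_consts):
        # removable singularities of alpha_m and Xi
        for V in (-47.13, -77.0):
            state = CellStateArrays.from_fields(
                V=V, m=0.5, h=0.5, j=0.5, d=0.5, f=0.5, X=0.5, Cai=1e-4
            )
            total, _ = ionic_currents(state, default_consts)
            assert np.isfinite(total).all()
            rhs = ode_rhs(state, default_consts)
            assert np.isfinite(rhs.data).all()

    def test_non_finite_state_rejected_with_node_id(self, default_consts):
        state = init_resting(4, default_consts)
        state.V[2] = np.nan
        with pytest.raises(NumericStateError, match="node 2"):
            ionic_currents(state, default_consts)


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------


class TestOdeRhs:
    def test_zero_at_rest(self, default_consts):
        state = init_resting(3, default_consts)
        rhs = ode_rhs(state, default_consts, stim=0.0)
        assert np.abs(rhs.data).max() < 1e-3

    def test_negative_stimulus_depolarizes(self, default_consts):
        state = init_resting(1, default_consts)
        rhs = ode_rhs(state, default_consts, stim=-80.0)
        assert rhs.V[0] > 70.0  # ~ +80 minus a small ionic term

    def test_doubling_capacitance_halves_dvdt(self):
        c1 = CellConstants()
        c2 = CellConstants(C_m=2.0)
        state = init_resting(1, c1)
        r1 = ode_rhs(state, c1, stim=-40.0)
        r2 = ode_rhs(state, c2, stim=-40.0)
        assert r2.V[0] == pytest.approx(r1.V[0] / 2.0, rel=1e-12)


# ---------------------------------------------------------------------------
# action-potential behavior
# ---------------------------------------------------------------------------


def simulate_single_cell(consts, dt, t_total, amplitude, duration,
                         integrator="euler"):
    Y = resting_state(consts)[:, None].copy()
    n = int(round(t_total / dt))
    V = np.empty(n)
    for k in range(n):
        stim = np.array([amplitude if k * dt < duration else 0.0])
        Y = advance_reaction(Y, consts, stim, dt, integrator)
        V[k] = Y[0, 0]
    return np.arange(1, n + 1) * dt, V, Y


class TestActionPotential:
    def test_suprathreshold_produces_full_ap(self, default_consts):
        t, V, _ = simulate_single_cell(default_consts, 0.005, 600.0, -80.0, 0.5)
        v_rest = resting_state(default_consts)[0]
        assert V.max() > 0.0  # overshoot
        assert V.max() < 60.0  # bounded peak
        assert V.min() > -100.0  # physiological envelope
        assert abs(V[-1] - v_rest) < 2.0  # repolarized by 600 ms

    def test_subthreshold_produces_no_ap(self, default_consts):
        t, V, _ = simulate_single_cell(default_consts, 0.005, 50.0, -2.0, 0.5)
        assert V.max() < -60.0

    def test_short_apd_variant_repolarizes_early(self, short_consts):
        t, V, _ = simulate_single_cell(short_consts, 0.005, 150.0, -80.0, 0.5)
        v_rest = resting_state(short_consts)[0]
        assert V.max() > 0.0
        assert abs(V[-1] - v_rest) < 2.0  # back to rest well before 150 ms

    @settings(deadline=None, max_examples=8, derandomize=True)
    @given(
        amplitude=st.floats(min_value=-200.0, max_value=-60.0),
        dt=st.sampled_from([0.005, 0.01]),
    )
    def test_gates_bounded_under_stimulation(self, amplitude, dt):
        consts = CellConstants()
        Y = resting_state(consts)[:, None].copy()
        for k in range(int(round(8.0 / dt))):  # through the AP upstroke
            stim = np.array([amplitude if k * dt < 1.0 else 0.0])
            Y = advance_reaction(Y, consts, stim, dt, "euler")
            gates = Y[1:7]
            assert gates.min() >= 0.0 and gates.max() <= 1.0


# ---------------------------------------------------------------------------
# stimulus protocol
# ---------------------------------------------------------------------------


class TestStimulusProtocol:
    def test_box_selection(self, tiny_mesh):
        stim = StimulusProtocol.from_box(tiny_mesh, (0, 0.3, 0, 0.3, 0, 0.3))
        coords = tiny_mesh.coords[stim.nodes]
        assert stim.nodes.size > 0
        assert (coords <= 0.3).all()

    def test_single_pulse_window(self):
        s = StimulusProtocol(nodes=[0], t_start=1.0, duration=0.5)
        assert not s.active_at(0.9)
        assert s.active_at(1.0)
        assert s.active_at(1.49)
        assert not s.active_at(1.5)

    def test_periodic_pacing(self):
        s = StimulusProtocol(nodes=[0], duration=0.5, period=100.0)
        for cycle in range(3):
            assert s.active_at(100.0 * cycle + 0.2)
            assert not s.active_at(100.0 * cycle + 50.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            StimulusProtocol(nodes=[0], duration=-1.0)
        with pytest.raises(ValueError):
            StimulusProtocol(nodes=[0], amplitude=math.inf)


# ---------------------------------------------------------------------------
# SoA layout and parameter accounting
# ---------------------------------------------------------------------------


class TestLayoutAndAccounting:
    def test_each_field_is_contiguous_row_view(self, default_consts):
        state = init_resting(10, default_consts)
        for name in STATE_FIELDS:
            row = getattr(state, name)
            assert row.flags["C_CONTIGUOUS"]
            assert row.base is state.data  # zero-copy view
            assert row.shape == (10,)

    def test_enumeration_totals(self):
        assert len(CONSTANT_PARAMETERS) == 20
        assert len(VARYING_PARAMETERS) == 40
        assert len(set(CONSTANT_PARAMETERS) & set(VARYING_PARAMETERS)) == 0

    def test_lr91_memory_figures(self):
        acc = parameter_accounting(60, 20, bytes_per_param=8)
        assert acc.bytes_naive == 480
        assert acc.bytes_optimized == 320
        assert acc.percent_saved == 33

    def test_defaults_match_module_enumeration(self):
        acc = parameter_accounting()
        assert (acc.n_total, acc.n_constant, acc.n_varying) == (60, 20, 40)

    def test_no_constants_no_saving(self):
        acc = parameter_accounting(60, 0)
        assert acc.bytes_optimized == 480
        assert acc.percent_saved == 0

    def test_constants_json_roundtrip(self, tmp_path, short_consts):
        path = str(tmp_path / "consts.json")
        short_consts.save(path)
        assert CellConstants.load(path) == short_consts

    def test_state_csv_roundtrip(self, tmp_path, default_consts):
        state = init_resting(5, default_consts)
        path = str(tmp_path / "state.csv")
        state.to_csv(path)
        back = CellStateArrays.from_csv(path)
        assert np.array_equal(back.data, state.data)
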