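"""Step assembly, conduction-state resolution and the transient march."""

import numpy as np
import pytest

import csneuron as cs
from csneuron.engine import (
    compile_circuit,
    initial_state,
    resolve_nonlinear_states,
    run_transient,
)


def test_ohms_law_single_resistor():
    net = cs.Netlist().add(
        cs.DCSource("V1", pos="p", neg=0, volts=1.0),
        cs.Resistor("R1", "p", 0, 1.0),
    )
    sol = resolve_nonlinear_states(net, dt=1e-4)
    assert sol.potential("p") == pytest.approx(1.0, rel=1e-9)
    assert sol.resistor_current("R1") == pytest.approx(1.0, rel=1e-9)


def test_rc_charging_matches_closed_form(rc_netlist):
    # V(t) = V_inf (1 - exp(-t/RC)); trapezoidal at dt = 1e-4 s
    tr = run_transient(rc_netlist, duration=1.0, dt=1e-4, probes=("c",))
    expected = 1.0 - np.exp(-tr.times)
    assert np.abs(tr.probe("c") - expected).max() < 5e-4


def test_backward_euler_less_accurate_but_converges(rc_netlist):
    tr = run_transient(rc_netlist, duration=1.0, dt=1e-4, probes=("c",), scheme="backward_euler")
    assert tr.probe("c")[-1] == pytest.approx(1.0 - np.exp(-1.0), abs=1e-3)


def test_reverse_biased_ideal_diode_blocks():
    net = cs.Netlist().add(
        cs.DCSource("V1", pos="p", neg=0, volts=5.0),
        cs.Diode("D1", anode=0, cathode="q"),
        cs.Resistor("R1", "q", "p", 10.0),
    )
    sol = resolve_nonlinear_states(net, dt=1e-4)
    assert abs(sol.resistor_current("R1")) < 1e-6


def test_forward_biased_ideal_diode_conducts():
    net = cs.Netlist().add(
        cs.DCSource("V1", pos="p", neg=0, volts=5.0),
        cs.Diode("D1", anode="p", cathode="q"),
        cs.Resistor("R1", "q", 0, 10.0),
    )
    sol = resolve_nonlinear_states(net, dt=1e-4)
    assert sol.state.dio_on[0]
    assert sol.resistor_current("R1") == pytest.approx(0.5, abs=1e-6)


def test_antiparallel_diodes_only_one_conducts():
    net = cs.Netlist().add(
        cs.DCSource("V1", pos="p", neg=0, volts=2.0),
        cs.Resistor("R1", "p", "q", 1.0),
        cs.Diode("Dfwd", anode="q", cathode=0),
        cs.Diode("Drev", anode=0, cathode="q"),
    )
    sol = resolve_nonlinear_states(net, dt=1e-4)
    cc = sol.cc
    states = dict(zip(cc.dio_names, sol.state.dio_on))
    assert states["Dfwd"] and not states["Drev"]


def test_shockley_calibration_one_amp_at_stated_forward_voltage():
    net = cs.Netlist().add(
        cs.DCSource("V1", pos="p", neg=0, volts=0.8059),
        cs.Diode("D1", anode="p", cathode="q", model="shockley"),
        cs.Resistor("R1", "q", 0, 1e-9),
    )
    sol = resolve_nonlinear_states(net, dt=1e-4, max_iter=200)
    assert sol.resistor_current("R1") == pytest.approx(1.0, rel=1e-4)


def test_precharged_unit_fires_and_output_jumps_by_withdraw_voltage():
    # capacitor pre-charged to the +10 V threshold: switch resolves closed
    # and the output node sits at V_cap + 20 V
    net = cs.Netlist().extend(cs.build_excitatory_unit(cs.UnitParams(), 0, "U"))
    net.replace_component("U.C", v0=10.0)
    sol = resolve_nonlinear_states(net, dt=1e-9, update_dynamics=False)
    assert sol.state.sw_closed[0]
    assert sol.potential("U.out") - sol.potential("U.cap") == pytest.approx(20.0, abs=1e-6)
    assert sol.potential("U.out") == pytest.approx(30.0, abs=0.1)


def test_no_discharge_path_keeps_capacitor_voltage():
    frag = cs.build_excitatory_unit(cs.UnitParams(), 0, "U", include_r_ground=False)
    net = cs.Netlist().extend(frag)
    net.replace_component("U.C", v0=5.0)
    tr = run_transient(net, duration=0.01, dt=5e-6, probes=("U.cap",))
    v = tr.probe("U.cap")
    assert np.all(np.abs(v - 5.0) < 1e-3)


def test_hysteresis_no_reopen_between_bounds_and_refractory(regular_bench, regular_run):
    """Between closing (>= v_upper) and opening (<= v_lower) the switch stays
    closed; after opening it never re-closes before t_min_off."""
    tr = run_transient(regular_bench.netlist, 0.05, 5e-6, probes=("U.cap",))
    closes = tr.transitions("U.S", closed=True)
    opens = tr.transitions("U.S", closed=False)
    assert closes.size >= 2
    # transitions alternate: close < open < next close
    n = min(closes.size, opens.size)
    assert np.all(closes[:n] < opens[:n])
    assert np.all(opens[: n - 1] < closes[1:n])
    # bursting bench has a 0.5 ms refractory: closed-to-closed gaps respect it
    bench = cs.build_single_unit_testbench(1, "bursting")
    trb = run_transient(bench.netlist, 0.1, 5e-6)
    cb, ob = trb.transitions("U.S", True), trb.transitions("U.S", False)
    m = min(cb.size - 1, ob.size)
    waits = (cb[1 : m + 1] - ob[:m]) * trb.dt
    assert np.all(waits >= 0.5e-3 - 1e-9)


def test_python_reference_matches_compiled_kernel(regular_bench):
    """The readable single-step solver and the numba march agree bit-for-bit
    over thousands of steps including switch and diode transitions."""
    cc = compile_circuit(regular_bench.netlist)
    st = initial_state(cc)
    vals = []
    n = 2500
    for _ in range(n):
        sol = resolve_nonlinear_states(cc, st, 5e-6)
        st = sol.state
        vals.append(sol.potential("U.cap"))
    tr = run_transient(regular_bench.netlist, n * 5e-6, 5e-6, probes=("U.cap",))
    assert np.abs(np.array(vals) - tr.probe("U.cap")).max() < 1e-12


def test_transient_rejects_bad_arguments(rc_netlist):
    with pytest.raises(ValueError):
        run_transient(rc_netlist, duration=1.0, dt=0.0)
    with pytest.raises(ValueError):
        run_transient(rc_netlist, duration=1e-9, dt=1e-4)
    with pytest.raises(ValueError):
        run_transient(rc_netlist, duration=1.0, dt=1e-4, scheme="euler")


def test_trace_text_outputs(tmp_path, regular_bench):
    tr = run_transient(regular_bench.netlist, 0.01, 5e-6, probes=("U.cap",))
    p1, p2 = tmp_path / "pot.tsv", tmp_path / "ev.tsv"
    tr.save_potentials(p1)
    tr.save_events(p2)
    data = np.loadtxt(p1, skiprows=1)
    assert data.shape == (tr.n_steps, 2)
    lines = p2.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["time_s", "switch", "transition"]
    assert len(lines) - 1 == tr.event_steps.size
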