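"""Unit builders, value sets and parameter scaling."""

import numpy as np
import pytest

import csneuron as cs
from csneuron.netlist import Capacitor, DCSource, Diode, NetlistError, Resistor, Switch
from csneuron.simulate import run_testbench


def _count(frag, typ):
    return sum(isinstance(c, typ) for c in frag)


def test_excitatory_unit_structure():
    frag = cs.build_excitatory_unit(cs.UnitParams(), n_outputs=3, name="N")
    assert _count(frag, Capacitor) == 1
    assert _count(frag, Switch) == 1
    assert _count(frag, DCSource) == 1
    assert _count(frag, Resistor) == 2  # R_ground + R_out
    assert _count(frag, Diode) == 3  # one per outgoing path


def test_excitatory_unit_rejects_invalid():
    with pytest.raises(ValueError):
        cs.build_excitatory_unit(cs.UnitParams(), n_outputs=-1)
    with pytest.raises(NetlistError):
        # withdraw + lower must exceed upper: 14 - 5 < 10
        cs.UnitParams(v_upper=10.0, v_lower=-5.0, v_dc_withdraw=14.0)


def test_derived_action_potential_triple():
    p = cs.UnitParams()
    assert p.v_threshold == 10.0
    assert p.v_hyperpolarization == -5.0
    assert p.v_action == 30.0  # threshold + withdraw


def test_inhibitory_unit_structure_and_degenerate_case():
    frag = cs.build_inhibitory_unit(cs.UnitParams(), n_drawing_paths=2, name="N")
    (sw,) = [c for c in frag if isinstance(c, Switch)]
    assert len(sw.poles) == 2  # DPST: capacitor pole + drawing pole
    assert _count(frag, Diode) == 2
    # no drawing paths -> structurally an excitatory unit without outputs
    frag0 = cs.build_inhibitory_unit(cs.UnitParams(), n_drawing_paths=0, name="N")
    exc = cs.build_excitatory_unit(cs.UnitParams(), n_outputs=0, name="N")
    assert frag0 == exc


def test_inhibitory_unit_requires_sufficient_withdraw_voltage():
    with pytest.raises(NetlistError):
        cs.build_inhibitory_unit(
            cs.UnitParams(v_upper=2.0, v_lower=-5.0, v_dc_withdraw=4.0), 1
        )


def test_inhibitory_firing_draws_charge_from_target():
    """While the inhibitory unit fires, a drawing path pulls a +6 V target
    capacitor down, and the unit's own capacitor ends at the lower bound."""
    frag = cs.build_inhibitory_unit(
        cs.UnitParams(capacitance=6e-6), n_drawing_paths=1, name="I"
    )
    net = cs.Netlist().extend(frag)
    net.add(
        cs.Capacitor("T.C", "T.cap", 0, 6e-6, v0=6.0),
        cs.Resistor("R.draw", "T.cap", "I.dw0", 20.0),
    )
    net.replace_component("I.C", v0=10.0)  # at threshold: fires immediately
    tr = cs.run_transient(net, 0.002, 5e-6, probes=("I.cap", "T.cap"))
    assert tr.transitions("I.S", closed=True).size == 1
    assert tr.probe("T.cap")[-1] < 5.0  # target lost charge
    own = tr.probe("I.cap")
    assert own.min() == pytest.approx(-5.0, abs=0.5)


def test_drawing_activity_does_not_change_own_firing_condition():
    """The inhibitory unit's firing is driven by its own capacitor; adding
    a loaded drawing path must not change when it fires."""

    def bench(with_target: bool):
        frag = cs.build_inhibitory_unit(
            cs.UnitParams(capacitance=6e-6), n_drawing_paths=1, name="I"
        )
        net = cs.Netlist().extend(frag)
        net.add(
            cs.PulseSource("P", "s", 0, v_max=15.0, frequency=200.0, duty=0.05),
            cs.Diode("Din", "s", "a"),
            cs.Resistor("Rin", "a", "I.cap", 10.0),
        )
        if with_target:
            net.add(
                cs.Capacitor("T.C", "T.cap", 0, 6e-6, v0=6.0),
                cs.Resistor("T.Rg", "T.cap", 0, 1000.0),
                cs.Resistor("R.draw", "T.cap", "I.dw0", 20.0),
            )
        else:
            # keep the stub terminated so the netlist stays connected
            net.add(cs.Resistor("R.stub", "I.dw0", 0, 1e6))
        tr = cs.run_transient(net, 0.02, 5e-6)
        return tr.transitions("I.S", closed=True)

    assert np.array_equal(bench(True), bench(False))


def test_scale_value_set_reproduces_published_alternatives():
    vs1 = cs.VALUE_SETS[1]
    assert cs.scale_value_set(vs1, r_factor=10).unit == cs.VALUE_SETS[2].unit
    assert cs.scale_value_set(vs1, r_factor=10).input == cs.VALUE_SETS[2].input
    assert cs.scale_value_set(vs1, v_factor=0.5).unit == cs.VALUE_SETS[3].unit
    assert cs.scale_value_set(vs1, v_factor=0.5).input == cs.VALUE_SETS[3].input
    ident = cs.scale_value_set(vs1, 1.0, 1.0)
    assert ident.unit == vs1.unit and ident.input == vs1.input
    with pytest.raises(ValueError):
        cs.scale_value_set(vs1, r_factor=0.0)


def test_regular_bench_one_spike_per_input_period(regular_run):
    isis = regular_run.pattern.isis
    assert regular_run.pattern.n_spikes >= 18
    # one spike per 5 ms period = 1000 steps of 5 us
    assert np.all(np.abs(isis.astype(float) - 1000.0) <= 1.0)


def test_slow_integration_needs_multiple_pulses_per_spike():
    bench = cs.build_single_unit_testbench(1, "slow_integration")
    res = run_testbench(bench, duration=0.2, dt=5e-6)
    assert res.pattern.n_spikes >= 3
    assert np.all(res.pattern.isis >= 1999)  # at least two input periods


def test_too_small_r_ground_silences_the_unit():
    """A leaky membrane discharges below threshold between pulses: silent
    fire pattern."""
    from dataclasses import replace

    vs = cs.VALUE_SETS[1]
    bench = cs.build_single_unit_testbench(
        cs.ValueSet("leaky", replace(vs.unit, r_ground=2.0, capacitance=6e-6),
                    replace(vs.input, r_input=80.0)),
        "regular",
    )
    res = run_testbench(bench, duration=0.2, dt=5e-6)
    assert res.pattern.n_spikes == 0


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="variant"):
        cs.build_single_unit_testbench(1, "tonic")
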