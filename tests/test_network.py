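"""Five-unit oscillator construction, catalog and ablations."""

import pytest

import csneuron as cs
from csneuron.netlist import Capacitor, Diode, NetlistError, PulseSource, Resistor, Switch
from csneuron.network import (
    AblationFlags,
    NetworkConfig,
    build_network,
    circuit_config,
    default_coupling_resistances,
    state_dimension,
    swap_frequencies,
)
from csneuron.units import ResistanceSchedule


def _count(net, typ):
    return sum(isinstance(c, typ) for c in net)


def test_full_network_structure():
    net = build_network(NetworkConfig())
    assert _count(net, Capacitor) == 5
    assert _count(net, Switch) == 5
    assert _count(net, PulseSource) == 3


def test_n4_n5_ablation_removes_units_and_their_input():
    cfg = NetworkConfig(ablation=AblationFlags(n4_n5=False))
    net = build_network(cfg)
    assert _count(net, Capacitor) == 3
    assert _count(net, PulseSource) == 2
    assert not any("N4" in c.name or "N5" in c.name for c in net)


def test_state_dimension_estimates():
    # capacitor charges + switch states + global time
    assert state_dimension(NetworkConfig()) == 11
    assert state_dimension(NetworkConfig(ablation=AblationFlags(n4_n5=False))) == 7


def _recurrent_resistors(net):
    names = []
    for c in net:
        if isinstance(c, Resistor) and c.name.startswith("R."):
            a, _, b = c.name[2:].partition("-")
            if a == b:
                names.append(c.name)
    return names


def test_back_synapse_flag_controls_recurrent_paths():
    with_back = build_network(NetworkConfig())
    without = build_network(NetworkConfig(ablation=AblationFlags(back_synapses=False)))
    assert "R.N3-N3" in _recurrent_resistors(with_back)
    assert _recurrent_resistors(without) == []


def test_r_ground_and_trashing_ablations():
    net = build_network(
        NetworkConfig(ablation=AblationFlags(r_ground_paths=False, trashing_paths=False))
    )
    assert not any("Rground" in c.name for c in net)
    assert not any("Rout" in c.name for c in net)
    # the capacitors themselves stay referenced to ground
    assert _count(net, Capacitor) == 5


def test_missing_coupling_resistance_is_an_error():
    coup = default_coupling_resistances()
    coup.pop("N5-N3")
    with pytest.raises(NetlistError, match="N5-N3"):
        build_network(NetworkConfig(couplings=coup))


@pytest.mark.parametrize(
    "no, freqs, flags",
    [
        (8, (200.0, 200.0, 223.0), (True, True, True, True)),
        (22, (200.0, 200.0, 200.0), (True, True, True, True)),
        (1, (200.0, 200.0, 223.0), (False, False, False, True)),
        (15, (200.0, 223.0, None), (False, False, True, False)),
    ],
)
def test_circuit_catalog_rows(no, freqs, flags):
    cfg = circuit_config(no)
    f2, f3, f5 = freqs
    assert cfg.freq_n2 == f2 and cfg.freq_n3 == f3
    if f5 is not None:
        assert cfg.freq_n5 == f5
    ab = cfg.ablation
    assert (ab.back_synapses, ab.r_ground_paths, ab.trashing_paths, ab.n4_n5) == flags


def test_unknown_circuit_rejected():
    with pytest.raises(ValueError, match="circuit"):
        circuit_config(99)


def test_frequency_swap_is_involutive_and_swaps():
    cfg = circuit_config(8)
    sw = swap_frequencies(cfg)
    assert (sw.freq_n2, sw.freq_n3, sw.freq_n5) == (223.0, 223.0, 200.0)
    back = swap_frequencies(sw)
    assert (back.freq_n2, back.freq_n3, back.freq_n5) == (200.0, 200.0, 223.0)


def test_apply_schedule_arithmetic():
    bench = cs.build_single_unit_testbench(1, "adaptation")
    sch = bench.schedules[0]
    assert sch == ResistanceSchedule("in1.R", "U.S", increment=30.0, initial=10.0)
    new = cs.apply_schedule(bench.netlist, sch, n_triggers=3)
    assert new == 100.0  # 10 + 3 * 30
    assert bench.netlist["in1.R"].ohms == 100.0
    # zero increment leaves the resistance constant
    net2 = cs.build_single_unit_testbench(1, "adaptation").netlist
    assert cs.apply_schedule(net2, ResistanceSchedule("in1.R", "U.S", 0.0, 10.0), 5) == 10.0
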