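import numpy as np
import pytest

import csneuron as cs


@pytest.fixture(scope="session")
def regular_bench():
    return cs.build_single_unit_testbench(1, "regular")


@pytest.fixture(scope="session")
def regular_run(regular_bench):
    """0.1 s of the value-set-1 regular-spiking bench at the standard step."""
    from csneuron.simulate import run_testbench

    return run_testbench(regular_bench, duration=0.1, dt=5e-6)


@pytest.fixture
def rc_netlist():
    """1 V step source charging C = 1 F through R = 1 ohm."""
    return cs.Netlist(name="rc").add(
        cs.DCSource("V1", pos="p", neg=0, volts=1.0),
        cs.Resistor("R1", "p", "c", 1.0),
        cs.Capacitor("C1", "c", 0, 1.0),
    )


def quasiperiodic_isis(n=3000, seed=0):
    from csneuron.fixtures import FixtureSpec, fixture_series

    return fixture_series(FixtureSpec("two_frequency_quasiperiodic", n_points=n, seed=seed))
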