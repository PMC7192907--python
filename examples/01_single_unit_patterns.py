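"""Fire patterns of a single capacitor-switch neuron.

Builds the four single-unit testbenches (regular spiking, slow integration,
bursting, spike-frequency adaptation), simulates each for a short window at
the standard 5 us step and prints the resulting interspike intervals (ISIs,
in time steps).  Regular spiking locks to the 200 Hz drive (1000 steps =
5 ms); slow integration needs several input pulses per spike (ISIs at
multiples of the drive period); bursting packs several spikes inside each
80 Hz pulse (ISIs near the 0.5 ms switch refractory period); adaptation
shows strictly lengthening ISIs as the input path resistance grows after
every spike.
"""

import numpy as np

from csneuron import build_single_unit_testbench
from csneuron.simulate import run_testbench

for variant, duration in [
    ("regular", 0.1),
    ("slow_integration", 0.2),
    ("bursting", 0.25),
    ("adaptation", 1.0),
]:
    bench = build_single_unit_testbench(1, variant)
    res = run_testbench(bench, duration=duration, dt=5e-6)
    isis = res.pattern.isis
    head = ", ".join(map(str, isis[:8]))
    print(f"{variant:17s} {res.pattern.n_spikes:3d} spikes in {duration:.2f} s; "
          f"first ISIs (steps): [{head}]")

print()
print("One step = 5 us, so 1000 steps = one 5 ms period of the 200 Hz drive.")
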