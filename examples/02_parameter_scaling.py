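"""Power-law parameter scaling of the single-unit circuit.

Scaling every resistance by k and every capacitance by 1/k leaves all node
voltages identical (value set 2); scaling every source and threshold
voltage by k preserves the fire pattern exactly while scaling the recorded
potentials (value set 3).  The script verifies both equivalences
numerically against value set 1.
"""

import numpy as np

from csneuron import VALUE_SETS, build_single_unit_testbench, run_transient, scale_value_set
from csneuron.simulate import run_testbench

vs1 = VALUE_SETS[1]
print("value set 2 == r-scaled set 1:", scale_value_set(vs1, r_factor=10).unit == VALUE_SETS[2].unit)
print("value set 3 == v-scaled set 1:", scale_value_set(vs1, v_factor=0.5).unit == VALUE_SETS[3].unit)

tr1 = run_transient(build_single_unit_testbench(1).netlist, 0.1, 5e-6, probes=("U.cap",))
tr2 = run_transient(build_single_unit_testbench(2).netlist, 0.1, 5e-6, probes=("U.cap",))
dv = np.abs(tr1.probe("U.cap") - tr2.probe("U.cap")).max()
print(f"set 1 vs set 2 capacitor trace: max |dV| = {dv:.2e} V (same potentials)")

r1 = run_testbench(build_single_unit_testbench(1), 1.0)
r3 = run_testbench(build_single_unit_testbench(3), 1.0)
same = np.array_equal(r1.pattern.spike_steps, r3.pattern.spike_steps)
print(f"set 1 vs set 3 spike steps identical: {same} "
      f"({r1.pattern.n_spikes} spikes at 200 Hz)")
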