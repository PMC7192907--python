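"""The five-unit chaotic-oscillator network and its ablations.

Three excitatory units (N3, N4, N5) and two inhibitory units (N1, N2):
the central excitatory unit N3 is cyclically interconnected with the chain
N4 -> N5 (positive feedback, N3 -> N4 -> N5 -> N3) and with the two
interconnected inhibitory units (negative feedback: N3 excites N1, N1 draws
charge off N3, and N1/N2 inhibit each other).  Independent square-pulse
sources drive N2, N3 and N5 through R_input resistors.  Each unit may also
carry a "back synapse", a recurrent diode + resistor path from its own
output back to its capacitor.

A catalog of 23 benchmark configurations (input frequencies x component
ablations) is provided via :func:`circuit_config`; configurations whose
positive-feedback input frequency differs from the measured unit's input
frequency are the ones that produce chaotic fire patterns.

Note on the coupling resistances: the original circuit drawing that fixes
the R_i,j values was not available as data; the packaged defaults
(``data/coupling_resistances_synthetic.yaml``) are a synthetic transcription
chosen once at the scale of the stated path resistances.  They are mandatory
configuration, not hard-coded: any path resistance can be overridden.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

from .netlist import Diode, Netlist, NetlistError, PulseSource, Resistor
from .units import (
    InputParams,
    ResistanceSchedule,
    UnitParams,
    build_excitatory_unit,
    build_inhibitory_unit,
)

__all__ = [
    "AblationFlags",
    "NetworkConfig",
    "build_network",
    "circuit_config",
    "swap_frequencies",
    "default_coupling_resistances",
    "state_dimension",
    "apply_schedule",
    "CIRCUIT_CATALOG",
    "EXCITATORY_UNITS",
    "INHIBITORY_UNITS",
    "EXCITATORY_PATHS",
    "DRAWING_PATHS",
    "MEASURED_UNIT",
]

EXCITATORY_UNITS = ("N3", "N4", "N5")
INHIBITORY_UNITS = ("N1", "N2")
#: (source, target): source unit's output charges target unit's capacitor.
EXCITATORY_PATHS = (("N3", "N4"), ("N4", "N5"), ("N5", "N3"), ("N3", "N1"))
#: (drawer, victim): drawer unit, while firing, pulls charge off the victim.
DRAWING_PATHS = (("N1", "N3"), ("N1", "N2"), ("N2", "N1"))
INPUT_UNITS = ("N2", "N3", "N5")
#: Fire patterns are always measured on the central unit.
MEASURED_UNIT = "N3"


@dataclass(frozen=True)
class AblationFlags:
    """Which optional component groups are present (True = retained).

    ``back_synapses`` - the recurrent R_i,i paths with their diodes;
    ``r_ground_paths`` - the R_ground resistors (the capacitor itself always
    stays referenced to ground); ``trashing_paths`` - the R_out paths with
    their grounding; ``n4_n5`` - units N4 and N5 with all their input and
    output paths (the positive-feedback chain).
    """

    back_synapses: bool = True
    r_ground_paths: bool = True
    trashing_paths: bool = True
    n4_n5: bool = True


def default_coupling_resistances() -> dict[str, float]:
    ref = importlib.resources.files("csneuron").joinpath(
        "data/coupling_resistances_synthetic.yaml"
    )
    return dict(yaml.safe_load(ref.read_text()))


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the five-unit oscillator.

    Defaults are the flagship chaotic configuration: 15 V / 5 % duty pulse
    drive at 200 Hz on N2 and N3 and 223 Hz on N5, 6 uF unit capacitors,
    +10 / -5 V switch bounds, 1000 ohm R_ground, 10 ohm R_input and R_out.
    """

    freq_n2: float = 200.0
    freq_n3: float = 200.0
    freq_n5: float = 223.0
    input_v_max: float = 15.0
    duty: float = 0.05
    capacitance: float = 6e-6
    v_upper: float = 10.0
    v_lower: float = -5.0
    v_dc_withdraw: float = 20.0
    r_ground: float = 1000.0
    r_input: float = 10.0
    r_out: float = 10.0
    couplings: Mapping[str, float] | None = None
    ablation: AblationFlags = field(default_factory=AblationFlags)
    circuit_no: int | None = None

    def unit_params(self) -> UnitParams:
        return UnitParams(
            v_upper=self.v_upper,
            v_lower=self.v_lower,
            v_dc_withdraw=self.v_dc_withdraw,
            capacitance=self.capacitance,
            r_ground=self.r_ground,
            r_out=self.r_out,
        )

    def input_frequency(self, unit: str) -> float:
        return {"N2": self.freq_n2, "N3": self.freq_n3, "N5": self.freq_n5}[unit]


def _coupling(couplings: Mapping[str, float], src: str, dst: str) -> float:
    key = f"{src}-{dst}"
    try:
        return float(couplings[key])
    except KeyError:
        raise NetlistError(f"missing inter-unit resistance for retained path {key}")


def active_units(ablation: AblationFlags) -> tuple[str, ...]:
    if ablation.n4_n5:
        return INHIBITORY_UNITS + EXCITATORY_UNITS
    return ("N1", "N2", "N3")


def build_network(config: NetworkConfig) -> Netlist:
    """Assemble the oscillator netlist for one configuration."""
    ab = config.ablation
    units = active_units(ab)
    couplings = config.couplings if config.couplings is not None else default_coupling_resistances()
    params = config.unit_params()

    exc_paths = [(s, t) for s, t in EXCITATORY_PATHS if s in units and t in units]
    draw_paths = [(d, v) for d, v in DRAWING_PATHS if d in units and v in units]
    inputs = [u for u in INPUT_UNITS if u in units]
    back = list(units) if ab.back_synapses else []

    # outgoing excitatory stubs per source unit (targets in fixed order)
    out_targets: dict[str, list[str]] = {u: [] for u in units}
    for s, t in exc_paths:
        out_targets[s].append(t)
    for u in back:
        if u in EXCITATORY_UNITS or u in INHIBITORY_UNITS:
            out_targets[u].append(u)
    draws_per_unit: dict[str, list[str]] = {u: [] for u in units}
    for d, v in draw_paths:
        draws_per_unit[d].append(v)

    name = f"circuit{config.circuit_no}" if config.circuit_no else "five-unit-oscillator"
    net = Netlist(name=name, description="excitatory/inhibitory CS oscillator")
    for u in units:
        if u in EXCITATORY_UNITS:
            net.extend(
                build_excitatory_unit(
                    params,
                    n_outputs=len(out_targets[u]),
                    name=u,
                    include_r_ground=ab.r_ground_paths,
                    include_r_out=ab.trashing_paths,
                )
            )
        else:
            frag = build_inhibitory_unit(
                params,
                n_drawing_paths=len(draws_per_unit[u]),
                name=u,
                include_r_ground=ab.r_ground_paths,
                include_r_out=ab.trashing_paths,
            )
            net.extend(frag)
            # inhibitory units can also carry regular (non-drawing) outputs,
            # e.g. their back synapse, behind their own diodes
            for k in range(len(out_targets[u])):
                net.add(Diode(f"{u}.Dout{k}", anode=f"{u}.out", cathode=f"{u}.ax{k}"))
    # excitatory + back-synapse resistors from output stubs to target capacitors
    for u in units:
        for k, t in enumerate(out_targets[u]):
            r = _coupling(couplings, u, t)
            net.add(Resistor(f"R.{u}-{t}", f"{u}.ax{k}", f"{t}.cap", r))
    # drawing resistors from victim capacitors into the drawer's stubs
    for d in units:
        for k, v in enumerate(draws_per_unit[d]):
            r = _coupling(couplings, d, v)
            net.add(Resistor(f"Rdraw.{d}-{v}", f"{v}.cap", f"{d}.dw{k}", r))
    # input pulse sources
    for u in inputs:
        src, a = f"in.{u}.src", f"in.{u}.a"
        net.add(
            PulseSource(
                f"in.{u}.DC",
                pos=src,
                neg=0,
                v_max=config.input_v_max,
                frequency=config.input_frequency(u),
                duty=config.duty,
            ),
            Diode(f"in.{u}.D", anode=src, cathode=a),
            Resistor(f"in.{u}.R", a, f"{u}.cap", config.r_input),
        )
    net.validate()
    return net


def state_dimension(config: NetworkConfig) -> int:
    """Dynamic-state dimension: one capacitor voltage and one switch state
    per unit, plus the global time (drive phase)."""
    n = len(active_units(config.ablation))
    return 2 * n + 1


# ---------------------------------------------------------------------------
# benchmark catalog

#: circuit number -> (freq_n2, freq_n3, freq_n5 or None,
#:                    back_synapses, r_ground_paths, trashing_paths, n4_n5)
CIRCUIT_CATALOG: dict[int, tuple] = {
    # chaotic configurations (positive feedback at a different frequency)
    1: (200, 200, 223, False, False, False, True),
    2: (200, 200, 223, True, False, False, True),
    3: (200, 200, 223, False, True, False, True),
    4: (200, 200, 223, True, True, False, True),
    5: (200, 200, 223, False, False, True, True),
    6: (200, 200, 223, True, False, True, True),
    7: (200, 200, 223, False, True, True, True),
    8: (200, 200, 223, True, True, True, True),
    9: (200, 223, 200, True, True, True, True),
    # non-chaotic configurations
    10: (200, 200, None, False, False, False, False),
    11: (200, 200, None, True, False, False, False),
    12: (200, 200, None, False, True, False, False),
    13: (200, 200, None, True, True, False, False),
    14: (200, 200, None, False, False, True, False),
    15: (200, 223, None, False, False, True, False),
    16: (200, 200, None, True, False, True, False),
    17: (200, 223, None, True, False, True, False),
    18: (200, 200, None, False, True, True, False),
    19: (200, 200, None, True, True, True, False),
    20: (200, 200, 200, True, True, False, True),
    21: (200, 223, 223, False, False, True, True),
    22: (200, 200, 200, True, True, True, True),
    23: (200, 223, 223, True, True, True, True),
}


def circuit_config(circuit_no: int, couplings: Mapping[str, float] | None = None) -> NetworkConfig:
    """Configuration of one catalogued benchmark circuit (1..23)."""
    try:
        f2, f3, f5, back, gnd, trash, n45 = CIRCUIT_CATALOG[circuit_no]
    except KeyError:
        raise ValueError(f"unknown circuit {circuit_no}; catalog covers 1..23")
    return NetworkConfig(
        freq_n2=float(f2),
        freq_n3=float(f3),
        freq_n5=float(f5) if f5 is not None else 200.0,
        couplings=couplings,
        ablation=AblationFlags(back, gnd, trash, n45),
        circuit_no=circuit_no,
    )


def swap_frequencies(config: NetworkConfig) -> NetworkConfig:
    """Exchange the 200 Hz and 223 Hz drives (numerical-stability probe:
    the chaotic/non-chaotic classification must not change)."""

    def sw(f: float) -> float:
        if f == 200.0:
            return 223.0
        if f == 223.0:
            return 200.0
        return f

    return replace(
        config,
        freq_n2=sw(config.freq_n2),
        freq_n3=sw(config.freq_n3),
        freq_n5=sw(config.freq_n5),
        circuit_no=None,
    )


def apply_schedule(netlist: Netlist, schedule: ResistanceSchedule, n_triggers: int = 1) -> float:
    """Apply ``n_triggers`` spike-end updates of a resistance schedule to a
    netlist in place; returns the new resistance.  (During simulation the
    engine applies the same update whenever the trigger switch opens.)"""
    r = netlist[schedule.resistor]
    base = schedule.initial if schedule.initial is not None else r.ohms
    new = base + schedule.increment * n_triggers
    netlist.replace_component(schedule.resistor, ohms=new)
    return new
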