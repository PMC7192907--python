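"""Builders for capacitor-switch (CS) neuron units and single-unit benches.

A CS unit extends the integrate-and-fire neuron with explicit circuit
elements: the membrane is a capacitor C to ground, the ionic pumps are a
high-valued R_ground to ground, the threshold/after-hyperpolarization
machinery is a hysteretic voltage-gated switch sensing the capacitor node,
and the action potential is produced by a floating DC "withdraw" source in
series with the switch.  When the capacitor reaches the upper bound
(V_threshold) the switch closes, the output node jumps to
V_capacitor + V_DC_withdraw (the action potential), and the capacitor is
drained through the trashing path (R_out to ground) and any outgoing paths
until it reaches the lower bound (V_hyperpolarization), whereupon the
switch reopens.

The inhibitory unit is the same circuit with a DPST (double-pole) switch:
the second pole connects "drawing paths" to the withdraw source input, so
while the unit fires it also pulls charge off target units' capacitors; the
drawn charge is trashed through the grounded output path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .netlist import (
    GROUND,
    Capacitor,
    Component,
    DCSource,
    Diode,
    Netlist,
    NetlistError,
    PulseSource,
    Resistor,
    Switch,
)

__all__ = [
    "UnitParams",
    "InputParams",
    "ValueSet",
    "VALUE_SETS",
    "build_excitatory_unit",
    "build_inhibitory_unit",
    "build_single_unit_testbench",
    "scale_value_set",
    "Testbench",
    "ResistanceSchedule",
    "TESTBENCH_VARIANTS",
]


@dataclass(frozen=True)
class UnitParams:
    """Per-unit parameter bundle.

    The biological triple (V_threshold, V_hyperpolarization, V_action) maps
    onto (v_upper, v_lower, v_upper + v_dc_withdraw).  The withdraw voltage
    plus the lower bound must exceed the upper bound so the capacitor can be
    fully discharged even against neighbours charged near threshold.
    """

    v_upper: float = 10.0
    v_lower: float = -5.0
    v_dc_withdraw: float = 20.0
    capacitance: float = 500e-9
    r_ground: float = 1000.0
    r_out: float = 10.0
    t_min_off: float = 0.0

    def __post_init__(self) -> None:
        if not self.v_lower < self.v_upper:
            raise NetlistError("unit params: v_lower must be below v_upper")
        if not self.v_dc_withdraw + self.v_lower > self.v_upper:
            raise NetlistError(
                "unit params: v_dc_withdraw + v_lower must exceed v_upper "
                f"({self.v_dc_withdraw} + {self.v_lower} <= {self.v_upper})"
            )

    @property
    def v_threshold(self) -> float:
        return self.v_upper

    @property
    def v_hyperpolarization(self) -> float:
        return self.v_lower

    @property
    def v_action(self) -> float:
        return self.v_upper + self.v_dc_withdraw


@dataclass(frozen=True)
class InputParams:
    """Pulse drive feeding a unit through a diode and R_input."""

    v_max: float = 20.0
    frequency: float = 200.0
    duty: float = 0.05
    r_input: float = 6.0
    phase_deg: float = 0.0


@dataclass(frozen=True)
class ValueSet:
    name: str
    unit: UnitParams
    input: InputParams


#: The three published single-unit parameter sets.  Set 2 is the impedance
#: scaling of set 1 (same voltages), set 3 the voltage scaling (same fire
#: pattern).  Stated for ideal diodes.
VALUE_SETS: dict[int, ValueSet] = {
    1: ValueSet(
        "set1",
        UnitParams(10.0, -5.0, 20.0, 500e-9, 1000.0, 10.0, 0.0),
        InputParams(20.0, 200.0, 0.05, 6.0),
    ),
    2: ValueSet(
        "set2",
        UnitParams(10.0, -5.0, 20.0, 50e-9, 10_000.0, 100.0, 0.0),
        InputParams(20.0, 200.0, 0.05, 60.0),
    ),
    3: ValueSet(
        "set3",
        UnitParams(5.0, -2.5, 10.0, 500e-9, 1000.0, 10.0, 0.0),
        InputParams(10.0, 200.0, 0.05, 6.0),
    ),
}


def scale_value_set(vs: ValueSet, r_factor: float = 1.0, v_factor: float = 1.0) -> ValueSet:
    """Power-law rescaling of a value set.

    ``r_factor`` multiplies every resistance and divides every capacitance,
    which leaves all node voltages identical (same RC products, same
    dividers).  ``v_factor`` multiplies every source and threshold voltage,
    which preserves the fire pattern exactly (the circuit is piecewise
    linear and ideal diodes are scale-invariant) while scaling recorded
    potentials.
    """
    if not (r_factor > 0 and v_factor > 0):
        raise ValueError("scaling factors must be > 0")
    u, i = vs.unit, vs.input
    unit = UnitParams(
        v_upper=u.v_upper * v_factor,
        v_lower=u.v_lower * v_factor,
        v_dc_withdraw=u.v_dc_withdraw * v_factor,
        capacitance=u.capacitance / r_factor,
        r_ground=u.r_ground * r_factor,
        r_out=u.r_out * r_factor,
        t_min_off=u.t_min_off,
    )
    inp = InputParams(
        v_max=i.v_max * v_factor,
        frequency=i.frequency,
        duty=i.duty,
        r_input=i.r_input * r_factor,
        phase_deg=i.phase_deg,
    )
    name = vs.name if (r_factor == 1.0 and v_factor == 1.0) else f"{vs.name}*r{r_factor}v{v_factor}"
    return ValueSet(name, unit, inp)


def build_excitatory_unit(
    params: UnitParams,
    n_outputs: int = 0,
    name: str = "U",
    *,
    include_r_ground: bool = True,
    include_r_out: bool = True,
    trash_source_voltage: float | None = None,
) -> list[Component]:
    """Netlist fragment for one excitatory CS unit.

    Nodes: ``{name}.cap`` (membrane capacitor / switch sense node),
    ``{name}.sw`` (switch output, withdraw-source input), ``{name}.out``
    (output node, at V_cap + V_DC_withdraw while firing).  Each of the
    ``n_outputs`` outgoing stubs ends at ``{name}.ax{k}`` behind its own
    diode so outgoing paths cannot bridge each other.

    ``trash_source_voltage`` optionally inserts a DC source under R_out
    instead of grounding it directly (an accelerated trashing path).
    """
    if n_outputs < 0:
        raise ValueError("n_outputs must be >= 0")
    cap, sw, out = f"{name}.cap", f"{name}.sw", f"{name}.out"
    comps: list[Component] = [
        Capacitor(f"{name}.C", cap, GROUND, params.capacitance),
        Switch(
            f"{name}.S",
            sense=cap,
            poles=((cap, sw),),
            v_upper=params.v_upper,
            v_lower=params.v_lower,
            t_min_off=params.t_min_off,
        ),
        DCSource(f"{name}.DCwithdraw", pos=out, neg=sw, volts=params.v_dc_withdraw),
    ]
    if include_r_ground:
        comps.append(Resistor(f"{name}.Rground", cap, GROUND, params.r_ground))
    if include_r_out:
        if trash_source_voltage is None:
            comps.append(Resistor(f"{name}.Rout", out, GROUND, params.r_out))
        else:
            comps.append(Resistor(f"{name}.Rout", out, f"{name}.trash", params.r_out))
            comps.append(
                DCSource(f"{name}.DCtrash", pos=f"{name}.trash", neg=GROUND, volts=trash_source_voltage)
            )
    for k in range(n_outputs):
        comps.append(Diode(f"{name}.Dout{k}", anode=out, cathode=f"{name}.ax{k}"))
    return comps


def build_inhibitory_unit(
    params: UnitParams,
    n_drawing_paths: int = 0,
    name: str = "U",
    *,
    include_r_ground: bool = True,
    include_r_out: bool = True,
) -> list[Component]:
    """Netlist fragment for one inhibitory CS unit.

    Same core as the excitatory unit, but the switch is a DPST: its second
    pole ties the shared drawing node ``{name}.draw`` to the withdraw-source
    input, so every drawing path is connected exactly while the unit fires.
    Drawing stub ``k`` enters at ``{name}.dw{k}`` through a diode oriented to
    pull charge from the target; the drawn charge leaves through the
    grounded trashing path.  With no drawing paths the fragment degenerates
    to an excitatory unit without outputs.
    """
    if n_drawing_paths < 0:
        raise ValueError("n_drawing_paths must be >= 0")
    if not params.v_dc_withdraw >= -params.v_lower:
        raise NetlistError(
            "inhibitory unit: v_dc_withdraw must be at least -v_lower to "
            "discharge the capacitor down to the hyperpolarization bound"
        )
    cap, sw, out, draw = f"{name}.cap", f"{name}.sw", f"{name}.out", f"{name}.draw"
    poles: tuple = ((cap, sw),) if n_drawing_paths == 0 else ((cap, sw), (draw, sw))
    comps: list[Component] = [
        Capacitor(f"{name}.C", cap, GROUND, params.capacitance),
        Switch(
            f"{name}.S",
            sense=cap,
            poles=poles,
            v_upper=params.v_upper,
            v_lower=params.v_lower,
            t_min_off=params.t_min_off,
        ),
        DCSource(f"{name}.DCwithdraw", pos=out, neg=sw, volts=params.v_dc_withdraw),
    ]
    if include_r_ground:
        comps.append(Resistor(f"{name}.Rground", cap, GROUND, params.r_ground))
    if include_r_out:
        comps.append(Resistor(f"{name}.Rout", out, GROUND, params.r_out))
    for k in range(n_drawing_paths):
        comps.append(Diode(f"{name}.Ddraw{k}", anode=f"{name}.dw{k}", cathode=draw))
    return comps


@dataclass(frozen=True)
class ResistanceSchedule:
    """Per-spike resistance update: each time ``trigger_switch`` opens (the
    end of a produced spike), ``resistor`` gains ``increment`` ohms."""

    resistor: str
    trigger_switch: str
    increment: float
    initial: float | None = None


@dataclass
class Testbench:
    netlist: Netlist
    switch: str  # the unit's main switch, whose closures are the spikes
    schedules: tuple[ResistanceSchedule, ...] = ()
    value_set: ValueSet | None = None
    variant: str = ""


TESTBENCH_VARIANTS = ("regular", "slow_integration", "bursting", "adaptation")


def _input_path(tag: str, inp: InputParams, target: str) -> list[Component]:
    src, a = f"{tag}.src", f"{tag}.a"
    return [
        PulseSource(f"{tag}.DC", pos=src, neg=GROUND, v_max=inp.v_max,
                    frequency=inp.frequency, duty=inp.duty, phase_deg=inp.phase_deg),
        Diode(f"{tag}.D", anode=src, cathode=a),
        Resistor(f"{tag}.R", a, target, inp.r_input),
    ]


def build_single_unit_testbench(
    value_set: ValueSet | int = 1,
    variant: str = "regular",
) -> Testbench:
    """One excitatory unit driven by pulse sources, per fire-pattern variant.

    ``regular``
        the value set as-is; with set 1 the unit emits one spike per 5 ms
        input period (steady 200 Hz output).
    ``slow_integration``
        R_input = 80 ohm and C = 6 uF: a single 250 us pulse no longer
        charges the membrane to threshold, so several input pulses elapse
        between output spikes.
    ``bursting``
        C = 6 uF, 80 Hz / 20 % duty drive, raised lower bound (+8 V) and a
        0.5 ms switch refractory period: each input pulse sustains a train
        of spikes.
    ``adaptation``
        three 200 Hz sources phase-shifted by 120 degrees; the resistance of
        the first input path starts at 10 ohm and grows by 30 ohm after each
        spike, so interspike intervals lengthen (spike-frequency
        adaptation).  C = 6 uF.
    """
    if isinstance(value_set, int):
        value_set = VALUE_SETS[value_set]
    if variant not in TESTBENCH_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {TESTBENCH_VARIANTS}")

    u, inp = value_set.unit, value_set.input
    schedules: tuple[ResistanceSchedule, ...] = ()
    if variant == "slow_integration":
        u = replace(u, capacitance=6e-6)
        inp = replace(inp, r_input=80.0)
    elif variant == "bursting":
        u = replace(u, capacitance=6e-6, v_lower=8.0, t_min_off=0.5e-3)
        inp = replace(inp, frequency=80.0, duty=0.20)
    elif variant == "adaptation":
        u = replace(u, capacitance=6e-6)

    net = Netlist(name=f"{value_set.name}:{variant}",
                  description="single CS excitatory unit with pulse drive")
    if variant == "adaptation":
        resistances = (10.0, 250.0, 250.0)
        for k, r in enumerate(resistances):
            path_inp = replace(inp, r_input=r, phase_deg=120.0 * k)
            net.extend(_input_path(f"in{k + 1}", path_inp, "U.cap"))
        schedules = (ResistanceSchedule("in1.R", "U.S", increment=30.0, initial=10.0),)
    else:
        net.extend(_input_path("in1", inp, "U.cap"))
    net.extend(build_excitatory_unit(u, n_outputs=0, name="U"))
    net.validate()
    return Testbench(netlist=net, switch="U.S", schedules=schedules,
                     value_set=ValueSet(value_set.name, u, inp), variant=variant)
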