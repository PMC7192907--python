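"""Circuit descriptions for capacitor-switch (CS) neuron models.

A :class:`Netlist` is a flat list of two-terminal (or multi-pole) components
wired between named nodes.  Node labels are arbitrary hashable values; the
label ``0`` (or ``"0"``) is the ground node, which represents the resting
potential that the modelled ionic pumps drive the membrane back to -- it is a
reference, not the extracellular space.

The component set is deliberately small: resistors, capacitors, diodes
(ideal or Shockley), DC and pulsed voltage sources, and hysteretic
voltage-gated switches.  Inductors, transistors and op-amps are out of scope
by design; every part maps onto a biological structure of the neuron model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Iterator, Union

import yaml

__all__ = [
    "GROUND",
    "Resistor",
    "Capacitor",
    "Diode",
    "DCSource",
    "PulseSource",
    "Switch",
    "Netlist",
    "NetlistError",
    "Component",
    "is_ground",
    "with_diode_model",
]

#: Canonical ground label.  ``"0"`` and ``"gnd"`` are accepted as synonyms.
GROUND = 0

Node = Union[int, str]


def is_ground(node: Node) -> bool:
    return node == 0 or node == "0" or node == "gnd"


class NetlistError(ValueError):
    """Raised for malformed or ill-posed circuit descriptions."""


@dataclass(frozen=True)
class Resistor:
    name: str
    a: Node
    b: Node
    ohms: float

    def __post_init__(self) -> None:
        if not (self.ohms > 0 and self.ohms < float("inf")):
            raise NetlistError(f"resistor {self.name}: resistance must be finite and > 0")

    @property
    def terminals(self) -> tuple[Node, ...]:
        return (self.a, self.b)


@dataclass(frozen=True)
class Capacitor:
    name: str
    a: Node
    b: Node
    farads: float
    v0: float = 0.0  # initial voltage across a->b

    def __post_init__(self) -> None:
        if not self.farads > 0:
            raise NetlistError(f"capacitor {self.name}: capacitance must be > 0")

    @property
    def terminals(self) -> tuple[Node, ...]:
        return (self.a, self.b)


@dataclass(frozen=True)
class Diode:
    """Ideal or Shockley diode from ``anode`` to ``cathode``.

    The ideal model conducts anode->cathode with zero drop and blocks with
    zero current.  The Shockley model is the exponential law
    ``I = I_s (exp(V / (n Vt)) - 1)`` with the saturation current calibrated
    so that the forward current at ``vf_at_1a`` volts equals exactly 1 A.
    Only the forward voltage at 1 A is pinned; the emission coefficient is a
    free model parameter.
    """

    name: str
    anode: Node
    cathode: Node
    model: str = "ideal"
    vf_at_1a: float = 0.8059
    emission: float = 2.0
    thermal_voltage: float = 0.025865

    def __post_init__(self) -> None:
        if self.model not in ("ideal", "shockley"):
            raise NetlistError(f"diode {self.name}: unknown model {self.model!r}")

    @property
    def terminals(self) -> tuple[Node, ...]:
        return (self.anode, self.cathode)


@dataclass(frozen=True)
class DCSource:
    """Constant voltage source enforcing ``V(pos) - V(neg) = volts``.

    Neither terminal needs to be ground, so this doubles as the floating
    withdraw source of a CS unit.
    """

    name: str
    pos: Node
    neg: Node
    volts: float

    @property
    def terminals(self) -> tuple[Node, ...]:
        return (self.pos, self.neg)


@dataclass(frozen=True)
class PulseSource:
    """Square-wave source: ``v_max`` for the first ``duty`` fraction of each
    period, 0 V otherwise.  ``phase_deg`` shifts the waveform left."""

    name: str
    pos: Node
    neg: Node
    v_max: float
    frequency: float
    duty: float
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise NetlistError(f"pulse source {self.name}: frequency must be > 0")
        if not 0.0 <= self.duty <= 1.0:
            raise NetlistError(f"pulse source {self.name}: duty cycle must be in [0, 1]")

    @property
    def terminals(self) -> tuple[Node, ...]:
        return (self.pos, self.neg)

    def value(self, t: float) -> float:
        ph = t * self.frequency + self.phase_deg / 360.0
        return self.v_max if (ph - int(ph)) % 1.0 < self.duty else 0.0


@dataclass(frozen=True)
class Switch:
    """Hysteretic voltage-gated switch.

    Monitors the potential of ``sense`` and closes every pole pair
    simultaneously when the sense potential reaches ``v_upper`` (provided at
    least ``t_min_off`` seconds have passed since it last opened -- the
    refractory period).  It reopens when the sense potential falls to
    ``v_lower``.  While closed each pole is a zero-resistance passive
    connection; the part has no gain, unlike a Schmitt trigger.
    """

    name: str
    sense: Node
    poles: tuple[tuple[Node, Node], ...]
    v_upper: float
    v_lower: float
    t_min_off: float = 0.0
    closed: bool = False

    def __post_init__(self) -> None:
        if not self.v_lower < self.v_upper:
            raise NetlistError(f"switch {self.name}: requires v_lower < v_upper")
        if self.t_min_off < 0:
            raise NetlistError(f"switch {self.name}: t_min_off must be >= 0")
        if len(self.poles) < 1:
            raise NetlistError(f"switch {self.name}: needs at least one pole")
        object.__setattr__(self, "poles", tuple(tuple(p) for p in self.poles))

    @property
    def terminals(self) -> tuple[Node, ...]:
        out: list[Node] = [self.sense]
        for a, b in self.poles:
            out.extend((a, b))
        return tuple(out)


Component = Union[Resistor, Capacitor, Diode, DCSource, PulseSource, Switch]

_TYPE_TAGS: dict[type, str] = {
    Resistor: "resistor",
    Capacitor: "capacitor",
    Diode: "diode",
    DCSource: "dc_source",
    PulseSource: "pulse_source",
    Switch: "switch",
}
_TAG_TYPES = {v: k for k, v in _TYPE_TAGS.items()}


@dataclass
class Netlist:
    """A named collection of components forming one circuit."""

    name: str = ""
    description: str = ""
    components: list[Component] = field(default_factory=list)

    def add(self, *components: Component) -> "Netlist":
        self.components.extend(components)
        return self

    def extend(self, components: Iterable[Component]) -> "Netlist":
        self.components.extend(components)
        return self

    def __iter__(self) -> Iterator[Component]:
        return iter(self.components)

    def __len__(self) -> int:
        return len(self.components)

    @property
    def nodes(self) -> list[Node]:
        """All non-ground node labels, in first-appearance order."""
        seen: dict[Node, None] = {}
        for c in self.components:
            for t in c.terminals:
                if not is_ground(t):
                    seen.setdefault(t, None)
        return list(seen)

    def __getitem__(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def replace_component(self, name: str, **changes: Any) -> None:
        for i, c in enumerate(self.components):
            if c.name == name:
                self.components[i] = replace(c, **changes)
                return
        raise KeyError(name)

    def validate(self) -> None:
        """Check structural invariants.

        Raises :class:`NetlistError` with the offending names if component
        names collide, no component touches ground, or some nodes are not
        connected to ground through any component (a floating subnetwork
        would make the nodal equations singular).
        """
        names: set[str] = set()
        for c in self.components:
            if c.name in names:
                raise NetlistError(f"duplicate component name {c.name!r}")
            names.add(c.name)
        touches_ground = any(
            any(is_ground(t) for t in c.terminals) for c in self.components
        )
        if self.components and not touches_ground:
            raise NetlistError("no component is connected to ground (node 0)")
        # Connectivity: treat every component as an edge set over its
        # terminals regardless of switch/diode state.
        adj: dict[Node, set[Node]] = {}
        def _norm(n: Node) -> Node:
            return GROUND if is_ground(n) else n
        for c in self.components:
            ts = [_norm(t) for t in c.terminals]
            for t in ts:
                adj.setdefault(t, set()).update(u for u in ts if u != t)
        if not adj:
            return
        reached = {GROUND}
        stack = [GROUND]
        while stack:
            for nb in adj.get(stack.pop(), ()):
                if nb not in reached:
                    reached.add(nb)
                    stack.append(nb)
        floating = [n for n in adj if n not in reached]
        if floating:
            raise NetlistError(
                "nodes not connected to ground: " + ", ".join(map(str, floating))
            )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        comps = []
        for c in self.components:
            tag = _TYPE_TAGS[type(c)]
            entry: dict[str, Any] = {"type": tag, "name": c.name}
            if isinstance(c, Switch):
                entry["nodes"] = [c.sense] + [list(p) for p in c.poles]
                entry["parameters"] = {
                    "v_upper": c.v_upper,
                    "v_lower": c.v_lower,
                    "t_min_off": c.t_min_off,
                    "closed": c.closed,
                }
            else:
                entry["nodes"] = list(c.terminals)
                params = {
                    k: v
                    for k, v in c.__dict__.items()
                    if k not in ("name", "a", "b", "anode", "cathode", "pos", "neg")
                }
                entry["parameters"] = params
            comps.append(entry)
        return {"name": self.name, "description": self.description, "components": comps}

    @classmethod
    def from_dict(cls, d: dict) -> "Netlist":
        comps: list[Component] = []
        for entry in d.get("components", []):
            tag = entry["type"]
            if tag not in _TAG_TYPES:
                raise NetlistError(f"unknown component type {tag!r}")
            typ = _TAG_TYPES[tag]
            nodes = entry["nodes"]
            params = dict(entry.get("parameters", {}))
            if typ is Switch:
                sense, *poles = nodes
                comps.append(
                    Switch(entry["name"], sense, tuple(tuple(p) for p in poles), **params)
                )
            elif typ is Diode:
                comps.append(Diode(entry["name"], nodes[0], nodes[1], **params))
            else:
                comps.append(typ(entry["name"], nodes[0], nodes[1], **params))
        return cls(d.get("name", ""), d.get("description", ""), comps)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "Netlist":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def with_diode_model(netlist: Netlist, model: str, **diode_params: float) -> Netlist:
    """Return a copy of ``netlist`` with every diode set to ``model``.

    Used to check that a circuit's qualitative fire pattern does not depend
    on whether diodes are ideal or follow the Shockley exponential law.
    """
    comps: list[Component] = []
    for c in netlist.components:
        if isinstance(c, Diode):
            comps.append(replace(c, model=model, **diode_params))
        else:
            comps.append(c)
    return Netlist(netlist.name, netlist.description, comps)
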