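"""Experiments: run circuits, detect spikes, extract interspike intervals.

A spike is the closure of a unit's main voltage-gated switch (the moment
the capacitor crosses the upper threshold); spike times are the step
indices of open->closed transitions, so interspike intervals (ISIs) come
out in integer multiples of the time step.  The first ~10 ms of every run
are discarded as the initial transient before the network settles into its
stationary fire pattern.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .engine import Trace, run_transient
from .network import MEASURED_UNIT, NetworkConfig, build_network, circuit_config
from .units import Testbench

__all__ = [
    "FirePattern",
    "ExperimentResult",
    "detect_spikes",
    "extract_isis",
    "run_experiment",
    "run_testbench",
    "write_isis",
    "read_isis",
    "DEFAULT_DT",
    "DEFAULT_DISCARD",
]

DEFAULT_DT = 5e-6
DEFAULT_DISCARD = 0.010


@dataclass
class FirePattern:
    """Ordered spike times of one unit, in integer time steps."""

    spike_steps: np.ndarray
    dt: float
    source_unit: str = ""

    def __post_init__(self) -> None:
        self.spike_steps = np.asarray(self.spike_steps, np.int64)
        if self.spike_steps.size > 1 and not np.all(np.diff(self.spike_steps) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_steps.size)

    @property
    def spike_times(self) -> np.ndarray:
        return self.spike_steps * self.dt

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_steps)


def detect_spikes(trace: Trace, switch: str) -> FirePattern:
    """One spike per open->closed transition of the unit's main switch.

    An empty pattern (switch never closed) is a valid "silent" fire
    pattern.
    """
    steps = trace.transitions(switch, closed=True)
    return FirePattern(spike_steps=steps, dt=trace.dt, source_unit=switch)


def extract_isis(pattern: FirePattern, discard_initial: float = DEFAULT_DISCARD) -> np.ndarray:
    """ISIs (in steps) between consecutive spikes after the initial
    transient window is discarded."""
    steps = pattern.spike_steps
    if discard_initial > 0:
        steps = steps[steps * pattern.dt >= discard_initial]
    if steps.size < 2:
        raise ValueError("fewer than 2 spikes retained; cannot form intervals")
    return np.diff(steps)


@dataclass
class ExperimentResult:
    isis: np.ndarray
    pattern: FirePattern
    provenance: dict = field(default_factory=dict)

    @property
    def max_isi(self) -> int:
        return int(self.isis.max())

    @property
    def n_isis(self) -> int:
        return int(self.isis.size)


def run_experiment(
    config: NetworkConfig | int,
    duration: float,
    dt: float = DEFAULT_DT,
    *,
    discard_initial: float = DEFAULT_DISCARD,
    unit: str = MEASURED_UNIT,
    diode_model: str = "ideal",
    scheme: str = "trapezoidal",
    probes: Sequence = (),
) -> ExperimentResult:
    """End-to-end network experiment: build -> transient -> spikes -> ISIs.

    ``config`` may be a :class:`NetworkConfig` or a catalog circuit number.
    The provenance record captures every parameter needed for bit-exact
    replay (the simulation is seed-free).
    """
    if duration < 1.0:
        raise ValueError("duration must be at least 1 s")
    if isinstance(config, int):
        config = circuit_config(config)
    net = build_network(config)
    if diode_model != "ideal":
        from .netlist import with_diode_model

        net = with_diode_model(net, diode_model)
    trace = run_transient(net, duration, dt, probes=probes, scheme=scheme)
    pattern = detect_spikes(trace, f"{unit}.S")
    isis = extract_isis(pattern, discard_initial)
    prov: dict = {
        "kind": "network",
        "circuit": config.circuit_no,
        "config": _config_dict(config),
        "duration": duration,
        "dt": dt,
        "discard_initial": discard_initial,
        "unit": unit,
        "diode_model": diode_model,
        "scheme": scheme,
    }
    return ExperimentResult(isis=isis, pattern=pattern, provenance=prov)


def run_testbench(
    bench: Testbench,
    duration: float,
    dt: float = DEFAULT_DT,
    *,
    discard_initial: float = 0.0,
    probes: Sequence = (),
) -> ExperimentResult:
    """Run a single-unit testbench and return its fire pattern."""
    trace = run_transient(
        bench.netlist, duration, dt, probes=probes, schedules=bench.schedules
    )
    pattern = detect_spikes(trace, bench.switch)
    isis = (
        extract_isis(pattern, discard_initial)
        if pattern.n_spikes >= 2
        else np.zeros(0, np.int64)
    )
    prov = {
        "kind": "testbench",
        "variant": bench.variant,
        "value_set": bench.value_set.name if bench.value_set else None,
        "duration": duration,
        "dt": dt,
    }
    return ExperimentResult(isis=isis, pattern=pattern, provenance=prov)


def _config_dict(config: NetworkConfig) -> dict:
    d = asdict(config)
    if d.get("couplings") is not None:
        d["couplings"] = dict(d["couplings"])
    return d


# ---------------------------------------------------------------------------
# ISI file format: one integer (steps) per line, '#'-prefixed header


def write_isis(path, isis: np.ndarray, header: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        for isi in np.asarray(isis).ravel():
            fh.write(f"{isi}\n")


def read_isis(path) -> tuple[np.ndarray, dict]:
    meta: dict = {}
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            values.append(float(line))
    arr = np.asarray(values)
    if arr.size and np.allclose(arr, np.round(arr)):
        arr = arr.astype(np.int64)
    return arr, meta
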