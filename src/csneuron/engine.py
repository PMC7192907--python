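"""Fixed-step piecewise-linear transient simulation.

The solver is a companion-model nodal analysis with a fixed time step, the
scheme used by interactive circuit simulators:

* capacitors become a conductance ``2C/dt`` (trapezoidal, second order) or
  ``C/dt`` (backward Euler) in parallel with a history current source;
* every voltage-defined element (DC source, pulse source, closed switch
  pole, conducting ideal diode) contributes a branch-current unknown and a
  constraint row, giving an augmented (MNA) linear system;
* ideal diodes and hysteretic switches make the system piecewise linear:
  each step is re-solved under hypothesised conduction states until the
  states are self-consistent (conducting diodes carry forward current,
  blocking diodes see non-positive bias, switch states satisfy the
  hysteresis rule at the solved sense potential);
* Shockley diodes are handled by damped Newton iteration on the same loop.

A switch may change state at most once per time step, so transition times
are quantised to the step grid.  Every node carries a 1 GOhm leak to ground
so that subcircuits isolated behind open switches stay numerically
well-posed; 1 GOhm is many orders above any circuit resistance, making the
leak currents negligible.

The long inner march is compiled with numba.  A plain-Python single-step
implementation of the same stamps (:func:`assemble_step_system`,
:func:`resolve_nonlinear_states`) is kept as the readable reference and is
cross-checked against the compiled kernel in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .netlist import (
    Capacitor,
    DCSource,
    Diode,
    Netlist,
    NetlistError,
    PulseSource,
    Resistor,
    Switch,
    is_ground,
)

__all__ = [
    "CompiledCircuit",
    "SimState",
    "Trace",
    "StepSolution",
    "compile_circuit",
    "initial_state",
    "assemble_step_system",
    "resolve_nonlinear_states",
    "run_transient",
    "ConvergenceError",
]

LEAK_G = 1e-9  # 1 GOhm to ground on every node
MAX_ITER = 100
_I_TOL = 1e-12  # ties (zero current / zero bias) resolve to blocking
_V_TOL = 1e-9

# branch kinds
_BR_DC = 0
_BR_PULSE = 1
_BR_POLE = 2
_BR_DIODE = 3


class ConvergenceError(RuntimeError):
    """No self-consistent conduction-state assignment was found."""


# ---------------------------------------------------------------------------
# compilation


@dataclass
class CompiledCircuit:
    """Array form of a netlist, ready for the stepping kernel.

    Node labels are mapped to indices ``0..n_nodes-1``; ground is ``-1``.
    """

    netlist: Netlist
    node_index: dict
    n_nodes: int
    # resistors
    res_a: np.ndarray
    res_b: np.ndarray
    res_ohms: np.ndarray  # mutable (resistance schedules)
    res_names: list
    # capacitors
    cap_a: np.ndarray
    cap_b: np.ndarray
    cap_c: np.ndarray
    cap_v0: np.ndarray
    cap_names: list
    # Shockley diodes (nonlinear conductances)
    sh_a: np.ndarray
    sh_b: np.ndarray
    sh_is: np.ndarray
    sh_nvt: np.ndarray
    sh_names: list
    # voltage-defined branches
    br_a: np.ndarray
    br_b: np.ndarray
    br_kind: np.ndarray
    br_val: np.ndarray
    br_names: list
    # pulse sources -> branch mapping
    pul_branch: np.ndarray
    pul_vmax: np.ndarray
    pul_freq: np.ndarray
    pul_duty: np.ndarray
    pul_phase: np.ndarray
    # ideal diodes -> branch mapping
    dio_branch: np.ndarray
    dio_names: list
    # switches
    sw_sense: np.ndarray
    sw_vu: np.ndarray
    sw_vl: np.ndarray
    sw_toff: np.ndarray
    sw_init_closed: np.ndarray
    sw_names: list
    pole_branch: np.ndarray
    pole_sw: np.ndarray

    @property
    def n_branches(self) -> int:
        return int(self.br_kind.size)

    @property
    def dim(self) -> int:
        return self.n_nodes + self.n_branches

    def node(self, label) -> int:
        if is_ground(label):
            return -1
        return self.node_index[label]


def compile_circuit(netlist: Netlist) -> CompiledCircuit:
    netlist.validate()
    node_index: dict = {}

    def idx(label) -> int:
        if is_ground(label):
            return -1
        if label not in node_index:
            node_index[label] = len(node_index)
        return node_index[label]

    res_a, res_b, res_ohms, res_names = [], [], [], []
    cap_a, cap_b, cap_c, cap_v0, cap_names = [], [], [], [], []
    sh_a, sh_b, sh_is, sh_nvt, sh_names = [], [], [], [], []
    br_a, br_b, br_kind, br_val, br_names = [], [], [], [], []
    pul_branch, pul_vmax, pul_freq, pul_duty, pul_phase = [], [], [], [], []
    dio_branch, dio_names = [], []
    sw_sense, sw_vu, sw_vl, sw_toff, sw_closed0, sw_names = [], [], [], [], [], []
    pole_branch, pole_sw = [], []

    def add_branch(a, b, kind, val, name) -> int:
        br_a.append(idx(a))
        br_b.append(idx(b))
        br_kind.append(kind)
        br_val.append(val)
        br_names.append(name)
        return len(br_kind) - 1

    for c in netlist.components:
        if isinstance(c, Resistor):
            res_a.append(idx(c.a))
            res_b.append(idx(c.b))
            res_ohms.append(c.ohms)
            res_names.append(c.name)
        elif isinstance(c, Capacitor):
            cap_a.append(idx(c.a))
            cap_b.append(idx(c.b))
            cap_c.append(c.farads)
            cap_v0.append(c.v0)
            cap_names.append(c.name)
        elif isinstance(c, Diode):
            if c.model == "ideal":
                k = add_branch(c.anode, c.cathode, _BR_DIODE, 0.0, c.name)
                dio_branch.append(k)
                dio_names.append(c.name)
            else:
                nvt = c.emission * c.thermal_voltage
                isat = 1.0 / math.expm1(c.vf_at_1a / nvt)
                sh_a.append(idx(c.anode))
                sh_b.append(idx(c.cathode))
                sh_is.append(isat)
                sh_nvt.append(nvt)
                sh_names.append(c.name)
        elif isinstance(c, DCSource):
            add_branch(c.pos, c.neg, _BR_DC, c.volts, c.name)
        elif isinstance(c, PulseSource):
            k = add_branch(c.pos, c.neg, _BR_PULSE, 0.0, c.name)
            pul_branch.append(k)
            pul_vmax.append(c.v_max)
            pul_freq.append(c.frequency)
            pul_duty.append(c.duty)
            pul_phase.append(c.phase_deg)
        elif isinstance(c, Switch):
            s = len(sw_names)
            sw_sense.append(idx(c.sense))
            sw_vu.append(c.v_upper)
            sw_vl.append(c.v_lower)
            sw_toff.append(c.t_min_off)
            sw_closed0.append(c.closed)
            sw_names.append(c.name)
            for p, (a, b) in enumerate(c.poles):
                k = add_branch(a, b, _BR_POLE, 0.0, f"{c.name}#pole{p}")
                pole_branch.append(k)
                pole_sw.append(s)
        else:  # pragma: no cover
            raise NetlistError(f"unsupported component {c!r}")

    f8 = np.asarray
    return CompiledCircuit(
        netlist=netlist,
        node_index=node_index,
        n_nodes=len(node_index),
        res_a=f8(res_a, np.int64),
        res_b=f8(res_b, np.int64),
        res_ohms=f8(res_ohms, np.float64),
        res_names=res_names,
        cap_a=f8(cap_a, np.int64),
        cap_b=f8(cap_b, np.int64),
        cap_c=f8(cap_c, np.float64),
        cap_v0=f8(cap_v0, np.float64),
        cap_names=cap_names,
        sh_a=f8(sh_a, np.int64),
        sh_b=f8(sh_b, np.int64),
        sh_is=f8(sh_is, np.float64),
        sh_nvt=f8(sh_nvt, np.float64),
        sh_names=sh_names,
        br_a=f8(br_a, np.int64),
        br_b=f8(br_b, np.int64),
        br_kind=f8(br_kind, np.int64),
        br_val=f8(br_val, np.float64),
        br_names=br_names,
        pul_branch=f8(pul_branch, np.int64),
        pul_vmax=f8(pul_vmax, np.float64),
        pul_freq=f8(pul_freq, np.float64),
        pul_duty=f8(pul_duty, np.float64),
        pul_phase=f8(pul_phase, np.float64),
        dio_branch=f8(dio_branch, np.int64),
        dio_names=dio_names,
        sw_sense=f8(sw_sense, np.int64),
        sw_vu=f8(sw_vu, np.float64),
        sw_vl=f8(sw_vl, np.float64),
        sw_toff=f8(sw_toff, np.float64),
        sw_init_closed=f8(sw_closed0, np.bool_),
        sw_names=sw_names,
        pole_branch=f8(pole_branch, np.int64),
        pole_sw=f8(pole_sw, np.int64),
    )


# ---------------------------------------------------------------------------
# state


@dataclass
class SimState:
    """Complete dynamic state: the simulation is a deterministic function of
    this plus the netlist (capacitor charges, switch states, global time)."""

    time: float = 0.0
    step_index: int = 0
    cap_v: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cap_i: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sw_closed: np.ndarray = field(default_factory=lambda: np.zeros(0, np.bool_))
    sw_last_open: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dio_on: np.ndarray = field(default_factory=lambda: np.zeros(0, np.bool_))
    sh_v: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sense_prev: np.ndarray = field(default_factory=lambda: np.zeros(0))
    node_potentials: dict = field(default_factory=dict)

    def copy(self) -> "SimState":
        return SimState(
            self.time,
            self.step_index,
            self.cap_v.copy(),
            self.cap_i.copy(),
            self.sw_closed.copy(),
            self.sw_last_open.copy(),
            self.dio_on.copy(),
            self.sh_v.copy(),
            self.sense_prev.copy(),
            dict(self.node_potentials),
        )


def initial_state(cc: CompiledCircuit) -> SimState:
    # Seed each switch's remembered sense potential from the initial charge
    # of a capacitor tied to its sense node, so that a capacitor pre-charged
    # to the threshold fires on the first step.
    sense_prev = np.zeros(len(cc.sw_names))
    for s in range(len(cc.sw_names)):
        node = cc.sw_sense[s]
        for k in range(cc.cap_a.size):
            if cc.cap_a[k] == node and cc.cap_b[k] < 0:
                sense_prev[s] = cc.cap_v0[k]
            elif cc.cap_b[k] == node and cc.cap_a[k] < 0:
                sense_prev[s] = -cc.cap_v0[k]
    return SimState(
        time=0.0,
        step_index=0,
        cap_v=cc.cap_v0.copy(),
        cap_i=np.zeros_like(cc.cap_v0),
        sw_closed=cc.sw_init_closed.copy(),
        sw_last_open=np.full(len(cc.sw_names), -1e30),
        dio_on=np.zeros(len(cc.dio_names), np.bool_),
        sh_v=np.zeros(len(cc.sh_names)),
        sense_prev=sense_prev,
    )


# ---------------------------------------------------------------------------
# reference (pure Python) single-step solver


def _branch_active(cc: CompiledCircuit, k: int, sw_closed, dio_on) -> bool:
    kind = cc.br_kind[k]
    if kind == _BR_DC or kind == _BR_PULSE:
        return True
    if kind == _BR_POLE:
        s = cc.pole_sw[np.searchsorted(cc.pole_branch, k)]
        return bool(sw_closed[s])
    d = int(np.searchsorted(cc.dio_branch, k))
    return bool(dio_on[d])


def assemble_step_system(
    cc: CompiledCircuit | Netlist,
    state: SimState | None = None,
    dt: float = 5e-6,
    *,
    time: float | None = None,
    scheme: str = "trapezoidal",
):
    """Build the augmented nodal system ``G x = rhs`` for one time step.

    The system is assembled for the conduction states recorded in ``state``
    (a hypothesis; :func:`resolve_nonlinear_states` iterates it to a fixed
    point).  Unknowns are the ``n_nodes`` node potentials followed by one
    current per voltage-defined branch.
    """
    if isinstance(cc, Netlist):
        cc = compile_circuit(cc)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    st = state if state is not None else initial_state(cc)
    # time comes from the step grid, not accumulation, so pulse edges land
    # on exactly the same steps regardless of how the march is chunked
    t = (st.step_index + 1) * dt if time is None else time
    trap = scheme == "trapezoidal"
    if scheme not in ("trapezoidal", "backward_euler"):
        raise ValueError(f"unknown scheme {scheme!r}")

    n = cc.n_nodes
    dim = cc.dim
    G = np.zeros((dim, dim))
    rhs = np.zeros(dim)

    def stamp_g(a: int, b: int, g: float) -> None:
        if a >= 0:
            G[a, a] += g
        if b >= 0:
            G[b, b] += g
        if a >= 0 and b >= 0:
            G[a, b] -= g
            G[b, a] -= g

    for i in range(n):
        G[i, i] += LEAK_G
    for k in range(cc.res_a.size):
        stamp_g(cc.res_a[k], cc.res_b[k], 1.0 / cc.res_ohms[k])
    for k in range(cc.cap_a.size):
        gc = (2.0 if trap else 1.0) * cc.cap_c[k] / dt
        stamp_g(cc.cap_a[k], cc.cap_b[k], gc)
        ieq = gc * st.cap_v[k] + (st.cap_i[k] if trap else 0.0)
        a, b = cc.cap_a[k], cc.cap_b[k]
        if a >= 0:
            rhs[a] += ieq
        if b >= 0:
            rhs[b] -= ieq
    for k in range(cc.sh_a.size):
        v0 = st.sh_v[k]
        e = math.exp(min(v0 / cc.sh_nvt[k], 60.0))
        g = cc.sh_is[k] / cc.sh_nvt[k] * e
        i0 = cc.sh_is[k] * (e - 1.0)
        stamp_g(cc.sh_a[k], cc.sh_b[k], g)
        ieq = i0 - g * v0  # residual current anode->cathode
        a, b = cc.sh_a[k], cc.sh_b[k]
        if a >= 0:
            rhs[a] -= ieq
        if b >= 0:
            rhs[b] += ieq
    for k in range(cc.n_branches):
        a, b = cc.br_a[k], cc.br_b[k]
        row = n + k
        if a >= 0:
            G[a, row] += 1.0
        if b >= 0:
            G[b, row] -= 1.0
        if _branch_active(cc, k, st.sw_closed, st.dio_on):
            if a >= 0:
                G[row, a] += 1.0
            if b >= 0:
                G[row, b] -= 1.0
            if cc.br_kind[k] == _BR_PULSE:
                p = int(np.searchsorted(cc.pul_branch, k))
                ph = t * cc.pul_freq[p] + cc.pul_phase[p] / 360.0
                rhs[row] = cc.pul_vmax[p] if ph % 1.0 < cc.pul_duty[p] else 0.0
            else:
                rhs[row] = cc.br_val[k]
        else:
            G[row, row] = 1.0
            rhs[row] = 0.0
    return G, rhs


@dataclass
class StepSolution:
    """Solved potentials and branch currents for one accepted step."""

    x: np.ndarray
    state: SimState
    cc: CompiledCircuit

    def potential(self, node) -> float:
        i = self.cc.node(node)
        return 0.0 if i < 0 else float(self.x[i])

    def branch_current(self, name: str) -> float:
        """Current through a voltage-defined branch (source, pole, ideal
        diode), measured from its first to its second terminal."""
        k = self.cc.br_names.index(name)
        return float(self.x[self.cc.n_nodes + k])

    def resistor_current(self, name: str) -> float:
        k = self.cc.res_names.index(name)
        a, b = self.cc.res_a[k], self.cc.res_b[k]
        va = self.x[a] if a >= 0 else 0.0
        vb = self.x[b] if b >= 0 else 0.0
        return float((va - vb) / self.cc.res_ohms[k])


def resolve_nonlinear_states(
    cc: CompiledCircuit | Netlist,
    state: SimState | None = None,
    dt: float = 5e-6,
    *,
    time: float | None = None,
    scheme: str = "trapezoidal",
    max_iter: int = MAX_ITER,
    update_dynamics: bool = True,
) -> StepSolution:
    """Advance one step: iterate conduction-state hypotheses to a fixed point.

    Starts from the previous step's assignment.  On return every conducting
    ideal diode carries non-negative forward current, every blocking diode
    sees non-positive forward bias, and every switch satisfies its
    hysteresis rule at the solved sense potential.  Ties resolve to
    blocking / retain-previous-state.  Raises :class:`ConvergenceError`
    naming the oscillating components if no fixed point is found.
    """
    if isinstance(cc, Netlist):
        cc = compile_circuit(cc)
    st = (state.copy() if state is not None else initial_state(cc))
    t = (st.step_index + 1) * dt if time is None else time
    trap = scheme == "trapezoidal"
    n = cc.n_nodes
    sw_toggled = np.zeros(len(cc.sw_names), np.bool_)
    flippers: set[str] = set()
    x = np.zeros(cc.dim)
    # a switch whose sense potential ended the previous step at/above the
    # upper bound closes now (transition quantized to the step grid)
    for s in range(len(cc.sw_names)):
        if (
            not st.sw_closed[s]
            and st.sense_prev.size
            and st.sense_prev[s] >= cc.sw_vu[s] - _V_TOL
            and t - st.sw_last_open[s] >= cc.sw_toff[s] - 1e-15
        ):
            st.sw_closed[s] = True
            sw_toggled[s] = True
    for _ in range(max_iter):
        G, rhs = assemble_step_system(cc, st, dt, time=t, scheme=scheme)
        x = np.linalg.solve(G, rhs)
        changed = False
        for d in range(cc.dio_branch.size):
            k = cc.dio_branch[d]
            if st.dio_on[d]:
                if x[n + k] < -_I_TOL:
                    st.dio_on[d] = False
                    changed = True
                    flippers.add(cc.dio_names[d])
            else:
                a, b = cc.br_a[k], cc.br_b[k]
                va = x[a] if a >= 0 else 0.0
                vb = x[b] if b >= 0 else 0.0
                if va - vb > _V_TOL:
                    st.dio_on[d] = True
                    changed = True
                    flippers.add(cc.dio_names[d])
        for s in range(len(cc.sw_names)):
            if sw_toggled[s]:
                continue
            vs = x[cc.sw_sense[s]]
            if st.sw_closed[s]:
                if vs <= cc.sw_vl[s] + _V_TOL:
                    st.sw_closed[s] = False
                    st.sw_last_open[s] = t
                    sw_toggled[s] = True
                    changed = True
            else:
                if vs >= cc.sw_vu[s] - _V_TOL and t - st.sw_last_open[s] >= cc.sw_toff[s] - 1e-15:
                    st.sw_closed[s] = True
                    sw_toggled[s] = True
                    changed = True
        for k in range(cc.sh_a.size):
            a, b = cc.sh_a[k], cc.sh_b[k]
            va = x[a] if a >= 0 else 0.0
            vb = x[b] if b >= 0 else 0.0
            vnew = min(va - vb, 1.0)  # limit into the feasible forward region
            if abs(vnew - st.sh_v[k]) > 1e-3:
                st.sh_v[k] = vnew
                changed = True
                flippers.add(cc.sh_names[k])
        if not changed:
            break
    else:
        raise ConvergenceError(
            f"no consistent conduction state at t={t:.6g}s; oscillating: "
            + ", ".join(sorted(flippers))
        )
    if update_dynamics:
        for k in range(cc.cap_a.size):
            a, b = cc.cap_a[k], cc.cap_b[k]
            va = x[a] if a >= 0 else 0.0
            vb = x[b] if b >= 0 else 0.0
            vnew = va - vb
            gc = (2.0 if trap else 1.0) * cc.cap_c[k] / dt
            ieq = gc * st.cap_v[k] + (st.cap_i[k] if trap else 0.0)
            st.cap_i[k] = gc * vnew - ieq
            st.cap_v[k] = vnew
        for s in range(len(cc.sw_names)):
            st.sense_prev[s] = x[cc.sw_sense[s]]
        st.time = t
        st.step_index += 1
        st.node_potentials = {lbl: float(x[i]) for lbl, i in cc.node_index.items()}
    return StepSolution(x=x, state=st, cc=cc)


# ---------------------------------------------------------------------------
# compiled march


@njit(cache=True)
def _march(  # noqa: C901 - hot loop, kept flat on purpose
    dt,
    n_steps,
    start_step,
    trap,
    n_nodes,
    res_a,
    res_b,
    res_ohms,
    cap_a,
    cap_b,
    cap_c,
    cap_v,
    cap_i,
    sh_a,
    sh_b,
    sh_is,
    sh_nvt,
    sh_v,
    br_a,
    br_b,
    br_kind,
    br_val,
    br_sw,
    br_dio,
    pul_branch,
    pul_vmax,
    pul_freq,
    pul_duty,
    pul_phase,
    dio_branch,
    dio_on,
    sw_sense,
    sw_vu,
    sw_vl,
    sw_toff,
    sw_closed,
    sw_last_open,
    sense_prev,
    sched_sw,
    sched_res,
    sched_incr,
    probe_nodes,
    probe_out,
    ev_step,
    ev_sw,
    ev_closed,
    leak_g,
    max_iter,
):
    n = n_nodes
    nb = br_kind.size
    dim = n + nb
    G = np.zeros((dim, dim))
    Ainv = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    gc = np.empty(cap_c.size)
    mult = 2.0 if trap else 1.0
    for k in range(cap_c.size):
        gc[k] = mult * cap_c[k] / dt
    need_rebuild = True
    ainv_valid = False
    n_ev = 0
    sw_toggled = np.zeros(sw_sense.size, np.bool_)
    x = np.zeros(dim)

    for step in range(n_steps):
        t = (start_step + step + 1) * dt
        # lazy factorization: pay for the inverse only once a conduction
        # state persists; freshly rebuilt systems are solved directly
        if not ainv_valid and not need_rebuild:
            Ainv[:, :] = np.linalg.inv(G)
            ainv_valid = True
        # pulse source values (enter the rhs only)
        for p in range(pul_branch.size):
            ph = t * pul_freq[p] + pul_phase[p] / 360.0
            frac = ph % 1.0
            br_val[pul_branch[p]] = pul_vmax[p] if frac < pul_duty[p] else 0.0
        for s in range(sw_sense.size):
            sw_toggled[s] = False
            if (
                not sw_closed[s]
                and sense_prev[s] >= sw_vu[s] - 1e-9
                and t - sw_last_open[s] >= sw_toff[s] - 1e-15
            ):
                sw_closed[s] = True
                sw_toggled[s] = True
                need_rebuild = True
        converged = False
        for _ in range(max_iter):
            if need_rebuild:
                ainv_valid = False
                for i in range(dim):
                    for j in range(dim):
                        G[i, j] = 0.0
                for i in range(n):
                    G[i, i] += leak_g
                for k in range(res_a.size):
                    g = 1.0 / res_ohms[k]
                    a = res_a[k]
                    b = res_b[k]
                    if a >= 0:
                        G[a, a] += g
                    if b >= 0:
                        G[b, b] += g
                    if a >= 0 and b >= 0:
                        G[a, b] -= g
                        G[b, a] -= g
                for k in range(cap_a.size):
                    g = gc[k]
                    a = cap_a[k]
                    b = cap_b[k]
                    if a >= 0:
                        G[a, a] += g
                    if b >= 0:
                        G[b, b] += g
                    if a >= 0 and b >= 0:
                        G[a, b] -= g
                        G[b, a] -= g
                for k in range(sh_a.size):
                    arg = sh_v[k] / sh_nvt[k]
                    if arg > 60.0:
                        arg = 60.0
                    e = np.exp(arg)
                    g = sh_is[k] / sh_nvt[k] * e
                    a = sh_a[k]
                    b = sh_b[k]
                    if a >= 0:
                        G[a, a] += g
                    if b >= 0:
                        G[b, b] += g
                    if a >= 0 and b >= 0:
                        G[a, b] -= g
                        G[b, a] -= g
                for k in range(nb):
                    a = br_a[k]
                    b = br_b[k]
                    row = n + k
                    if a >= 0:
                        G[a, row] += 1.0
                    if b >= 0:
                        G[b, row] -= 1.0
                    kind = br_kind[k]
                    active = True
                    if kind == 2:
                        active = sw_closed[br_sw[k]]
                    elif kind == 3:
                        active = dio_on[br_dio[k]]
                    if active:
                        if a >= 0:
                            G[row, a] += 1.0
                        if b >= 0:
                            G[row, b] -= 1.0
                    else:
                        G[row, row] = 1.0
                need_rebuild = False
            # rhs
            for i in range(dim):
                rhs[i] = 0.0
            for k in range(cap_a.size):
                ieq = gc[k] * cap_v[k]
                if trap:
                    ieq += cap_i[k]
                a = cap_a[k]
                b = cap_b[k]
                if a >= 0:
                    rhs[a] += ieq
                if b >= 0:
                    rhs[b] -= ieq
            for k in range(sh_a.size):
                arg = sh_v[k] / sh_nvt[k]
                if arg > 60.0:
                    arg = 60.0
                e = np.exp(arg)
                g = sh_is[k] / sh_nvt[k] * e
                i0 = sh_is[k] * (e - 1.0)
                ieq = i0 - g * sh_v[k]
                a = sh_a[k]
                b = sh_b[k]
                if a >= 0:
                    rhs[a] -= ieq
                if b >= 0:
                    rhs[b] += ieq
            for k in range(nb):
                kind = br_kind[k]
                active = True
                if kind == 2:
                    active = sw_closed[br_sw[k]]
                elif kind == 3:
                    active = dio_on[br_dio[k]]
                if active:
                    rhs[n + k] = br_val[k]
            if ainv_valid:
                x = Ainv.dot(rhs)
            else:
                x = np.linalg.solve(G, rhs)
            changed = False
            for d in range(dio_branch.size):
                k = dio_branch[d]
                if dio_on[d]:
                    if x[n + k] < -1e-12:
                        dio_on[d] = False
                        changed = True
                else:
                    a = br_a[k]
                    b = br_b[k]
                    va = x[a] if a >= 0 else 0.0
                    vb = x[b] if b >= 0 else 0.0
                    if va - vb > 1e-9:
                        dio_on[d] = True
                        changed = True
            for s in range(sw_sense.size):
                if sw_toggled[s]:
                    continue
                vs = x[sw_sense[s]]
                if sw_closed[s]:
                    if vs <= sw_vl[s] + 1e-9:
                        sw_closed[s] = False
                        sw_last_open[s] = t
                        sw_toggled[s] = True
                        changed = True
                else:
                    if vs >= sw_vu[s] - 1e-9 and t - sw_last_open[s] >= sw_toff[s] - 1e-15:
                        sw_closed[s] = True
                        sw_toggled[s] = True
                        changed = True
            for k in range(sh_a.size):
                a = sh_a[k]
                b = sh_b[k]
                va = x[a] if a >= 0 else 0.0
                vb = x[b] if b >= 0 else 0.0
                vnew = va - vb
                if vnew > 1.0:
                    vnew = 1.0
                if abs(vnew - sh_v[k]) > 1e-3:
                    sh_v[k] = vnew
                    changed = True
            if changed:
                need_rebuild = True
            else:
                converged = True
                break
        if not converged:
            return 1, start_step + step, n_ev
        # accept: update capacitor states
        for k in range(cap_a.size):
            a = cap_a[k]
            b = cap_b[k]
            va = x[a] if a >= 0 else 0.0
            vb = x[b] if b >= 0 else 0.0
            vnew = va - vb
            ieq = gc[k] * cap_v[k]
            if trap:
                ieq += cap_i[k]
            cap_i[k] = gc[k] * vnew - ieq
            cap_v[k] = vnew
        for s in range(sw_sense.size):
            sense_prev[s] = x[sw_sense[s]]
        for j in range(probe_nodes.size):
            probe_out[step, j] = x[probe_nodes[j]]
        for s in range(sw_sense.size):
            if sw_toggled[s]:
                if n_ev >= ev_step.size:
                    return 2, start_step + step, n_ev
                ev_step[n_ev] = start_step + step + 1
                ev_sw[n_ev] = s
                ev_closed[n_ev] = 1 if sw_closed[s] else 0
                n_ev += 1
                if not sw_closed[s]:
                    # per-spike resistance schedules fire on switch opening
                    for q in range(sched_sw.size):
                        if sched_sw[q] == s:
                            res_ohms[sched_res[q]] += sched_incr[q]
                            need_rebuild = True
    return 0, start_step + n_steps, n_ev


# ---------------------------------------------------------------------------
# trace + public runner


@dataclass
class Trace:
    """Output of a transient run: probed potentials on the uniform step grid
    plus the full switch transition log."""

    dt: float
    n_steps: int
    probe_labels: tuple
    potentials: np.ndarray  # (n_steps, n_probes)
    event_steps: np.ndarray  # global step index of each transition
    event_switch: np.ndarray  # index into switch_labels
    event_closed: np.ndarray  # 1 = open->closed, 0 = closed->open
    switch_labels: tuple
    final_state: SimState

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_steps) + 1) * self.dt

    def probe(self, label) -> np.ndarray:
        return self.potentials[:, self.probe_labels.index(label)]

    def transitions(self, switch: str, closed: bool | None = None) -> np.ndarray:
        s = self.switch_labels.index(switch)
        mask = self.event_switch == s
        if closed is not None:
            mask &= self.event_closed == (1 if closed else 0)
        return self.event_steps[mask]

    def save_potentials(self, path) -> None:
        """Delimited text: time_s then one column per probe."""
        header = "time_s\t" + "\t".join(str(p) for p in self.probe_labels)
        data = np.column_stack([self.times, self.potentials])
        np.savetxt(path, data, delimiter="\t", header=header, comments="")

    def save_events(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time_s\tswitch\ttransition\n")
            for st, sw, cl in zip(self.event_steps, self.event_switch, self.event_closed):
                kind = "close" if cl else "open"
                fh.write(f"{st * self.dt:.9g}\t{self.switch_labels[sw]}\t{kind}\n")


def _schedule_arrays(cc: CompiledCircuit, schedules: Sequence) -> tuple:
    sw_idx, res_idx, incr, init = [], [], [], []
    for sch in schedules:
        try:
            r = cc.res_names.index(sch.resistor)
        except ValueError:
            raise NetlistError(f"schedule targets unknown resistor {sch.resistor!r}")
        s = cc.sw_names.index(sch.trigger_switch)
        sw_idx.append(s)
        res_idx.append(r)
        incr.append(float(sch.increment))
        init.append(getattr(sch, "initial", None))
    return (
        np.asarray(sw_idx, np.int64),
        np.asarray(res_idx, np.int64),
        np.asarray(incr, np.float64),
        init,
    )


def run_transient(
    netlist: Netlist | CompiledCircuit,
    duration: float,
    dt: float = 5e-6,
    probes: Sequence = (),
    *,
    scheme: str = "trapezoidal",
    schedules: Sequence = (),
    max_events: int | None = None,
    max_iter: int = MAX_ITER,
) -> Trace:
    """Fixed-step transient march over ``duration`` seconds.

    Records the probed node potentials at every step and all switch
    transition times.  Bit-reproducible: the simulation itself is seed-free
    and deterministic in the netlist, duration and dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration <= dt:
        raise ValueError("duration must exceed dt")
    if scheme not in ("trapezoidal", "backward_euler"):
        raise ValueError(f"unknown scheme {scheme!r}")
    cc = netlist if isinstance(netlist, CompiledCircuit) else compile_circuit(netlist)
    st = initial_state(cc)
    n_steps = int(round(duration / dt))
    probe_nodes = np.asarray([cc.node_index[p] for p in probes], np.int64)
    sched_sw, sched_res, sched_incr, sched_init = _schedule_arrays(cc, schedules)

    if max_events is None:
        # generous default: up to ~2 kHz of transitions per switch
        max_events = min(int(4000 * duration) * max(1, len(cc.sw_names)) + 10_000, 50_000_000)
    for _attempt in range(3):
        probe_out = np.zeros((n_steps, probe_nodes.size))
        ev_step = np.zeros(max_events, np.int64)
        ev_sw = np.zeros(max_events, np.int64)
        ev_closed = np.zeros(max_events, np.int8)
        run_st = st.copy()
        res_ohms = cc.res_ohms.copy()
        for r, v0 in zip(sched_res, sched_init):
            if v0 is not None:
                res_ohms[r] = float(v0)
        code, info, n_ev = _march(
            dt,
            n_steps,
            0,
            scheme == "trapezoidal",
            cc.n_nodes,
            cc.res_a,
            cc.res_b,
            res_ohms,
            cc.cap_a,
            cc.cap_b,
            cc.cap_c,
            run_st.cap_v,
            run_st.cap_i,
            cc.sh_a,
            cc.sh_b,
            cc.sh_is,
            cc.sh_nvt,
            run_st.sh_v,
            cc.br_a,
            cc.br_b,
            cc.br_kind,
            cc.br_val.copy(),
            _branch_switch_map(cc),
            _branch_diode_map(cc),
            cc.pul_branch,
            cc.pul_vmax,
            cc.pul_freq,
            cc.pul_duty,
            cc.pul_phase,
            cc.dio_branch,
            run_st.dio_on,
            cc.sw_sense,
            cc.sw_vu,
            cc.sw_vl,
            cc.sw_toff,
            run_st.sw_closed,
            run_st.sw_last_open,
            run_st.sense_prev,
            sched_sw,
            sched_res,
            sched_incr,
            probe_nodes,
            probe_out,
            ev_step,
            ev_sw,
            ev_closed,
            LEAK_G,
            max_iter,
        )
        if code == 2:
            max_events *= 4
            continue
        break
    if code == 1:
        raise ConvergenceError(
            f"no consistent conduction-state assignment at step {info} (t={info * dt:.6g}s)"
        )
    if code == 2:
        raise RuntimeError("switch event buffer overflow; pass a larger max_events")
    run_st.time = n_steps * dt
    run_st.step_index = n_steps
    return Trace(
        dt=dt,
        n_steps=n_steps,
        probe_labels=tuple(probes),
        potentials=probe_out,
        event_steps=ev_step[:n_ev].copy(),
        event_switch=ev_sw[:n_ev].copy(),
        event_closed=ev_closed[:n_ev].copy(),
        switch_labels=tuple(cc.sw_names),
        final_state=run_st,
    )


def _branch_switch_map(cc: CompiledCircuit) -> np.ndarray:
    m = np.full(cc.n_branches, -1, np.int64)
    for pb, ps in zip(cc.pole_branch, cc.pole_sw):
        m[pb] = ps
    return m


def _branch_diode_map(cc: CompiledCircuit) -> np.ndarray:
    m = np.full(cc.n_branches, -1, np.int64)
    for d, k in enumerate(cc.dio_branch):
        m[k] = d
    return m
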