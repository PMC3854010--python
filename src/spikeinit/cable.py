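"""Compartmental ball-and-stick cable simulator.

The soma is one isopotential lumped compartment (node 0); the axon is a chain
of nodes at multiples of dx with sealed (zero-flux) distal end.  Axial
coupling conductances come from the exact segment resistances (including the
tapered hillock), so the discrete soma→x resistance matches the closed form
at every node.  Integration is backward Euler on the tridiagonal system with
gating advanced by an exact exponential step (see ``_kernels``).

Voltage clamp is realized by row substitution (a Dirichlet node at the soma),
so the somatic row of the solution equals the command exactly at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .core import (
    LinearDecreasingProfile,
    NeuronSpec,
    PointProfile,
    UniformProfile,
    axial_resistance,
    somatic_capacitance,
    somatic_leak_conductance,
)
from .stimuli import VoltageSchedule

__all__ = [
    "Discretization",
    "Compartments",
    "State",
    "ResetRule",
    "SimulationTrace",
    "SteadyState",
    "build_compartments",
    "initial_state",
    "simulate_vclamp",
    "simulate_iclamp",
    "run_to_steady",
    "steady_state_profile",
    "net_currents",
]


@dataclass(frozen=True)
class Discretization:
    """Spatial and temporal resolution: dx = 1 µm, dt = 0.025 ms by default."""

    dx: float = 1.0
    dt: float = 0.025

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")


@dataclass(frozen=True)
class ResetRule:
    """Spike-and-reset rule for current clamp: when the conductance-weighted
    open fraction reaches ``threshold``, reset all compartments to the leak
    reversal and clamp there for ``hold`` ms."""

    threshold: float = 0.5
    hold: float = 5.0


@dataclass
class Compartments:
    """Per-node electrical quantities of the discretized neuron (arrays)."""

    x: np.ndarray          # node positions, µm (0 = soma)
    C: np.ndarray          # pF
    gL: np.ndarray         # nS
    gax: np.ndarray        # nS, coupling node i <-> i+1
    E_L: float
    # flat channel entries
    ch_set: np.ndarray     # int, channel-set index of each entry
    ch_node: np.ndarray    # int, node index
    ch_g: np.ndarray       # nS, maximal conductance of the entry
    ch_vh: np.ndarray
    ch_ka: np.ndarray
    ch_ena: np.ndarray
    ch_taum: np.ndarray
    set_names: tuple[str, ...]
    spec: NeuronSpec = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def n_sets(self) -> int:
        return len(self.set_names)

    def g_total_per_set(self) -> np.ndarray:
        out = np.zeros(self.n_sets)
        np.add.at(out, self.ch_set, self.ch_g)
        return out


@dataclass
class State:
    V: np.ndarray
    m: np.ndarray

    def copy(self) -> "State":
        return State(self.V.copy(), self.m.copy())


@dataclass
class SteadyState:
    V: np.ndarray
    m: np.ndarray
    converged: bool
    elapsed: float  # ms

    def require_converged(self) -> "SteadyState":
        if not self.converged:
            raise RuntimeError(
                "steady state not reached within the time cap "
                f"({self.elapsed:.1f} ms); system may be near a bifurcation"
            )
        return self


@dataclass
class SimulationTrace:
    """Recorded time course of a simulation.

    ``V`` has one column per entry of ``positions``; ``open_fraction`` one
    column per channel set (conductance-weighted mean of m).  ``current`` is
    the somatic clamp current (voltage clamp) or the injected current
    (current clamp), in pA.  ``spike_times`` is populated when a reset rule
    was active.
    """

    times: np.ndarray
    positions: np.ndarray
    V: np.ndarray
    open_fraction: np.ndarray
    set_names: tuple[str, ...]
    current: np.ndarray
    mode: str
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def voltage_at(self, position: float) -> np.ndarray:
        j = int(np.argmin(np.abs(self.positions - position)))
        return self.V[:, j]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time, position, V) plus open fractions."""
        T, P = self.V.shape
        df = pd.DataFrame(
            {
                "time_ms": np.repeat(self.times, P),
                "position_um": np.tile(self.positions, T),
                "V_mV": self.V.ravel(),
            }
        )
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# building
# ---------------------------------------------------------------------------

def _allocate_profile(profile, nodes_x: np.ndarray, dx: float, g_total: float):
    """Distribute g_total over axon nodes according to the density profile.

    Returns (node_indices, conductances).  A point cluster is split linearly
    between the two bracketing nodes so the effective axial resistance matches
    the requested location even off-grid; interval profiles weight each node
    by the density integrated over its dx cell and are renormalized so the
    sum is exactly g_total.
    """
    if isinstance(profile, PointProfile):
        xq = profile.x
        i = int(np.floor(xq / dx + 1e-9))
        lo = i * dx
        w = (xq - lo) / dx
        if w < 1e-9 or i + 1 >= nodes_x.size:
            return np.array([i]), np.array([g_total])
        return np.array([i, i + 1]), g_total * np.array([1.0 - w, w])

    x1, x2 = profile.bounds()
    idx, wts = [], []
    for i in range(1, nodes_x.size):  # axonal nodes only
        a = nodes_x[i] - dx / 2.0
        b = nodes_x[i] + dx / 2.0
        a2, b2 = max(a, x1), min(b, x2)
        if b2 <= a2:
            continue
        if isinstance(profile, UniformProfile):
            w = b2 - a2
        elif isinstance(profile, LinearDecreasingProfile):
            # density ∝ (x2 − s): integrate over the overlap
            w = ((x2 - a2) ** 2 - (x2 - b2) ** 2) / 2.0
        else:
            raise TypeError(f"unknown profile {profile!r}")
        if w > 0:
            idx.append(i)
            wts.append(w)
    wts = np.asarray(wts, dtype=float)
    return np.asarray(idx), g_total * wts / wts.sum()


def build_compartments(spec: NeuronSpec, disc: Discretization) -> Compartments:
    """Discretize the neuron: soma node + axon nodes every dx µm."""
    geo = spec.geometry
    pas = spec.passive
    n_ax = int(round(geo.axon_length / disc.dx))
    x = np.concatenate([[0.0], disc.dx * np.arange(1, n_ax + 1)])
    n = x.size

    area = np.empty(n)  # cm²
    area[0] = 4.0 * np.pi * (geo.soma_diameter / 2.0) ** 2 * 1e-8
    for i in range(1, n):
        area[i] = np.pi * geo.diameter_at(x[i]) * disc.dx * 1e-8
    C = area * pas.C_m * 1e6          # pF
    gL = area / pas.R_m * 1e9         # nS

    # exact segment resistances -> coupling conductances
    R_cum = np.array([axial_resistance(spec, xi) for xi in x])  # MΩ
    gax = 1e3 / np.diff(R_cum)        # nS

    ch_set, ch_node, ch_g = [], [], []
    ch_vh, ch_ka, ch_ena, ch_taum = [], [], [], []
    names = []
    for s, ch in enumerate(spec.channel_sets):
        names.append(ch.name)
        idx, g = _allocate_profile(ch.profile, x, disc.dx, ch.g_total)
        for i, gi in zip(idx, g):
            ch_set.append(s)
            ch_node.append(int(i))
            ch_g.append(float(gi))
            ch_vh.append(ch.V_half)
            ch_ka.append(ch.k_a)
            ch_ena.append(ch.E_Na)
            ch_taum.append(ch.tau_m)

    return Compartments(
        x=x,
        C=C,
        gL=gL,
        gax=gax,
        E_L=pas.E_L,
        ch_set=np.asarray(ch_set, dtype=np.int64),
        ch_node=np.asarray(ch_node, dtype=np.int64),
        ch_g=np.asarray(ch_g, dtype=float),
        ch_vh=np.asarray(ch_vh, dtype=float),
        ch_ka=np.asarray(ch_ka, dtype=float),
        ch_ena=np.asarray(ch_ena, dtype=float),
        ch_taum=np.asarray(ch_taum, dtype=float),
        set_names=tuple(names),
        spec=spec,
    )


def initial_state(comp: Compartments, V0: Optional[float] = None) -> State:
    """Rest state: uniform voltage (default E_L) with m at its steady value."""
    if V0 is None:
        V0 = comp.E_L
    V = np.full(comp.n, float(V0))
    m = 1.0 / (1.0 + np.exp((comp.ch_vh - V0) / comp.ch_ka))
    return State(V=V, m=m)


def _kernel_args(comp: Compartments, dt: float):
    ch_em = np.exp(-dt / comp.ch_taum)
    return (
        dt, comp.C, comp.gL, comp.E_L, comp.gax,
        comp.ch_node, comp.ch_vh, comp.ch_ka, ch_em,
        comp.ch_g, comp.ch_ena,
    )


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def simulate_vclamp(
    spec: NeuronSpec,
    disc: Discretization,
    command: VoltageSchedule | np.ndarray,
    record_every: int = 1,
    state: Optional[State] = None,
    comp: Optional[Compartments] = None,
) -> SimulationTrace:
    """Integrate under a somatic voltage-clamp command.

    ``command`` is a VoltageSchedule or an array with one level per dt step.
    The recorded current is the total current the clamp must supply.
    """
    comp = comp or build_compartments(spec, disc)
    vcmd = command.as_array(disc.dt) if isinstance(command, VoltageSchedule) else np.asarray(command, dtype=float)
    st = state or initial_state(comp)
    n_rec = (vcmd.size + record_every - 1) // record_every
    V_rec = np.empty((n_rec, comp.n))
    frac_rec = np.empty((n_rec, max(comp.n_sets, 1)))
    I_rec = np.empty(n_rec)
    status = _kernels.run_vclamp(
        st.V, st.m, *_kernel_args(comp, disc.dt),
        comp.ch_set, comp.n_sets, vcmd, record_every, V_rec, frac_rec, I_rec,
    )
    if status != 0:
        raise RuntimeError("numeric blow-up in voltage-clamp simulation")
    times = disc.dt * record_every * np.arange(n_rec)
    return SimulationTrace(
        times=times,
        positions=comp.x,
        V=V_rec,
        open_fraction=frac_rec[:, : comp.n_sets],
        set_names=comp.set_names,
        current=I_rec,
        mode="vclamp",
        meta={"dt": disc.dt, "dx": disc.dx, "record_every": record_every},
    )


def simulate_iclamp(
    spec: NeuronSpec,
    disc: Discretization,
    I_inj: np.ndarray,
    reset_rule: Optional[ResetRule] = None,
    record_every: int = 1,
    record_positions: Optional[Sequence[float]] = None,
    state: Optional[State] = None,
    comp: Optional[Compartments] = None,
) -> SimulationTrace:
    """Integrate under somatic current clamp (``I_inj`` in pA, one per step).

    With a :class:`ResetRule` the trace's ``spike_times`` log the threshold
    crossings and ``meta['mean_na_current']`` holds the time-averaged total Na
    current (pA) over the simulation excluding the post-spike clamp windows.
    """
    comp = comp or build_compartments(spec, disc)
    I_inj = np.asarray(I_inj, dtype=float)
    st = state or initial_state(comp)
    if record_positions is None:
        rec_pos = np.arange(comp.n, dtype=np.int64)
    else:
        rec_pos = np.asarray(
            [int(np.argmin(np.abs(comp.x - p))) for p in record_positions],
            dtype=np.int64,
        )
    n_rec = (I_inj.size + record_every - 1) // record_every
    V_rec = np.empty((n_rec, rec_pos.size))
    frac_rec = np.empty((n_rec, max(comp.n_sets, 1)))
    spike_steps = np.full(1_000_000, -1, dtype=np.int64)
    na_sum = np.zeros(2)
    use_reset = reset_rule is not None
    thr = reset_rule.threshold if use_reset else 1.1
    hold_steps = int(round((reset_rule.hold if use_reset else 0.0) / disc.dt))
    n_spikes, status = _kernels.run_iclamp(
        st.V, st.m, *_kernel_args(comp, disc.dt),
        comp.ch_set, comp.n_sets, I_inj, use_reset, thr, hold_steps,
        record_every, rec_pos, V_rec, frac_rec, spike_steps, na_sum,
    )
    if status != 0:
        raise RuntimeError("numeric blow-up in current-clamp simulation")
    times = disc.dt * record_every * np.arange(n_rec)
    spike_times = disc.dt * spike_steps[:n_spikes].astype(float)
    return SimulationTrace(
        times=times,
        positions=comp.x[rec_pos],
        V=V_rec,
        open_fraction=frac_rec[:, : comp.n_sets],
        set_names=comp.set_names,
        current=I_inj[::record_every][:n_rec],
        mode="iclamp",
        spike_times=spike_times,
        meta={
            "dt": disc.dt,
            "dx": disc.dx,
            "record_every": record_every,
            "mean_na_current": na_sum[0] / na_sum[1] if na_sum[1] > 0 else np.nan,
        },
    )


def run_to_steady(
    comp: Compartments,
    state: State,
    V_cmd: float,
    disc: Discretization,
    tol: float = 1e-4,
    sustain: float = 1.0,
    cap: float = 200.0,
) -> SteadyState:
    """Hold the somatic clamp at ``V_cmd`` until the axon settles.

    Convergence requires max |dV/dt| < ``tol`` mV/ms across free nodes,
    sustained for ``sustain`` ms, within a cap of ``cap`` ms; a hit cap is
    reported via ``converged=False`` (near a fold, relaxation critically
    slows and the cap state is the honest answer), never silently.
    """
    steps, converged, blown = _kernels.run_to_steady(
        state.V, state.m, *_kernel_args(comp, disc.dt),
        V_cmd, tol, int(round(sustain / disc.dt)), int(round(cap / disc.dt)),
    )
    if blown:
        raise RuntimeError("numeric blow-up while relaxing to steady state")
    return SteadyState(
        V=state.V, m=state.m, converged=bool(converged), elapsed=steps * disc.dt
    )


def steady_state_profile(
    spec: NeuronSpec,
    disc: Discretization,
    V_s: float,
    state: Optional[State] = None,
    comp: Optional[Compartments] = None,
    **steady_kwargs,
) -> tuple[np.ndarray, SteadyState]:
    """Steady spatial voltage profile with the soma clamped at ``V_s``.

    Starting from rest (or a supplied state, e.g. the previous level of a
    quasi-static upward sweep — the branch reached from below defines the
    reported profile in bistable regimes).  Returns (positions are
    ``comp.x``): the voltage profile and the full SteadyState.
    """
    comp = comp or build_compartments(spec, disc)
    st = state or initial_state(comp)
    ss = run_to_steady(comp, st, V_s, disc, **steady_kwargs)
    return ss.V.copy(), ss


def net_currents(comp: Compartments, state: State) -> np.ndarray:
    """Net membrane+axial current into every node (pA); ≈0 at steady state.

    Uses m at its instantaneous value (at a true steady state m = m_inf(V)).
    Node 0 is excluded from steady-state checks under clamp (the clamp
    supplies its balance).
    """
    V, m = state.V, state.m
    I = -comp.gL * (V - comp.E_L)
    np.add.at(
        I, comp.ch_node, comp.ch_g * m * (comp.ch_ena - V[comp.ch_node])
    )
    ax = comp.gax * np.diff(V)  # current flowing from node i+1 toward i? sign:
    # positive ax[i] = current from node i to i+1 is gax*(V[i]-V[i+1]) = -ax[i]
    I[:-1] += ax
    I[1:] -= ax
    return I
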