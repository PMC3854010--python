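"""Summary measurements on simulated traces and steady-state sweeps.

These operations turn raw cable simulations into the quantities the analysis
is about: somatic I–V curves and their minimum V_T, the activation-vs-somatic-
voltage curve and its 27%→73% half-width (the sharpness of spike initiation),
phase plots (dV/dt vs V) with the onset-rapidness and kink measures, and the
effective-location rule for distributed channel profiles.

Sharpness sweeps use adaptive bisection on the clamp level to locate the
27/50/73% crossings: each evaluation relaxes the neuron from rest to steady
state under somatic voltage clamp, which follows the branch reached from
below (the quasi-static upward sweep of the step protocol).  Uniform grids
cannot reach the sub-0.1 mV regime at sane cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cable import (
    Compartments,
    Discretization,
    SimulationTrace,
    build_compartments,
    initial_state,
    run_to_steady,
)
from .core import NeuronSpec

__all__ = [
    "IVCurve",
    "SharpnessResult",
    "PhasePlot",
    "open_fraction_at",
    "iv_curve",
    "activation_sharpness",
    "phase_plot",
    "onset_rapidness",
    "kink_jump",
    "effective_location",
    "profile_concavity",
]


# ---------------------------------------------------------------------------
# steady-state voltage-clamp measurements
# ---------------------------------------------------------------------------

def open_fraction_at(
    comp: Compartments,
    V_s: float,
    disc: Discretization,
    channel_index: Optional[int] = None,
    **steady_kwargs,
) -> float:
    """Conductance-weighted open Na fraction at the steady state reached from
    rest with the soma clamped at ``V_s``.

    Starting from rest selects the branch a quasi-static upward sweep would
    follow (below the unstable root the system relaxes to the resting branch;
    past the fold only the depolarized branch remains).
    """
    st = initial_state(comp)
    run_to_steady(comp, st, V_s, disc, **steady_kwargs)
    if channel_index is None:
        mask = np.ones(comp.ch_g.size, dtype=bool)
    else:
        mask = comp.ch_set == channel_index
    g = comp.ch_g[mask]
    return float(np.sum(g * st.m[mask]) / np.sum(g))


@dataclass
class IVCurve:
    """Steady-state somatic I–V relationship under voltage clamp.

    ``I`` is the net depolarizing (inward-positive) current the soma
    receives, i.e. minus the clamp holding current: zero at the leak
    reversal, dipping to a minimum at V_T — the largest voltage a constant
    current injection can hold without triggering a spike — and rising
    steeply beyond as the axonal Na current takes over.
    """

    V: np.ndarray          # command voltages, mV
    I: np.ndarray          # inward-positive steady currents, pA
    V_T: Optional[float]   # voltage at the interior minimum (quadratic refined)
    has_minimum: bool
    diagnostics: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"V_mV": self.V, "I_pA": self.I})


def iv_curve(
    spec: NeuronSpec,
    disc: Discretization,
    v_grid: Sequence[float],
    comp: Optional[Compartments] = None,
    **steady_kwargs,
) -> IVCurve:
    """Quasi-static upward sweep of the somatic clamp: steady current per level.

    Each level starts from the previous level's state (continuation), matching
    a step-ladder protocol.  ``V_T`` is the location of the interior minimum,
    refined by a local quadratic fit through the three bracketing points.
    """
    comp = comp or build_compartments(spec, disc)
    v_grid = np.asarray(sorted(v_grid), dtype=float)
    st = initial_state(comp)
    I = np.empty(v_grid.size)
    from ._kernels import _clamp_current

    for j, v in enumerate(v_grid):
        run_to_steady(comp, st, float(v), disc, **steady_kwargs)
        # inward-positive membrane current = minus the clamp holding current
        I[j] = -_clamp_current(st.V, st.m, comp.gL, comp.E_L, comp.gax,
                               comp.ch_node, comp.ch_g, comp.ch_ena)
    i = int(np.argmin(I))
    if i == 0 or i == v_grid.size - 1:
        return IVCurve(V=v_grid, I=I, V_T=None, has_minimum=False,
                       diagnostics="no interior minimum in the scanned range")
    # quadratic refinement of the minimum location
    x0, x1, x2 = v_grid[i - 1: i + 2]
    y0, y1, y2 = I[i - 1: i + 2]
    denom = (y0 - 2 * y1 + y2)
    if denom <= 0:
        V_T = float(v_grid[i])
    else:
        V_T = float(x1 + 0.5 * (y0 - y2) / denom * (x2 - x1))
    return IVCurve(V=v_grid, I=I, V_T=V_T, has_minimum=True)


@dataclass
class SharpnessResult:
    """Sharpness of spike initiation from the activation-vs-V_s curve.

    ``half_width`` = (V_s@73% − V_s@27%)/2; ``threshold_half`` = V_s at 50%
    open.  When the steady-state curve is discontinuous (supercritical
    coupling) both landmarks collapse onto the fold and ``half_width`` is
    only an upper bound set by the bisection resolution (``discontinuous``
    is then True).
    """

    curve: pd.DataFrame
    half_width: float
    threshold_half: float
    V_27: float
    V_73: float
    resolution: float
    discontinuous: bool
    per_set_threshold_half: dict = field(default_factory=dict)


def _bisect_crossing(F, target: float, lo: float, hi: float, f_lo: float,
                     f_hi: float, xtol: float, evals: list) -> float:
    """Locate V where the non-decreasing sweep F crosses ``target``."""
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        f_mid = F(mid)
        evals.append((mid, f_mid))
        if f_mid < target:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)


def activation_sharpness(
    spec: NeuronSpec,
    disc: Discretization,
    resolution: float = 0.01,
    v_lo: Optional[float] = None,
    v_hi: Optional[float] = None,
    coarse_step: float = 1.0,
    comp: Optional[Compartments] = None,
    channel_index: Optional[int] = None,
    **steady_kwargs,
) -> SharpnessResult:
    """Measure the 27%→73% half-width of Na activation vs somatic voltage.

    A coarse upward scan brackets the transition, then adaptive bisection
    resolves the 27%, 50% and 73% crossings to ``resolution`` mV.  The
    aggregate open fraction weights m by per-entry maximal conductance across
    all channel sets (or one set via ``channel_index``).
    """
    comp = comp or build_compartments(spec, disc)
    if comp.ch_g.size == 0:
        raise ValueError("neuron has no Na channels; sharpness undefined")
    ch0 = spec.channel_sets[0]
    if v_lo is None:
        v_lo = spec.passive.E_L
    if v_hi is None:
        v_hi = ch0.V_half + 4.0 * ch0.k_a

    evals: list[tuple[float, float]] = []

    def F(v: float) -> float:
        f = open_fraction_at(comp, v, disc, channel_index=channel_index,
                             **steady_kwargs)
        return f

    # coarse upward scan to bracket the 27% and 73% crossings
    vs = np.arange(v_lo, v_hi + coarse_step, coarse_step)
    fs = []
    for v in vs:
        f = F(float(v))
        evals.append((float(v), f))
        fs.append(f)
        if f >= 0.73:
            break
    fs = np.asarray(fs)
    if fs[-1] < 0.73 or fs[0] > 0.27:
        raise RuntimeError(
            "activation transition not bracketed by the scan range; "
            f"open fraction spans [{fs.min():.3f}, {fs.max():.3f}]"
        )
    vs = vs[: fs.size]

    def bracket(target: float) -> tuple[float, float, float, float]:
        k = int(np.argmax(fs >= target))
        return float(vs[k - 1]), float(vs[k]), float(fs[k - 1]), float(fs[k])

    V_27 = _bisect_crossing(F, 0.27, *bracket(0.27), resolution, evals)
    V_50 = _bisect_crossing(F, 0.50, *bracket(0.50), resolution, evals)
    V_73 = _bisect_crossing(F, 0.73, *bracket(0.73), resolution, evals)

    half_width = max((V_73 - V_27) / 2.0, 0.0)
    discontinuous = (V_73 - V_27) <= 2.0 * resolution

    per_set = {}
    if comp.n_sets > 1 and channel_index is None:
        for s, name in enumerate(comp.set_names):
            sub = activation_sharpness(
                spec, disc, resolution=resolution, v_lo=v_lo, v_hi=v_hi,
                coarse_step=coarse_step, comp=comp, channel_index=s,
                **steady_kwargs,
            )
            per_set[name] = sub.threshold_half

    curve = pd.DataFrame(sorted(evals), columns=["V_s", "open_fraction"])
    return SharpnessResult(
        curve=curve,
        half_width=half_width,
        threshold_half=V_50,
        V_27=V_27,
        V_73=V_73,
        resolution=resolution,
        discontinuous=discontinuous,
        per_set_threshold_half=per_set,
    )


# ---------------------------------------------------------------------------
# phase-plane measurements
# ---------------------------------------------------------------------------

@dataclass
class PhasePlot:
    """dV/dt vs V at one position, from centered differences (no smoothing —
    the kink is the signal)."""

    t: np.ndarray
    V: np.ndarray
    dVdt: np.ndarray
    position: float
    diagnostics: str = ""

    @property
    def empty(self) -> bool:
        return self.V.size == 0


def phase_plot(trace: SimulationTrace, position: float,
               require_spike: bool = True) -> PhasePlot:
    """Centered-difference phase plot at the recorded position nearest ``position``.

    With ``require_spike`` (default), a trace in which the aggregate open
    fraction never reaches 50% yields an empty curve with a diagnostic.
    """
    j = int(np.argmin(np.abs(trace.positions - position)))
    pos = float(trace.positions[j])
    if require_spike and (
        trace.open_fraction.size == 0 or trace.open_fraction.max() < 0.5
    ):
        return PhasePlot(
            t=np.empty(0), V=np.empty(0), dVdt=np.empty(0), position=pos,
            diagnostics="no spike in trace (open fraction stayed below 50%)",
        )
    V = trace.V[:, j]
    dt = float(trace.times[1] - trace.times[0])
    dVdt = np.empty_like(V)
    dVdt[1:-1] = (V[2:] - V[:-2]) / (2.0 * dt)
    dVdt[0] = (V[1] - V[0]) / dt
    dVdt[-1] = (V[-1] - V[-2]) / dt
    return PhasePlot(t=trace.times.copy(), V=V.copy(), dVdt=dVdt, position=pos)


def onset_rapidness(phase: PhasePlot, alpha: float = 10.0,
                    band: float = 1.0) -> Optional[float]:
    """Slope (ms⁻¹) of the phase trajectory where dV/dt first reaches ``alpha``.

    Least-squares slope of dV/dt vs V over the contiguous rising samples with
    dV/dt within ±``band`` mV/ms of the first upward alpha crossing; when the
    rise is so steep that the band holds a single sample, the two-point secant
    across the crossing is used.  Returns None (with no side effects) if the
    trajectory never reaches alpha.
    """
    if phase.empty:
        return None
    above = np.nonzero(phase.dVdt >= alpha)[0]
    if above.size == 0:
        return None
    k = int(above[0])
    if k == 0:
        return None
    lo = k
    while lo > 0 and phase.dVdt[lo - 1] >= alpha - band and phase.dVdt[lo - 1] <= phase.dVdt[lo]:
        lo -= 1
    hi = k
    while hi + 1 < phase.dVdt.size and phase.dVdt[hi + 1] <= alpha + band and phase.dVdt[hi + 1] >= phase.dVdt[hi]:
        hi += 1
    x, y = phase.V[lo: hi + 1], phase.dVdt[lo: hi + 1]
    if x.size < 2 or np.ptp(x) == 0:
        x, y = phase.V[k - 1: k + 1], phase.dVdt[k - 1: k + 1]
        if np.ptp(x) == 0:
            return None
        return float((y[1] - y[0]) / (x[1] - x[0]))
    A = np.vstack([x, np.ones_like(x)]).T
    slope, _ = np.linalg.lstsq(A, y, rcond=None)[0]
    return float(slope)


@dataclass
class KinkMeasure:
    """The abrupt dV/dt transition at spike onset.

    ``level`` is the dV/dt value at the top of the near-vertical segment of
    the phase plot (the derivative the lateral-current step drives the soma
    to); ``pre`` the baseline just before the segment; ``jump`` their
    difference.  With a just-suprathreshold pulse the baseline is small and
    level ≈ jump.
    """

    jump: float
    level: float
    pre: float
    t_peak: float


def kink_jump(phase: PhasePlot, window: Optional[tuple[float, float]] = None,
              pre_window: float = 3.0) -> Optional[KinkMeasure]:
    """Measure the abrupt dV/dt increase at spike onset (mV/ms).

    The transition top is the dV/dt peak inside ``window`` (a (t0, t1)
    interval in ms, e.g. bracketing the moment the axonal channels open;
    whole trace by default); the baseline is the dV/dt minimum over the
    ``pre_window`` ms immediately preceding it.

    The peak is the *first* prominent local maximum of dV/dt inside the
    window (rising above the window-start baseline by a quarter of the full
    excursion), so that later accelerations — e.g. a somatic Na spike riding
    on top of the axonal kink — do not contaminate the initial-kink measure.
    """
    if phase.empty or phase.dVdt.size < 5:
        return None
    mask = np.ones(phase.t.size, dtype=bool)
    if window is not None:
        mask = (phase.t >= window[0]) & (phase.t <= window[1])
        if not mask.any():
            return None
    idx = np.nonzero(mask)[0]
    dv = phase.dVdt
    baseline = dv[idx[0]]
    excursion = dv[idx].max() - baseline
    if excursion <= 0:
        return None
    thresh = baseline + 0.25 * excursion
    look = max(1, int(round(0.2 / (phase.t[1] - phase.t[0]))))  # 0.2 ms lookahead
    ipeak = idx[int(np.argmax(dv[idx]))]
    for i in idx[1:]:
        if dv[i] >= thresh and i + 1 < dv.size:
            ahead = dv[i + 1: min(i + 1 + look, dv.size)]
            if ahead.size and dv[i] >= ahead.max():
                ipeak = i
                break
    pre_mask = (phase.t >= phase.t[ipeak] - pre_window) & (phase.t < phase.t[ipeak])
    if not pre_mask.any():
        return None
    pre = float(dv[pre_mask].min())
    return KinkMeasure(jump=float(dv[ipeak]) - pre, level=float(dv[ipeak]),
                       pre=pre, t_peak=float(phase.t[ipeak]))


# ---------------------------------------------------------------------------
# distributed channels
# ---------------------------------------------------------------------------

def effective_location(x1: float, x2: float) -> float:
    """Single 'effective' clustering point of channels spread on [x1, x2]:
    0.6·x1 + 0.4·x2 (empirical at the standard parameter point)."""
    if x1 > x2:
        raise ValueError("need x1 <= x2")
    return 0.6 * x1 + 0.4 * x2


def profile_concavity(
    x: np.ndarray, V: np.ndarray, region: tuple[float, float],
    tol: float = 1e-6,
) -> tuple[bool, float, float]:
    """Check concavity of a steady suprathreshold voltage profile.

    Returns (is_concave, max_violation, peak_position): the discrete second
    difference must be ≤ tol over the channel-bearing ``region`` and the
    maximum depolarization must sit at the distal end of that region.
    """
    x = np.asarray(x)
    V = np.asarray(V)
    d2 = V[2:] - 2 * V[1:-1] + V[:-2]
    inner = x[1:-1]
    mask = (inner >= region[0]) & (inner <= region[1])
    violation = float(d2[mask].max()) if mask.any() else 0.0
    peak = float(x[np.argmax(V)])
    return violation <= tol, violation, peak
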