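"""Reduced two-point model of spike initiation and its bifurcation analysis.

The initiation site (voltage V_a, carrying the whole Na conductance) is coupled
to the soma (voltage V_s, treated as a voltage source because the large soma
acts as a current sink) through the axial resistance R_a.  At any moment the
lateral current equals the Na current, which gives the scalar fixed-point
("current") equation

    (V_a − V_s) / R_a = f(V_a),        f(V) = g_Na · m_inf(V) · (E_Na − V).

When R_a·g_Na exceeds a critical product (~0.27 for the standard Nav1.6
parameters) this equation undergoes a fold bifurcation as V_s is raised: the
resting root collides with the unstable middle root and V_a jumps
discontinuously to the depolarized branch.  That fold defines the somatic
spike threshold, and its existence is what makes spike initiation all-or-none
as a function of somatic voltage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .core import (
    NaChannelSet,
    NeuronSpec,
    axial_resistance,
    equivalent_cylinder_extension,
    m_inf,
    na_current,
    na_current_slope,
    somatic_capacitance,
)

__all__ = [
    "ReducedModel",
    "Root",
    "FoldResult",
    "FixedPointDiagram",
    "reduced_from_spec",
    "solve_fixed_points",
    "fold_threshold",
    "critical_coupling",
    "critical_distance",
    "threshold_vs_distance",
    "kink_rate",
    "onset_rapidness_theory",
    "reduced_activation_curve",
    "fixed_point_diagram",
]

_MOHM_TO_GOHM = 1e-3


@dataclass(frozen=True)
class ReducedModel:
    """Initiation site coupled to the soma through an axial resistance.

    R_a in MΩ, C_soma in pF (only used by :func:`kink_rate`).
    """

    R_a: float
    channels: NaChannelSet
    C_soma: float = 58.905

    def __post_init__(self) -> None:
        if self.R_a < 0:
            raise ValueError("R_a must be non-negative")
        if self.C_soma <= 0:
            raise ValueError("C_soma must be positive")

    @property
    def coupling_product(self) -> float:
        """Dimensionless R_a·g_Na."""
        return self.R_a * _MOHM_TO_GOHM * self.channels.g_total


def reduced_from_spec(spec: NeuronSpec, x: float, channel_index: int = 0) -> ReducedModel:
    """Reduced model for initiation site at ``x`` µm on a given neuron."""
    return ReducedModel(
        R_a=axial_resistance(spec, x),
        channels=spec.channel_sets[channel_index],
        C_soma=somatic_capacitance(spec),
    )


@dataclass(frozen=True)
class Root:
    V_a: float
    stable: bool


def _residual(V, V_s: float, model: ReducedModel):
    """Current-balance residual (V−V_s)/R_a − f(V), in pA (R_a in GΩ → nA·1e3)."""
    Ra_G = model.R_a * _MOHM_TO_GOHM
    return (np.asarray(V) - V_s) / Ra_G - na_current(V, model.channels)


def solve_fixed_points(
    model: ReducedModel, V_s: float, grid_step: float = 0.01
) -> list[Root]:
    """All roots of (V_a−V_s)/R_a = f(V_a) on [V_s−5, E_Na], with stability.

    Roots are located by sign changes of the residual on a fixed grid and
    polished with Brent's method; a root is stable iff f′(V_a) < 1/R_a.
    With R_a = 0 the isopotential limit V_a = V_s is returned (stable).
    """
    ch = model.channels
    if model.R_a == 0.0:
        return [Root(V_a=V_s, stable=True)]
    lo, hi = V_s - 5.0, ch.E_Na
    grid = np.arange(lo, hi + grid_step, grid_step)
    res = _residual(grid, V_s, model)
    roots: list[float] = []
    for i in np.nonzero(np.diff(np.sign(res)) != 0)[0]:
        r = brentq(lambda v: float(_residual(v, V_s, model)), grid[i], grid[i + 1],
                   xtol=1e-12)
        roots.append(r)
    # exact zeros on grid points (rare)
    for i in np.nonzero(res == 0.0)[0]:
        if not any(abs(grid[i] - r) < grid_step / 2 for r in roots):
            roots.append(float(grid[i]))
    roots.sort()
    inv_Ra = 1.0 / (model.R_a * _MOHM_TO_GOHM)
    return [
        Root(V_a=r, stable=bool(na_current_slope(r, ch) < inv_Ra)) for r in roots
    ]


@dataclass(frozen=True)
class FoldResult:
    """Lower fold of the current equation (the spike threshold).

    ``V_s_fold``: somatic voltage at which the resting root disappears;
    ``V_a_fold``: axonal voltage at the fold; ``V_a_upper``: the depolarized
    stable root at V_s_fold (where V_a lands after the jump);
    ``delta_V = V_a_upper − V_s_fold``; ``V_s_fold_upper`` is the second
    (de-activation) fold met on a downward sweep, if applicable.
    """

    V_s_fold: float
    V_a_fold: float
    V_a_upper: float
    delta_V: float
    V_s_fold_upper: Optional[float] = None


def critical_coupling(channels: NaChannelSet) -> float:
    """Critical dimensionless product R_a·g_total above which a fold exists.

    Equals 1 / max_V d/dV[m_inf(V)·(E_Na−V)]; at that coupling the lateral
    current line is tangent to the Na current curve at its inflexion point.
    """
    def neg_slope(V: float) -> float:
        return -float(na_current_slope(V, channels)) / channels.g_total

    # dense bracketing scan, then polish
    grid = np.linspace(channels.V_half - 60.0, channels.E_Na, 4001)
    slopes = na_current_slope(grid, channels) / channels.g_total
    i = int(np.argmax(slopes))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(neg_slope, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return 1.0 / (-res.fun)


def fold_threshold(model: ReducedModel) -> Optional[FoldResult]:
    """Locate the fold bifurcation (spike threshold) of the current equation.

    Solves 1/R_a = f′(V_a) for the two tangency points; the smaller-V_a
    solution is the threshold fold, with V_s* = V_a* − R_a·f(V_a*).  Returns
    ``None`` when the coupling is subcritical (no fold exists).
    """
    ch = model.channels
    if model.R_a <= 0:
        return None
    if model.coupling_product <= critical_coupling(ch):
        return None
    inv_Ra = 1.0 / (model.R_a * _MOHM_TO_GOHM)

    def h(V: float) -> float:
        return float(na_current_slope(V, ch)) - inv_Ra

    grid = np.linspace(ch.V_half - 60.0, ch.E_Na, 8001)
    hv = na_current_slope(grid, ch) - inv_Ra
    sign_changes = np.nonzero(np.diff(np.sign(hv)) != 0)[0]
    folds = [brentq(h, grid[i], grid[i + 1], xtol=1e-12) for i in sign_changes]
    if len(folds) < 2:  # numerically tangent: treat as no fold
        return None
    V_a_lower, V_a_upper_fold = folds[0], folds[-1]
    Ra_G = model.R_a * _MOHM_TO_GOHM
    V_s_fold = V_a_lower - Ra_G * float(na_current(V_a_lower, ch))
    V_s_fold_upper = V_a_upper_fold - Ra_G * float(na_current(V_a_upper_fold, ch))
    # depolarized stable root at the threshold V_s (just past the fold)
    roots = solve_fixed_points(model, V_s_fold)
    upper = max(r.V_a for r in roots if r.stable)
    return FoldResult(
        V_s_fold=V_s_fold,
        V_a_fold=V_a_lower,
        V_a_upper=upper,
        delta_V=upper - V_s_fold,
        V_s_fold_upper=V_s_fold_upper,
    )


def critical_distance(spec: NeuronSpec, channels: NaChannelSet | None = None) -> float:
    """Distance x* (µm) beyond which a point Na cluster gives a fold.

    Solves axial_resistance(x*)·g_total = critical product.  With a tapered
    hillock the cylinder formula is applied to the equivalent length and the
    result mapped back to anatomical distance.
    """
    if channels is None:
        channels = spec.channel_sets[0]
    crit = critical_coupling(channels)
    R_per_um = axial_resistance(spec, spec.geometry.axon_length) - (
        axial_resistance(spec, spec.geometry.axon_length - 1.0)
    )  # MΩ per µm of distal cylinder
    R_star_M = crit / channels.g_total / _MOHM_TO_GOHM  # MΩ
    t = spec.geometry.taper
    if t is None:
        return R_star_M / R_per_um
    R_taper = axial_resistance(spec, t.length)
    if R_star_M <= R_taper:
        # inside the taper: invert R(x) = 4 R_i x /(π d1 d(x)) numerically
        return brentq(lambda x: axial_resistance(spec, x) - R_star_M, 0.0, t.length)
    return t.length + (R_star_M - R_taper) / R_per_um


def threshold_vs_distance(
    spec: NeuronSpec,
    channels: NaChannelSet | None = None,
    x_grid: Sequence[float] = (),
) -> pd.DataFrame:
    """Fold threshold V_s*(x) along the axon (columns x_um, V_s_fold, ...).

    Points below the critical distance are excluded; the ``excluded`` frame
    attribute lists them with the reason.  The threshold decreases roughly
    linearly in ln x with slope → −k_a.
    """
    if channels is None:
        channels = spec.channel_sets[0]
    C_s = somatic_capacitance(spec)
    rows, excluded = [], []
    for x in x_grid:
        model = ReducedModel(axial_resistance(spec, x), channels, C_s)
        fr = fold_threshold(model)
        if fr is None:
            excluded.append({"x_um": x, "reason": "subcritical coupling (no fold)"})
            continue
        rows.append(
            {
                "x_um": x,
                "R_a_MOhm": model.R_a,
                "V_s_fold": fr.V_s_fold,
                "V_a_fold": fr.V_a_fold,
                "delta_V": fr.delta_V,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["excluded"] = excluded
    return df


def kink_rate(model: ReducedModel) -> Optional[float]:
    """Predicted initial somatic dV/dt jump at spike onset, mV/ms.

    The abrupt opening of the axonal channels steps the lateral current by
    ΔV/R_a, which the somatic capacitance integrates: dV/dt = ΔV/(C·R_a).
    Returns ``None`` for subcritical coupling.
    """
    fr = fold_threshold(model)
    if fr is None:
        return None
    # pF · GΩ = ms, so the ratio is directly in mV/ms
    return fr.delta_V / (model.C_soma * model.R_a * _MOHM_TO_GOHM)


def onset_rapidness_theory(alpha: float, channels: NaChannelSet) -> float:
    """Phase-plot slope α/k_a (ms⁻¹) at the initiation site.

    At the site the trajectory follows the Na activation curve, so the slope
    of dV/dt vs V at criterion α depends only on the Boltzmann slope factor.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return alpha / channels.k_a


def reduced_activation_curve(
    model: ReducedModel, V_s_grid: Sequence[float], sweep: str = "up"
) -> pd.DataFrame:
    """Open fraction m_inf(V_a) on the followed stable branch vs V_s.

    ``sweep='up'`` follows the resting branch until the lower fold then jumps
    to the depolarized branch (hysteresis appears for ``sweep='down'``,
    which holds the depolarized branch down to the upper fold).
    """
    if sweep not in ("up", "down"):
        raise ValueError("sweep must be 'up' or 'down'")
    V_s_grid = np.asarray(sorted(V_s_grid))
    fr = fold_threshold(model)
    out = []
    for V_s in V_s_grid:
        roots = [r for r in solve_fixed_points(model, V_s) if r.stable]
        if fr is None:
            branch = roots[0].V_a
        elif sweep == "up":
            branch = roots[0].V_a if V_s < fr.V_s_fold else roots[-1].V_a
        else:
            assert fr.V_s_fold_upper is not None
            branch = roots[-1].V_a if V_s > fr.V_s_fold_upper else roots[0].V_a
        out.append({"V_s": float(V_s), "V_a": branch,
                    "open_fraction": float(m_inf(branch, model.channels))})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# diagram container
# ---------------------------------------------------------------------------

@dataclass
class FixedPointDiagram:
    """Roots of the current equation over a grid of somatic voltages."""

    model: ReducedModel
    V_s_grid: np.ndarray
    roots: list[list[Root]]
    fold: Optional[FoldResult] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for V_s, rs in zip(self.V_s_grid, self.roots):
            for r in rs:
                rows.append({"V_s": float(V_s), "V_a": r.V_a, "stable": r.stable})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fixed_point_diagram(
    model: ReducedModel, V_s_grid: Sequence[float]
) -> FixedPointDiagram:
    grid = np.asarray(V_s_grid, dtype=float)
    roots = [solve_fixed_points(model, float(v)) for v in grid]
    return FixedPointDiagram(model=model, V_s_grid=grid, roots=roots,
                             fold=fold_threshold(model))
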