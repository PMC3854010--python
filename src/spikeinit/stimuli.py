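"""Synthetic stimulation protocols.

Three kinds of input drive every experiment in the package: somatic
voltage-clamp step ladders, somatic current pulses, and a seeded fluctuating
(Ornstein–Uhlenbeck) current emulating in-vivo-like input for the
energy-efficiency experiment.  All waveforms are deterministic functions of
their parameters (and seed), so runs are reproducible bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VoltageSchedule",
    "make_step_ladder",
    "make_current_pulse",
    "OUParams",
    "make_ou_current",
    "save_waveform",
    "load_waveform",
]


@dataclass(frozen=True)
class VoltageSchedule:
    """Piecewise-constant somatic command voltage: levels (mV) held for ``hold`` ms."""

    levels: tuple[float, ...]
    hold: float

    def __post_init__(self) -> None:
        if self.hold <= 0:
            raise ValueError("hold duration must be positive")
        if not self.levels:
            raise ValueError("schedule needs at least one level")

    @property
    def duration(self) -> float:
        return self.hold * len(self.levels)

    def as_array(self, dt: float) -> np.ndarray:
        """Sample the schedule at resolution ``dt`` ms (one value per step)."""
        n_per = int(round(self.hold / dt))
        return np.repeat(np.asarray(self.levels, dtype=float), n_per)


def make_step_ladder(levels: Sequence[float], hold: float) -> VoltageSchedule:
    """Voltage-step ladder, e.g. 4 steps of 3 mV from −64 to −55 mV."""
    return VoltageSchedule(levels=tuple(float(v) for v in levels), hold=float(hold))


def make_current_pulse(
    amplitude: float, onset: float, width: float, duration: float, dt: float
) -> np.ndarray:
    """Rectangular somatic current pulse (pA); returns one sample per dt step."""
    if duration <= 0 or width <= 0:
        raise ValueError("duration and width must be positive")
    n = int(round(duration / dt))
    I = np.zeros(n)
    i0 = int(round(onset / dt))
    i1 = min(n, int(round((onset + width) / dt)))
    I[i0:i1] = amplitude
    return I


@dataclass(frozen=True)
class OUParams:
    """Fluctuating-current parameters: mean I_0 (pA), stationary SD σ_I (pA),
    correlation time τ_I (ms)."""

    tau_I: float = 5.0
    I_0: float = 18.3
    sigma_I: float = 31.4
    duration: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_I <= 0 or self.duration <= 0:
            raise ValueError("tau_I and duration must be positive")
        if self.sigma_I < 0:
            raise ValueError("sigma_I must be non-negative")


def make_ou_current(params: OUParams, dt: float) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck current, sampled every ``dt`` ms.

    Uses the exact discrete update
    ``I[k+1] = I_0 + (I[k]−I_0)·ρ + σ_I·sqrt(1−ρ²)·ξ`` with ``ρ = exp(−dt/τ_I)``,
    whose stationary mean, SD and autocorrelation time match I_0, σ_I and τ_I
    for any dt.  The first sample is drawn from the stationary distribution,
    so the waveform is a deterministic function of (seed, dt, duration).
    """
    if dt > params.tau_I / 10.0:
        warnings.warn(
            f"dt={dt} ms is coarse relative to tau_I={params.tau_I} ms; "
            "waveform under-resolves the fluctuations",
            stacklevel=2,
        )
    n = int(round(params.duration / dt))
    rng = np.random.default_rng(params.seed)
    if params.sigma_I == 0.0:
        return np.full(n, params.I_0)
    rho = np.exp(-dt / params.tau_I)
    noise_scale = params.sigma_I * np.sqrt(1.0 - rho * rho)
    xi = rng.standard_normal(n)
    # AR(1) recursion y[k] = rho·y[k-1] + w[k] as an IIR filter (exact, vectorized)
    from scipy.signal import lfilter

    w = noise_scale * xi
    w[0] = params.sigma_I * xi[0]  # stationary start
    y = lfilter([1.0], [1.0, -rho], w)
    return params.I_0 + y


def save_waveform(path: str | Path, t: np.ndarray, value: np.ndarray) -> None:
    """Write a (time, value) waveform to CSV so runs are replayable."""
    pd.DataFrame({"time_ms": t, "value": value}).to_csv(path, index=False)


def load_waveform(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_ms"].to_numpy(), df["value"].to_numpy()
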