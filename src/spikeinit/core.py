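"""Parameter objects and closed-form electrical quantities for the ball-and-stick neuron.

The model is a spherical soma attached to a thin cylindrical axon (optionally
with a tapered hillock), carrying leak channels everywhere and non-inactivating
sodium channels with first-order Boltzmann activation (``m^1`` kinetics) placed
somewhere on the axon.  Spikes initiate where those channels sit; the geometry
makes the soma a current sink for the axonal Na current.

Unit conventions (used consistently across the whole package):

=============  ======
voltage        mV
time           ms
length         µm
current        pA
conductance    nS
capacitance    pF
resistance     MΩ
=============  ======

These are mutually consistent up to fixed powers of ten: ``nS · mV = pA``,
``pF · mV/ms = pA`` and ``GΩ · nS = 1`` (so ``R[MΩ] · g[nS] / 1000`` is the
dimensionless coupling product used by the reduced model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = [
    "PassiveParams",
    "Taper",
    "Geometry",
    "PointProfile",
    "UniformProfile",
    "LinearDecreasingProfile",
    "ChannelProfile",
    "NaChannelSet",
    "NeuronSpec",
    "somatic_leak_conductance",
    "somatic_capacitance",
    "membrane_time_constant",
    "axial_resistance",
    "equivalent_cylinder_extension",
    "space_constant",
    "m_inf",
    "na_current",
    "na_current_slope",
    "ball_and_stick",
    "STANDARD_PASSIVE",
    "save_spec",
    "load_spec",
    "write_swc",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane constants.

    Attributes
    ----------
    R_m : specific membrane resistance, Ω·cm².
    C_m : specific membrane capacitance, µF/cm².
    R_i : intracellular (axial) resistivity, Ω·cm.
    E_L : leak reversal potential, mV.
    """

    R_m: float = 30_000.0
    C_m: float = 0.75
    R_i: float = 150.0
    E_L: float = -75.0

    def __post_init__(self) -> None:
        if self.R_m <= 0 or self.C_m <= 0 or self.R_i <= 0:
            raise ValueError("R_m, C_m and R_i must be strictly positive")
        if not -100.0 <= self.E_L <= 0.0:
            raise ValueError("E_L must lie in [-100, 0] mV")


@dataclass(frozen=True)
class Taper:
    """Linearly tapered hillock at the proximal end of the axon.

    ``length`` µm over which the diameter falls linearly from
    ``start_diameter`` to ``end_diameter`` (µm).
    """

    length: float
    start_diameter: float
    end_diameter: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("taper length must be positive")
        if self.start_diameter <= 0 or self.end_diameter <= 0:
            raise ValueError("taper diameters must be positive")
        if self.start_diameter < self.end_diameter:
            raise ValueError("taper must not widen (start_diameter >= end_diameter)")

    def diameter_at(self, s: float) -> float:
        """Diameter (µm) at distance ``s`` µm from the proximal end."""
        frac = min(max(s / self.length, 0.0), 1.0)
        return self.start_diameter + (self.end_diameter - self.start_diameter) * frac


@dataclass(frozen=True)
class Geometry:
    """Ball-and-stick geometry: spherical soma plus cylindrical axon (µm)."""

    soma_diameter: float = 50.0
    axon_diameter: float = 1.0
    axon_length: float = 300.0
    taper: Optional[Taper] = None

    def __post_init__(self) -> None:
        if self.soma_diameter <= 0 or self.axon_diameter <= 0 or self.axon_length <= 0:
            raise ValueError("all diameters and lengths must be positive")
        if self.taper is not None and self.axon_length <= self.taper.length:
            raise ValueError("axon_length must exceed taper length")

    def diameter_at(self, x: float) -> float:
        """Axon diameter (µm) at distance ``x`` µm from the soma."""
        if not 0.0 <= x <= self.axon_length:
            raise ValueError(f"x={x} µm outside axon [0, {self.axon_length}]")
        if self.taper is not None and x < self.taper.length:
            return self.taper.diameter_at(x)
        return self.axon_diameter


# --- channel density profiles ----------------------------------------------

@dataclass(frozen=True)
class PointProfile:
    """All channels clustered at one axonal location ``x`` (µm from soma)."""

    x: float

    def bounds(self) -> tuple[float, float]:
        return (self.x, self.x)


@dataclass(frozen=True)
class UniformProfile:
    """Channels spread with constant density on ``[x1, x2]`` µm."""

    x1: float
    x2: float

    def __post_init__(self) -> None:
        if not self.x1 < self.x2:
            raise ValueError("uniform profile needs x1 < x2")

    def bounds(self) -> tuple[float, float]:
        return (self.x1, self.x2)


@dataclass(frozen=True)
class LinearDecreasingProfile:
    """Density falling linearly from ``x1`` to zero at ``x2`` (µm)."""

    x1: float
    x2: float

    def __post_init__(self) -> None:
        if not self.x1 < self.x2:
            raise ValueError("linear profile needs x1 < x2")

    def bounds(self) -> tuple[float, float]:
        return (self.x1, self.x2)


ChannelProfile = Union[PointProfile, UniformProfile, LinearDecreasingProfile]


@dataclass(frozen=True)
class NaChannelSet:
    """A population of non-inactivating Na channels with Boltzmann activation.

    Attributes
    ----------
    V_half : half-activation voltage, mV.
    k_a : Boltzmann slope factor, mV (voltage scale of the sigmoid).
    E_Na : reversal potential, mV.
    tau_m : activation time constant, ms.
    g_total : total maximal conductance of the set, nS.
    profile : spatial placement on the axon.
    name : optional label (e.g. ``"Nav1.6"``).
    """

    V_half: float = -40.0
    k_a: float = 6.0
    E_Na: float = 60.0
    tau_m: float = 0.1
    g_total: float = 1.0
    profile: ChannelProfile = field(default_factory=lambda: PointProfile(40.0))
    name: str = "Na"

    def __post_init__(self) -> None:
        if self.k_a <= 0:
            raise ValueError("k_a must be positive")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.g_total <= 0:
            raise ValueError("g_total must be positive")


@dataclass(frozen=True)
class NeuronSpec:
    """Complete model instance: geometry + passive constants + channel sets."""

    geometry: Geometry = field(default_factory=Geometry)
    passive: PassiveParams = field(default_factory=PassiveParams)
    channel_sets: tuple[NaChannelSet, ...] = ()

    def __post_init__(self) -> None:
        L = self.geometry.axon_length
        for ch in self.channel_sets:
            lo, hi = ch.profile.bounds()
            if lo < 0 or hi > L:
                raise ValueError(
                    f"channel profile {ch.profile} outside axon [0, {L}] µm"
                )


STANDARD_PASSIVE = PassiveParams()
"""Standard passive constants of the reference cortical-neuron model."""


# ---------------------------------------------------------------------------
# closed-form quantities
# ---------------------------------------------------------------------------

_CM2_PER_UM2 = 1e-8  # (1 µm)² in cm²


def _soma_area_cm2(spec: NeuronSpec) -> float:
    r = spec.geometry.soma_diameter / 2.0
    return 4.0 * math.pi * r * r * _CM2_PER_UM2


def somatic_leak_conductance(spec: NeuronSpec) -> float:
    """Leak conductance of the soma alone, nS (= soma area / R_m)."""
    return _soma_area_cm2(spec) / spec.passive.R_m * 1e9


def somatic_capacitance(spec: NeuronSpec) -> float:
    """Capacitance of the soma alone, pF (= soma area × C_m)."""
    return _soma_area_cm2(spec) * spec.passive.C_m * 1e6


def membrane_time_constant(passive: PassiveParams) -> float:
    """Membrane time constant τ = R_m·C_m, ms."""
    return passive.R_m * passive.C_m * 1e-3


def axial_resistance(spec: NeuronSpec, x: float) -> float:
    """Axial resistance (MΩ) from the soma surface to distance ``x`` µm.

    For a cylinder ``R_a = 4·R_i·x/(π·d²)``; over a linearly tapered piece the
    integral ``∫ 4 R_i/(π d(s)²) ds`` has the closed form
    ``4 R_i s/(π d_start d(s))``.
    """
    geo = spec.geometry
    if not 0.0 <= x <= geo.axon_length:
        raise ValueError(f"x={x} µm outside axon [0, {geo.axon_length}]")
    R_i = spec.passive.R_i  # Ω·cm
    # resistance of s µm of cylinder with diameter d µm, in MΩ:
    #   4 R_i (s·1e-4 cm) / (π (d·1e-4 cm)²) Ω = 4 R_i s / (π d²) · 1e-2 MΩ
    def cyl(s: float, d: float) -> float:
        return 4.0 * R_i * s / (math.pi * d * d) * 1e-2

    if geo.taper is None:
        return cyl(x, geo.axon_diameter)
    t = geo.taper
    if x <= t.length:
        return cyl(x, math.sqrt(t.start_diameter * t.diameter_at(x)))
    return cyl(t.length, math.sqrt(t.start_diameter * t.end_diameter)) + cyl(
        x - t.length, geo.axon_diameter
    )


def equivalent_cylinder_extension(spec: NeuronSpec) -> float:
    """Length of plain cylinder (µm) with the same resistance as the taper.

    A hillock of length L tapering from d₁ to d₂ adds the axial resistance of
    ``L·d²/(d₁·d₂)`` µm of the distal cylinder (diameter d).  Returns 0 when
    the geometry has no taper.
    """
    t = spec.geometry.taper
    if t is None:
        return 0.0
    d = spec.geometry.axon_diameter
    return t.length * d * d / (t.start_diameter * t.end_diameter)


def space_constant(spec: NeuronSpec) -> float:
    """Passive space constant λ = sqrt(d·R_m/(4·R_i)) of the cylinder, µm."""
    d_cm = spec.geometry.axon_diameter * 1e-4
    lam_cm = math.sqrt(d_cm * spec.passive.R_m / (4.0 * spec.passive.R_i))
    return lam_cm * 1e4


def m_inf(V, channels: NaChannelSet):
    """Steady-state open fraction 1/(1+exp((V_half−V)/k_a)); V in mV."""
    import numpy as np

    return 1.0 / (1.0 + np.exp((channels.V_half - np.asarray(V)) / channels.k_a))


def na_current(V_a, channels: NaChannelSet):
    """Steady-state Na current f(V_a) = g_total·m_inf·(E_Na−V_a), pA.

    Positive (inward, depolarizing) below E_Na; changes sign at E_Na.
    """
    import numpy as np

    V = np.asarray(V_a)
    return channels.g_total * m_inf(V, channels) * (channels.E_Na - V)


def na_current_slope(V_a, channels: NaChannelSet):
    """Analytic derivative f'(V_a) of the steady-state Na current, nS."""
    import numpy as np

    V = np.asarray(V_a)
    m = m_inf(V, channels)
    # d/dV [m (E-V)] = m(1-m)(E-V)/k_a - m
    return channels.g_total * (
        m * (1.0 - m) * (channels.E_Na - V) / channels.k_a - m
    )


# ---------------------------------------------------------------------------
# convenience constructor
# ---------------------------------------------------------------------------

def ball_and_stick(
    profile: ChannelProfile | float = 40.0,
    g_na_ratio: float = 2.0,
    *,
    passive: PassiveParams = STANDARD_PASSIVE,
    geometry: Geometry | None = None,
    extra_sets: tuple[NaChannelSet, ...] = (),
    **channel_kwargs,
) -> NeuronSpec:
    """Standard cortical-neuron ball-and-stick model.

    Soma 50 µm sphere, axon 1 µm × 300 µm, Nav1.6-like channels
    (V_half = −40 mV, k_a = 6 mV, E_Na = 60 mV, τ_m = 0.1 ms) with total
    conductance ``g_na_ratio`` times the somatic leak conductance.  A float
    ``profile`` is shorthand for a point cluster at that distance (µm); pass
    ``profile=None`` for a purely passive neuron.
    """
    geometry = geometry or Geometry()
    base = NeuronSpec(geometry=geometry, passive=passive)
    sets: tuple[NaChannelSet, ...] = ()
    if profile is not None:
        if isinstance(profile, (int, float)):
            profile = PointProfile(float(profile))
        g = g_na_ratio * somatic_leak_conductance(base)
        sets = (
            NaChannelSet(
                g_total=g, profile=profile, name="Nav1.6", **channel_kwargs
            ),
        )
    return NeuronSpec(
        geometry=geometry, passive=passive, channel_sets=sets + tuple(extra_sets)
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_PROFILE_TAGS = {
    "point": PointProfile,
    "uniform": UniformProfile,
    "linear_decreasing": LinearDecreasingProfile,
}


def _profile_to_dict(p: ChannelProfile) -> dict:
    for tag, cls in _PROFILE_TAGS.items():
        if isinstance(p, cls):
            return {"kind": tag, **asdict(p)}
    raise TypeError(f"unknown profile {p!r}")


def spec_to_dict(spec: NeuronSpec) -> dict:
    d = {
        "geometry": asdict(spec.geometry),
        "passive": asdict(spec.passive),
        "channel_sets": [],
    }
    for ch in spec.channel_sets:
        cd = asdict(ch)
        cd["profile"] = _profile_to_dict(ch.profile)
        d["channel_sets"].append(cd)
    return d


def spec_from_dict(d: dict) -> NeuronSpec:
    geo = dict(d.get("geometry", {}))
    taper = geo.pop("taper", None)
    geometry = Geometry(**geo, taper=Taper(**taper) if taper else None)
    passive = PassiveParams(**d.get("passive", {}))
    sets = []
    for cd in d.get("channel_sets", []):
        cd = dict(cd)
        pd = dict(cd.pop("profile"))
        cls = _PROFILE_TAGS[pd.pop("kind")]
        sets.append(NaChannelSet(**cd, profile=cls(**pd)))
    return NeuronSpec(geometry=geometry, passive=passive, channel_sets=tuple(sets))


def save_spec(spec: NeuronSpec, path: str | Path) -> None:
    """Write a NeuronSpec to a YAML config file."""
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def load_spec(path: str | Path) -> NeuronSpec:
    """Read a NeuronSpec from a YAML config file."""
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


def write_swc(spec: NeuronSpec, path: str | Path, dx: float = 10.0) -> None:
    """Export the ball-and-stick morphology as SWC (soma point + axon samples)."""
    geo = spec.geometry
    lines = ["# generated by spikeinit", "# id type x y z radius parent"]
    lines.append(f"1 1 0.0 0.0 0.0 {geo.soma_diameter / 2.0:.4f} -1")
    n = max(2, int(round(geo.axon_length / dx)) + 1)
    xs = [geo.axon_length * i / (n - 1) for i in range(n)]
    parent = 1
    for i, x in enumerate(xs):
        r = geo.diameter_at(x) / 2.0
        ident = i + 2
        lines.append(f"{ident} 2 {x:.4f} 0.0 0.0 {r:.4f} {parent}")
        parent = ident
    Path(path).write_text("\n".join(lines) + "\n")
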