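"""Zero-force free-energy profile versus complex elongation.

Five stationary points along the elongation coordinate: the
non-intercalated, mono-intercalated and bis-intercalated minima and the
two transition states between them.  Minima energies follow from the
equilibrium constants and the ligand concentration; barrier energies
follow from the zero-force rates up to the attempt-rate convention
DeltaG_dagger = kBT * ln(k0_attempt / k).  Energies are reported in kBT
units with the bis-intercalated state as the zero reference; elongations
in nm with the non-intercalated complex at zero.

Two conventions exist for the mono-state energy because the published
constants are internally inconsistent at the ~0.3 kBT level: the ratio
of the independently fitted dissociation constants (ln(Kd1/Kd)) and the
directly fitted second-step constant (ln(K2)).  Neither is silently
preferred; ``mono_convention`` selects one per computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .kinetics import ElementaryRates

STATE_ORDER = ("non", "TS1", "mono", "TS2", "bis")


@dataclass(frozen=True)
class LandscapeSpec:
    """Inputs of the zero-force landscape construction.

    ``distances`` maps the four transition distances (nm) by rate name:
    k1 (x+1), k_m1 (x-1), k2 (x+2), k_m2 (x-2).  ``attempt_rate`` (s^-1)
    sets the barrier-height convention and is always reported alongside
    the energies.  ``K2`` is only needed for the 'k2' mono convention.
    """

    rates0: ElementaryRates
    distances: dict[str, float]
    Kd: float
    Kd1: float
    concentration: float
    attempt_rate: float = 1.0
    kbt: float = 1.0  # energies are expressed in kBT units
    K2: float | None = None

    def __post_init__(self) -> None:
        if self.attempt_rate <= 0:
            raise ValueError("attempt rate must be positive")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.Kd <= 0 or self.Kd1 <= 0:
            raise ValueError("Kd and Kd1 must be positive")
        missing = {"k1", "k_m1", "k2", "k_m2"} - set(self.distances)
        if missing:
            raise ValueError(f"missing transition distances: {sorted(missing)}")


@dataclass(frozen=True)
class LandscapeState:
    label: str
    elongation: float  # nm
    energy: float  # kBT


@dataclass(frozen=True)
class EnergyLandscape:
    states: tuple[LandscapeState, ...]
    attempt_rate: float
    concentration: float
    mono_convention: str
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        labels = tuple(s.label for s in self.states)
        if labels != STATE_ORDER:
            raise ValueError(f"states must be ordered {STATE_ORDER}, got {labels}")
        elong = [s.elongation for s in self.states]
        if any(b <= a for a, b in zip(elong, elong[1:])):
            raise ValueError("elongations must be strictly increasing along the pathway")
        g = {s.label: s.energy for s in self.states}
        if not (g["TS1"] > g["non"] and g["TS1"] > g["mono"]):
            raise ValueError("first barrier does not exceed its adjacent minima")
        if not (g["TS2"] > g["mono"] and g["TS2"] > g["bis"]):
            raise ValueError("second barrier does not exceed its adjacent minima")

    def __getitem__(self, label: str) -> LandscapeState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(label)

    def energies(self) -> dict[str, float]:
        return {s.label: s.energy for s in self.states}

    def elongations(self) -> dict[str, float]:
        return {s.label: s.elongation for s in self.states}


def rate_barrier(rate: float, attempt_rate: float = 1.0) -> float:
    """Barrier height (kBT) implied by a rate: DeltaG = ln(k0_attempt / k)."""
    if rate <= 0 or attempt_rate <= 0:
        raise ValueError("rate and attempt rate must be positive")
    return math.log(attempt_rate / rate)


def build_landscape(spec: LandscapeSpec, mono_convention: str = "kd_ratio") -> EnergyLandscape:
    """Construct the five-state zero-force landscape.

    Energies (kBT, bis state = 0):
      non  = ln(C / Kd)                    (zero when C = Kd)
      mono = ln(Kd1 / Kd)  or  ln(K2)      (per ``mono_convention``)
      TS1  = non  + ln(k0_attempt / (k1 * C))
      TS2  = mono + ln(k0_attempt / k2)

    Elongations (nm, non-intercalated = 0): TS1 at x+1, mono at
    x1 = x+1 - x-1, TS2 at x1 + x+2, bis at x1 + x2 with
    x2 = x+2 - x-2.
    """
    d = spec.distances
    x1 = d["k1"] - d["k_m1"]
    x2 = d["k2"] - d["k_m2"]
    elongations = {
        "non": 0.0,
        "TS1": d["k1"],
        "mono": x1,
        "TS2": x1 + d["k2"],
        "bis": x1 + x2,
    }
    g_non = math.log(spec.concentration / spec.Kd)
    if mono_convention == "kd_ratio":
        g_mono = math.log(spec.Kd1 / spec.Kd)
    elif mono_convention == "k2":
        k2eq = spec.K2
        if k2eq is None:
            if spec.rates0.k_m2 <= 0:
                raise ValueError("K2 convention needs spec.K2 or a positive k-2")
            k2eq = spec.rates0.k2 / spec.rates0.k_m2
        g_mono = math.log(k2eq)
    else:
        raise ValueError(f"unknown mono_convention {mono_convention!r}")
    energies = {
        "non": g_non,
        "mono": g_mono,
        "bis": 0.0,
        "TS1": g_non + rate_barrier(spec.rates0.k1 * spec.concentration, spec.attempt_rate),
        "TS2": g_mono + rate_barrier(spec.rates0.k2, spec.attempt_rate),
    }
    states = tuple(
        LandscapeState(label, elongations[label], energies[label]) for label in STATE_ORDER
    )
    return EnergyLandscape(
        states=states,
        attempt_rate=spec.attempt_rate,
        concentration=spec.concentration,
        mono_convention=mono_convention,
        metadata={"x1": x1, "x2": x2, "Kd": spec.Kd, "Kd1": spec.Kd1},
    )


_ADJACENT = {
    ("non", "mono"): "TS1",
    ("mono", "non"): "TS1",
    ("mono", "bis"): "TS2",
    ("bis", "mono"): "TS2",
}


def barrier_heights(landscape: EnergyLandscape, from_state: str, to_state: str | None = None) -> float:
    """Barrier DeltaG_dagger = G(TS) - G(from_state), kBT.

    Valid transitions are non<->mono over TS1 and mono<->bis over TS2.
    With ``to_state`` omitted, the forward direction (toward bis) is
    taken for the minima non and mono, and mono for bis.
    """
    if to_state is None:
        to_state = {"non": "mono", "mono": "bis", "bis": "mono"}.get(from_state)
    ts = _ADJACENT.get((from_state, to_state))
    if ts is None:
        raise ValueError(f"states {from_state!r} -> {to_state!r} are not adjacent minima")
    return landscape[ts].energy - landscape[from_state].energy


def rates_from_landscape(landscape: EnergyLandscape) -> ElementaryRates:
    """Invert the barrier convention back to elementary rates.

    k = k0_attempt * exp(-DeltaG_dagger) for each of the four transitions
    (the bimolecular first step returns k1 = k_on/(C) so the round trip is
    exact for the concentration the landscape was built at).
    """
    k0a = landscape.attempt_rate
    c = landscape.concentration
    k1c = k0a * math.exp(-barrier_heights(landscape, "non", "mono"))
    return ElementaryRates(
        k1=k1c / c,
        k_m1=k0a * math.exp(-barrier_heights(landscape, "mono", "non")),
        k2=k0a * math.exp(-barrier_heights(landscape, "mono", "bis")),
        k_m2=k0a * math.exp(-barrier_heights(landscape, "bis", "mono")),
        force=0.0,
    )
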