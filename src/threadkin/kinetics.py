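"""Two-step sequential intercalation kinetics.

The scheme is

    Ru + DNA  <=[k1*C]=[k-1]=>  mono-intercalated  <=[k2]=[k-2]=>  bis-intercalated

with a bimolecular first step (k1 in nM^-1 s^-1, C in nM) and a
monomolecular conversion step.  When the first step is much faster
(k1*C + k-1 >> k2 + k-2) it stays in pre-equilibrium to the second, and
the two observable relaxation rates reduce to the closed forms

    k_f = k1*C + k-1
    k_s = k2 * k1*C / (k1*C + k-1) + k-2.

The exact observable rates are the eigenvalues of the 2x2 relaxation
matrix and are used here as the reference oracle for that approximation.
Applied force tilts each elementary rate exponentially (Bell model),
k(F) = k0 * exp(F * x_dagger / kBT), with the signed transition-state
distance x_dagger in nm (positive = the complex lengthens on the way to
the transition state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .elasticity import KBT_DEFAULT

#: Pre-equilibrium quality threshold: warn when (k1*C + k-1)/(k2 + k-2)
#: falls below this.  The approximation error is ~1/ratio.
PREEQUILIBRIUM_WARN_RATIO = 10.0


@dataclass(frozen=True)
class ElementaryRates:
    """The four elementary rates of the two-step scheme at one force.

    k1 is per-concentration (nM^-1 s^-1); the other three are s^-1.
    ``force`` is context only (pN); None means unspecified/zero-force.
    """

    k1: float
    k_m1: float
    k2: float
    k_m2: float
    force: float | None = None

    def __post_init__(self) -> None:
        if min(self.k1, self.k_m1, self.k2, self.k_m2) < 0:
            raise ValueError("elementary rates must be non-negative")
        if self.k1 == 0 and self.k_m1 == 0:
            raise ValueError("first step is degenerate: k1 and k-1 both zero")

    def to_dict(self) -> dict:
        return {"k1": self.k1, "k_m1": self.k_m1, "k2": self.k2, "k_m2": self.k_m2,
                "force": self.force}


@dataclass(frozen=True)
class BellParams:
    """Zero-force rate and signed transition-state distance of one rate."""

    k0: float
    x_dagger: float

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("zero-force rate must be positive")

    def to_dict(self) -> dict:
        return {"k0": self.k0, "x_dagger": self.x_dagger}


@dataclass(frozen=True)
class EquilibriumConstants:
    """Step and overall equilibrium constants at one force.

    Kd1 (nM): dissociation constant of the mono-intercalation step.
    K2 (dimensionless): forward equilibrium constant of the conversion step.
    Kd (nM): overall dissociation constant, Kd = Kd1/K2.
    """

    Kd1: float
    K2: float
    Kd: float
    force: float | None = None

    def __post_init__(self) -> None:
        # Kd1 = 0 is the infinitely tight first-step limit (k-1 = 0)
        if self.Kd1 < 0 or self.K2 <= 0 or self.Kd < 0:
            raise ValueError("equilibrium constants must be non-negative (K2 positive)")

    def to_dict(self) -> dict:
        return {"Kd1": self.Kd1, "K2": self.K2, "Kd": self.Kd, "force": self.force}


@dataclass(frozen=True)
class EquilibriumForceLaw:
    """Exponential force law of an equilibrium constant.

    K(F) = K0 * exp(-F * x0 / kBT); x0 (nm) is the equilibrium elongation
    of the step, so force strengthens binding (lowers a dissociation
    constant) when x0 > 0.
    """

    K0: float
    x0: float

    def __post_init__(self) -> None:
        if self.K0 <= 0:
            raise ValueError("zero-force constant must be positive")

    def to_dict(self) -> dict:
        return {"K0": self.K0, "x0": self.x0}


def observed_rates_preequilibrium(rates: ElementaryRates, concentration: float) -> tuple[float, float]:
    """Pre-equilibrium fast/slow observable rates (k_f, k_s) in s^-1."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    a = rates.k1 * concentration + rates.k_m1
    if a == 0:
        raise ValueError("k1*C + k-1 = 0: slow rate undefined")
    k_f = a
    k_s = rates.k2 * (rates.k1 * concentration / a) + rates.k_m2
    return k_f, k_s


def observed_rates_exact(rates: ElementaryRates, concentration: float) -> tuple[float, float]:
    """Exact observable rates: eigenvalues of the 2x2 relaxation matrix.

    With a = k1*C + k-1, trace S = a + k2 + k-2 and determinant
    P = k1*C*(k2 + k-2) + k-1*k-2, the relaxation eigenrates are
    lambda_pm = (S +- sqrt(S^2 - 4P)) / 2, both real and non-negative.
    Returns (lambda_fast, lambda_slow).
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    a = rates.k1 * concentration + rates.k_m1
    if a == 0:
        raise ValueError("k1*C + k-1 = 0: relaxation degenerate")
    s = a + rates.k2 + rates.k_m2
    p = rates.k1 * concentration * (rates.k2 + rates.k_m2) + rates.k_m1 * rates.k_m2
    disc = max(s * s - 4.0 * p, 0.0)
    root = math.sqrt(disc)
    return (s + root) / 2.0, (s - root) / 2.0


def preequilibrium_ratio(rates: ElementaryRates, concentration: float) -> float:
    """Quality factor (k1*C + k-1)/(k2 + k-2) of the pre-equilibrium approximation."""
    denom = rates.k2 + rates.k_m2
    num = rates.k1 * concentration + rates.k_m1
    if denom == 0:
        return math.inf
    return num / denom


def bell_rate(bp: BellParams, force: float, kbt: float = KBT_DEFAULT):
    """Force-scaled rate k0 * exp(F * x_dagger / kBT)."""
    return bp.k0 * np.exp(np.asarray(force, dtype=float) * bp.x_dagger / kbt)


def rates_at_force(truth: dict[str, BellParams], force: float, kbt: float = KBT_DEFAULT) -> ElementaryRates:
    """Evaluate four Bell laws (keys k1, k_m1, k2, k_m2) at one force."""
    return ElementaryRates(
        k1=float(bell_rate(truth["k1"], force, kbt)),
        k_m1=float(bell_rate(truth["k_m1"], force, kbt)),
        k2=float(bell_rate(truth["k2"], force, kbt)),
        k_m2=float(bell_rate(truth["k_m2"], force, kbt)),
        force=force,
    )


def equilibrium_from_rates(rates: ElementaryRates) -> EquilibriumConstants:
    """Equilibrium constants implied by the elementary rates.

    Kd1 = k-1/k1 (nM), K2 = k2/k-2, Kd = Kd1/K2.  Requires positive
    forward rates.
    """
    if rates.k1 <= 0 or rates.k2 <= 0:
        raise ValueError("forward rates must be positive to form equilibrium constants")
    kd1 = rates.k_m1 / rates.k1
    if rates.k_m2 <= 0:
        raise ValueError("k-2 = 0: K2 infinite, equilibrium constants undefined")
    k2eq = rates.k2 / rates.k_m2
    return EquilibriumConstants(Kd1=kd1, K2=k2eq, Kd=kd1 / k2eq, force=rates.force)


def equilibrium_force_law_eval(law: EquilibriumForceLaw, force: float, kbt: float = KBT_DEFAULT):
    """K(F) = K0 * exp(-F * x0 / kBT)."""
    return law.K0 * np.exp(-np.asarray(force, dtype=float) * law.x0 / kbt)


def step_elongation(x_plus: float, x_minus: float) -> float:
    """Net elongation of a step from its two transition distances, x = x+ - x-."""
    return x_plus - x_minus
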