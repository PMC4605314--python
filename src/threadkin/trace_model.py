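"""Observable layer: bi-exponential relaxation and equilibrium amplitudes.

A constant-force binding trace stores the excess extension over bare DNA,
dx(t) = x(t) - x_ds(F), which relaxes as

    dx(t) = dx_eq - dx_f * exp(-k_f t) - dx_s * exp(-k_s t).

At equilibrium the excess extension follows a simple binding isotherm in
ligand concentration, and the fast/slow amplitude split is governed by
the equilibrium probability f of the mono-intercalated state: a mono
bound ligand contributes half the per-site saturated elongation, a bis
bound ligand the full amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fraction of the per-site saturated elongation contributed by a
#: mono-intercalated ligand (equal-step-elongation assumption).  Kept as a
#: module constant so sensitivity analyses can vary it.
MONO_EXTENSION_FRACTION = 0.5

# A trace starts at or above zero excess extension, so dx_f + dx_s must not
# exceed dx_eq -- but fitted parameters of noisy traces can violate this by
# roughly the noise floor, hence the absolute + relative slack.
_AMPLITUDE_TOL_ABS = 1e-3
_AMPLITUDE_TOL_REL = 0.1


@dataclass(frozen=True)
class RelaxationParams:
    """Bi-exponential relaxation: amplitudes (nm/bp) and rates (s^-1)."""

    dx_eq: float
    dx_f: float
    dx_s: float
    k_f: float
    k_s: float

    def __post_init__(self) -> None:
        if not (self.k_f >= self.k_s > 0):
            raise ValueError("rates must satisfy k_f >= k_s > 0")
        if min(self.dx_eq, self.dx_f, self.dx_s) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.dx_f + self.dx_s > self.dx_eq + _AMPLITUDE_TOL_ABS + _AMPLITUDE_TOL_REL * self.dx_eq:
            raise ValueError(
                "dx_f + dx_s exceeds dx_eq: trace would start below zero excess extension"
            )

    def to_dict(self) -> dict:
        return {"dx_eq": self.dx_eq, "dx_f": self.dx_f, "dx_s": self.dx_s,
                "k_f": self.k_f, "k_s": self.k_s}


@dataclass
class Trace:
    """One constant-force excess-extension time series.

    ``extensions`` holds dx(t) = x(t) - x_ds(F) in nm/bp.
    """

    times: np.ndarray
    extensions: np.ndarray
    force: float
    concentration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.extensions = np.asarray(self.extensions, dtype=float)
        if self.times.shape != self.extensions.shape:
            raise ValueError("times and extensions must have the same length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def biexp_extension(p: RelaxationParams, t):
    """Evaluate the bi-exponential relaxation at times t >= 0 (s)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("relaxation model is defined for t >= 0")
    out = p.dx_eq - p.dx_f * np.exp(-p.k_f * t) - p.dx_s * np.exp(-p.k_s * t)
    return out if out.ndim else float(out)


def equilibrium_extension(concentration: float, Kd: float, dx_sat: float):
    """Equilibrium excess extension dx_eq = dx_sat * (C/Kd)/(C/Kd + 1)."""
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    r = c / Kd
    out = dx_sat * r / (r + 1.0)
    return out if out.ndim else float(out)


def mono_state_probability(concentration: float, Kd1: float):
    """Equilibrium probability f of the mono-intercalated state.

    f = (C/Kd1)/(C/Kd1 + 1), in [0, 1), increasing in C.
    """
    if Kd1 <= 0:
        raise ValueError("Kd1 must be positive")
    r = np.asarray(concentration, dtype=float) / Kd1
    out = r / (r + 1.0)
    return out if out.ndim else float(out)


def amplitude_partition(
    concentration: float, Kd: float, Kd1: float, dx_sat: float
) -> tuple[float, float]:
    """Split the equilibrium extension into fast and slow amplitudes.

    dx_f = dx_eq * f/2 and dx_s = dx_eq * (1 - f/2), so the two always
    sum to dx_eq exactly.  The factor f/2 follows from the equal
    step-elongation assumption (MONO_EXTENSION_FRACTION).
    """
    dx_eq = equilibrium_extension(concentration, Kd, dx_sat)
    f = mono_state_probability(concentration, Kd1)
    half = MONO_EXTENSION_FRACTION * f
    return dx_eq * half, dx_eq * (1.0 - half)


def amplitude_ratio(concentration: float, Kd1: float):
    """dx_f/dx_s = (C/Kd1)/(C/Kd1 + 2): increasing in C, bounded by 1."""
    if Kd1 <= 0:
        raise ValueError("Kd1 must be positive")
    r = np.asarray(concentration, dtype=float) / Kd1
    out = r / (r + 2.0)
    return out if out.ndim else float(out)
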