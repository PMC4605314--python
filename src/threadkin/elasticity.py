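"""Extensible worm-like-chain elasticity and occupancy conversion.

The stretched polymer (bare B-DNA or ligand-saturated complex) is described
by the high-force interpolation of the extensible worm-like chain,

    x(F) = x_max * (1 - 1/(2*sqrt(F*A/kBT)) + F/S),

with contour length per base pair ``x_max`` (nm/bp), persistence length
``A`` (nm) and stretch modulus ``S`` (pN).  Fractional ligand occupancy is
read off the measured extension by linear interpolation between the bare
and saturated curves.  All extensions are stored per base pair; converting
to a per-molecule length requires an explicit base-pair count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

#: Thermal energy at 20 degC, pN*nm.  Configurable everywhere; never baked
#: into a formula.
KBT_DEFAULT = 4.05


@dataclass(frozen=True)
class PolymerParams:
    """Extensible WLC parameters of one polymer species.

    Parameters
    ----------
    contour_per_bp : float
        Contour length per base pair, nm/bp.
    persistence : float
        Persistence length A, nm.
    stretch_modulus : float
        Elastic (stretch) modulus S, pN.
    """

    contour_per_bp: float
    persistence: float
    stretch_modulus: float

    def __post_init__(self) -> None:
        if not (self.contour_per_bp > 0 and self.persistence > 0 and self.stretch_modulus > 0):
            raise ValueError("all WLC parameters must be strictly positive")
        if not (0.1 < self.contour_per_bp < 1.0):
            raise ValueError(
                f"contour_per_bp={self.contour_per_bp} nm/bp outside the sane range (0.1, 1.0)"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.contour_per_bp, self.persistence, self.stretch_modulus)


@dataclass(frozen=True)
class WLCFitResult:
    """Least-squares WLC fit with per-parameter uncertainties."""

    params: PolymerParams
    uncertainties: tuple[float, float, float]
    residual_rms: float
    n_points: int
    converged: bool = True
    covariance: np.ndarray | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "params": {
                "contour_per_bp": self.params.contour_per_bp,
                "persistence": self.params.persistence,
                "stretch_modulus": self.params.stretch_modulus,
            },
            "uncertainties": {
                "contour_per_bp": self.uncertainties[0],
                "persistence": self.uncertainties[1],
                "stretch_modulus": self.uncertainties[2],
            },
            "residual_rms": self.residual_rms,
            "n_points": self.n_points,
            "converged": self.converged,
        }


def wlc_extension(params: PolymerParams, force, kbt: float = KBT_DEFAULT):
    """Extension per bp (nm/bp) of an extensible WLC at force ``force`` (pN).

    Monotonically increasing in F on (0, S]; diverges (to -inf) as F -> 0,
    so non-positive forces are a domain error.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f <= 0):
        raise ValueError("wlc_extension requires force > 0 (entropic term diverges at F = 0)")
    x_max, a, s = params.as_tuple()
    out = x_max * (1.0 - 1.0 / (2.0 * np.sqrt(f * a / kbt)) + f / s)
    return out if out.ndim else float(out)


def fit_wlc(
    forces,
    extensions,
    kbt: float = KBT_DEFAULT,
    sigma=None,
    p0: PolymerParams | None = None,
) -> WLCFitResult:
    """Fit (x_max, A, S) to force-extension points by least squares.

    Unweighted by default; pass per-point ``sigma`` for a weighted fit.
    Requires at least 4 points spanning a >= 2x force range.
    """
    f = np.asarray(forces, dtype=float)
    x = np.asarray(extensions, dtype=float)
    if f.shape != x.shape:
        raise ValueError("forces and extensions must have the same length")
    if f.size < 4:
        raise ValueError(f"need >= 4 force-extension points, got {f.size}")
    if np.any(f <= 0):
        raise ValueError("forces must be positive")
    if f.max() < 2.0 * f.min():
        raise ValueError("force range must span at least a factor of 2 for identifiability")

    if p0 is None:
        # highest-force extension approximates the contour length
        guess = PolymerParams(float(np.clip(x.max(), 0.11, 0.99)), 10.0, 1000.0)
    else:
        guess = p0

    def model(force, x_max, a, s):
        return x_max * (1.0 - 1.0 / (2.0 * np.sqrt(force * a / kbt)) + force / s)

    try:
        popt, pcov = curve_fit(
            model,
            f,
            x,
            p0=guess.as_tuple(),
            sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=([0.1, 1e-3, 1.0], [1.0, 1e3, 1e5]),
            maxfev=20000,
        )
        converged = np.all(np.isfinite(pcov))
    except RuntimeError:
        # flagged, not silent: return the initial guess marked unconverged
        popt = np.array(guess.as_tuple())
        pcov = np.full((3, 3), np.nan)
        converged = False

    resid = x - model(f, *popt)
    sigmas = tuple(np.sqrt(np.diag(pcov)))
    return WLCFitResult(
        params=PolymerParams(*popt),
        uncertainties=sigmas,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(f.size),
        converged=bool(converged),
        covariance=pcov,
    )


def occupancy_from_extension(x, x_ds: float, x_sat: float, clip: bool = False):
    """Fractional ligand occupancy from complex extension at one force.

    Theta = (x - x_ds) / (x_sat - x_ds); raw (possibly outside [0, 1])
    unless ``clip`` is requested.  Values outside [-0.05, 1.05] trigger a
    warning, as they indicate an inconsistent bare/saturated pair.
    """
    if x_sat <= x_ds:
        raise ValueError("saturated extension must exceed bare-DNA extension")
    theta = (np.asarray(x, dtype=float) - x_ds) / (x_sat - x_ds)
    if np.any((theta < -0.05) | (theta > 1.05)):
        warnings.warn(
            "occupancy outside [-0.05, 1.05]: extension inconsistent with the "
            "bare/saturated reference curves",
            stacklevel=2,
        )
    if clip:
        theta = np.clip(theta, 0.0, 1.0)
    return theta if theta.ndim else float(theta)


def saturation_geometry(
    x_sat_max: float,
    x_ds_max: float,
    site_size_bp: int,
    moieties_per_ligand: int,
) -> float:
    """Per-moiety elongation (nm) implied by saturated contour lengths.

    With one ligand per ``site_size_bp`` base pairs contributing
    ``moieties_per_ligand`` intercalation events, the per-bp contour excess
    (x_sat_max - x_ds_max) converts to an elongation per intercalated
    moiety of (x_sat_max - x_ds_max) * site_size_bp / moieties_per_ligand.
    """
    if site_size_bp <= 0 or moieties_per_ligand <= 0:
        raise ValueError("site_size_bp and moieties_per_ligand must be positive")
    return (x_sat_max - x_ds_max) * site_size_bp / moieties_per_ligand


def fractional_elongation(x_sat_max: float, x_ds_max: float) -> float:
    """Relative contour-length increase (x_sat - x_ds)/x_ds of the saturated complex."""
    if x_ds_max <= 0:
        raise ValueError("bare contour length must be positive")
    return (x_sat_max - x_ds_max) / x_ds_max
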