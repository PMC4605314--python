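"""Synthetic constant-force binding traces and force-extension curves.

Everything the analysis pipeline consumes can be generated here: traces
whose mean path follows the two-step intercalation scheme with
force-scaled rates, saturated force-extension point sets from the WLC,
and the published parameter bundles (see :mod:`threadkin.fixtures`).

Each binding site on the DNA is an independent three-state system
(empty, mono-intercalated, bis-intercalated).  The ``meanfield`` backend
uses the exact solution of the linear mean-field ODE for the state
fractions (P0, P1, P2) starting from ligand-free DNA; the ``gillespie``
backend draws an exact stochastic path of the aggregate site-state
counts, which is statistically identical to simulating n_sites
independent sites.  The extension readout is

    dx(t) = dx_sat(F) * (1/2 * P1 + P2),

i.e. a mono-bound ligand contributes half of the per-site saturated
elongation.  Free ligand concentration is held constant (excess-ligand
flow-cell condition); sites do not interact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fixtures
from .elasticity import KBT_DEFAULT, PolymerParams, wlc_extension
from .kinetics import BellParams, ElementaryRates, rates_at_force
from .trace_model import MONO_EXTENSION_FRACTION, RelaxationParams, Trace

__all__ = [
    "SimulationConfig",
    "saturated_excess_extension",
    "meanfield_occupancies",
    "exact_relaxation_params",
    "simulate_trace",
    "simulate_saturated_curve",
    "published_parameters",
]

published_parameters = fixtures.published_parameters


@dataclass
class SimulationConfig:
    """One constant-force simulated experiment condition.

    Defaults reproduce the study conditions: published zero-force truth,
    600 s at 1 Hz, Gaussian noise of 0.002 nm/bp, no drift, constant free
    ligand concentration.
    """

    force: float
    concentration: float
    truth: dict[str, BellParams] = field(default_factory=fixtures.kinetic_truth)
    duration: float = 600.0
    sample_rate: float = 1.0
    noise_sd: float = 0.002
    drift_rate: float = 0.0
    n_sites: int = 400
    seed: int | None = None
    backend: str = "meanfield"
    kbt: float = KBT_DEFAULT
    polymer_sat: PolymerParams = field(
        default_factory=lambda: fixtures.WLC_PARAMS["dsDNA_flexRu2"].params
    )
    polymer_ds: PolymerParams = field(
        default_factory=lambda: fixtures.WLC_PARAMS["dsDNA"].params
    )

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.backend not in ("meanfield", "gillespie"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.backend == "gillespie" and self.n_sites < 1:
            raise ValueError("gillespie backend needs n_sites >= 1")
        if self.force <= 0:
            raise ValueError("force must be positive (constant-force protocol)")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")

    def rates(self) -> ElementaryRates:
        return rates_at_force(self.truth, self.force, self.kbt)

    def dx_sat(self) -> float:
        return saturated_excess_extension(
            self.force, self.polymer_sat, self.polymer_ds, self.kbt
        )

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration * self.sample_rate)) + 1
        return np.arange(n) / self.sample_rate


def saturated_excess_extension(
    force: float,
    polymer_sat: PolymerParams | None = None,
    polymer_ds: PolymerParams | None = None,
    kbt: float = KBT_DEFAULT,
) -> float:
    """dx_sat(F) = x_sat(F) - x_ds(F), nm/bp, from the two WLC curves."""
    if polymer_sat is None:
        polymer_sat = fixtures.WLC_PARAMS["dsDNA_flexRu2"].params
    if polymer_ds is None:
        polymer_ds = fixtures.WLC_PARAMS["dsDNA"].params
    return wlc_extension(polymer_sat, force, kbt) - wlc_extension(polymer_ds, force, kbt)


def _relaxation_matrix(rates: ElementaryRates, concentration: float):
    """Linear system dv/dt = A v + b for v = (P1, P2), with P0 = 1 - P1 - P2."""
    a1 = rates.k1 * concentration
    mat = np.array(
        [
            [-(a1 + rates.k_m1 + rates.k2), rates.k_m2 - a1],
            [rates.k2, -rates.k_m2],
        ]
    )
    b = np.array([a1, 0.0])
    return mat, b


def meanfield_occupancies(
    rates: ElementaryRates, concentration: float, times
) -> np.ndarray:
    """State fractions (P0, P1, P2) of the mean-field scheme, shape (n, 3).

    Exact solution of the linear ODE starting from (1, 0, 0), via
    eigen-decomposition of the 2x2 reduced system.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    mat, b = _relaxation_matrix(rates, concentration)
    if concentration == 0 and rates.k2 == 0:
        # nothing ever binds; avoid a singular steady-state solve
        p1 = np.zeros_like(t)
        p2 = np.zeros_like(t)
    else:
        v_star = np.linalg.solve(mat, -b)
        evals, evecs = np.linalg.eig(mat)
        coef = np.linalg.solve(evecs, -v_star)  # v(0) = (0, 0)
        modes = np.exp(np.outer(t, evals)) * coef  # (n, 2)
        v = v_star[None, :] + modes @ evecs.T
        p1, p2 = v[:, 0].real, v[:, 1].real
    p0 = 1.0 - p1 - p2
    return np.column_stack([p0, p1, p2])


def exact_relaxation_params(
    rates: ElementaryRates, concentration: float, dx_sat: float
) -> RelaxationParams:
    """Bi-exponential parameters of the exact mean-field extension path.

    Projects the eigen-solution onto the extension readout
    w = (1/2, 1) so that dx(t) = dx_eq - dx_f e^{-k_f t} - dx_s e^{-k_s t}
    holds exactly (to numerical precision).
    """
    mat, b = _relaxation_matrix(rates, concentration)
    v_star = np.linalg.solve(mat, -b)
    evals, evecs = np.linalg.eig(mat)
    coef = np.linalg.solve(evecs, -v_star)
    w = np.array([MONO_EXTENSION_FRACTION, 1.0])
    dx_eq = dx_sat * float(w @ v_star)
    # dx(t) = dx_eq + dx_sat * sum_i (w . u_i) c_i e^{eval_i t}
    amps = -dx_sat * (w @ evecs) * coef  # amplitude of each e^{-lambda t} term
    lams = -evals.real
    order = np.argsort(lams)[::-1]  # fast first
    lam_f, lam_s = lams[order]
    a_f, a_s = np.real(amps[order])
    return RelaxationParams(
        dx_eq=dx_eq, dx_f=max(a_f, 0.0), dx_s=max(a_s, 0.0), k_f=lam_f, k_s=lam_s
    )


def _gillespie_occupancy(
    rates: ElementaryRates,
    concentration: float,
    times: np.ndarray,
    n_sites: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact stochastic path of the site-average extension fraction.

    Event-driven simulation of the aggregate counts (n0, n1, n2) of
    independent identical three-state sites; returns
    (1/2 * n1 + n2)/n_sites sampled at ``times``.
    """
    a1 = rates.k1 * concentration
    n0, n1, n2 = n_sites, 0, 0
    t = 0.0
    out = np.empty(times.size)
    idx = 0
    t_end = times[-1]
    while True:
        r01 = n0 * a1
        r10 = n1 * rates.k_m1
        r12 = n1 * rates.k2
        r21 = n2 * rates.k_m2
        total = r01 + r10 + r12 + r21
        t_next = t + rng.exponential(1.0 / total) if total > 0 else np.inf
        while idx < times.size and times[idx] < t_next:
            out[idx] = (MONO_EXTENSION_FRACTION * n1 + n2) / n_sites
            idx += 1
        if idx >= times.size or t_next > t_end:
            break
        t = t_next
        u = rng.random() * total
        if u < r01:
            n0 -= 1
            n1 += 1
        elif u < r01 + r10:
            n1 -= 1
            n0 += 1
        elif u < r01 + r10 + r12:
            n1 -= 1
            n2 += 1
        else:
            n2 -= 1
            n1 += 1
        assert n0 >= 0 and n1 >= 0 and n2 >= 0 and n0 + n1 + n2 == n_sites
    while idx < times.size:
        out[idx] = (MONO_EXTENSION_FRACTION * n1 + n2) / n_sites
        idx += 1
    return out


def simulate_trace(cfg: SimulationConfig) -> Trace:
    """Simulate one constant-force excess-extension trace.

    Reproducible under a fixed seed; identical config + seed gives a
    bit-identical trace.
    """
    rng = np.random.default_rng(cfg.seed)
    times = cfg.time_grid()
    rates = cfg.rates()
    dx_sat = cfg.dx_sat()
    if cfg.concentration == 0:
        mean = np.zeros_like(times)
    elif cfg.backend == "meanfield":
        occ = meanfield_occupancies(rates, cfg.concentration, times)
        mean = dx_sat * (MONO_EXTENSION_FRACTION * occ[:, 1] + occ[:, 2])
    else:
        mean = dx_sat * _gillespie_occupancy(
            rates, cfg.concentration, times, cfg.n_sites, rng
        )
    dx = mean.copy()
    if cfg.noise_sd > 0:
        dx = dx + rng.normal(0.0, cfg.noise_sd, size=times.size)
    if cfg.drift_rate != 0.0:
        dx = dx + cfg.drift_rate * times
    metadata = {
        "seed": cfg.seed,
        "backend": cfg.backend,
        "noise_sd": cfg.noise_sd,
        "drift_rate": cfg.drift_rate,
        "dx_sat": dx_sat,
        "kbt": cfg.kbt,
    }
    return Trace(
        times=times,
        extensions=dx,
        force=cfg.force,
        concentration=cfg.concentration,
        metadata=metadata,
    )


def simulate_saturated_curve(
    params: PolymerParams,
    forces,
    noise_sd: float = 0.0,
    seed: int | None = None,
    kbt: float = KBT_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Force-extension points of a saturated complex: WLC plus noise.

    Returns (forces, extensions) arrays; extension noise is Gaussian with
    standard deviation ``noise_sd`` (nm/bp).
    """
    f = np.asarray(forces, dtype=float)
    if np.any(f <= 0):
        raise ValueError("forces must be positive (WLC domain)")
    x = np.asarray(wlc_extension(params, f, kbt), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=f.shape)
    return f, x
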