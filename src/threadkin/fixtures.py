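"""Published parameter sets used as generator truth and reference values.

``WLC_PARAMS`` holds the WLC fit parameters of the four polymer species
(bare dsDNA, dsDNA saturated with the mono-intercalator, dsDNA saturated
with the flexibly linked Ru dimer, and ssDNA).  The remaining bundles hold the
zero-force kinetic and equilibrium parameter sets of the two-step
intercalation scheme, each value with its published uncertainty.  These
are measured quantities, not reproducible without the raw tweezers data;
the package uses them as synthetic-data truth and as fixture values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .elasticity import PolymerParams
from .kinetics import BellParams, ElementaryRates, EquilibriumForceLaw


@dataclass(frozen=True)
class ValueWithError:
    value: float
    error: float


@dataclass(frozen=True)
class PolymerRow:
    params: PolymerParams
    #: 1-sigma uncertainties of (contour_per_bp, persistence, stretch_modulus)
    errors: tuple[float, float, float]


@dataclass(frozen=True)
class BellRow:
    """One rate row: zero-force rate, transition distance, both with errors."""

    k0: ValueWithError
    x_dagger: ValueWithError

    @property
    def bell(self) -> BellParams:
        return BellParams(k0=self.k0.value, x_dagger=self.x_dagger.value)


@dataclass(frozen=True)
class ForceLawRow:
    """One equilibrium-constant row: zero-force value and elongation, with errors."""

    K0: ValueWithError
    x0: ValueWithError

    @property
    def law(self) -> EquilibriumForceLaw:
        return EquilibriumForceLaw(K0=self.K0.value, x0=self.x0.value)


WLC_PARAMS: dict[str, PolymerRow] = {
    "dsDNA": PolymerRow(PolymerParams(0.340, 47.0, 1270.0), (0.001, 2.0, 200.0)),
    "dsDNA_Ru1": PolymerRow(PolymerParams(0.41, 14.3, 320.0), (0.01, 0.8, 17.0)),
    "dsDNA_flexRu2": PolymerRow(PolymerParams(0.49, 2.9, 800.0), (0.01, 0.8, 50.0)),
    "ssDNA": PolymerRow(PolymerParams(0.680, 1.2, 1220.0), (0.002, 0.1, 70.0)),
}

#: Zero-force elementary rates and transition distances (kinetic route).
#: k1 in nM^-1 s^-1, others s^-1; distances in nm.
RATE_PARAMS: dict[str, BellRow] = {
    "k1": BellRow(ValueWithError(1.8e-3, 0.4e-3), ValueWithError(0.19, 0.02)),
    "k_m1": BellRow(ValueWithError(68e-3, 4e-3), ValueWithError(-0.06, 0.01)),
    "k2": BellRow(ValueWithError(5.8e-3, 1.0e-3), ValueWithError(0.08, 0.01)),
    "k_m2": BellRow(ValueWithError(3.6e-3, 1.0e-3), ValueWithError(-0.15, 0.03)),
}

#: Zero-force equilibrium constants (Kd, Kd1 in nM; K2 dimensionless) from
#: the kinetic route (force-law fits of rate-derived constants) ...
KINETIC_ROUTE_CONSTANTS: dict[str, ForceLawRow] = {
    "Kd": ForceLawRow(ValueWithError(15.0, 6.0), ValueWithError(0.44, 0.04)),
    "Kd1": ForceLawRow(ValueWithError(35.0, 9.0), ValueWithError(0.24, 0.02)),
    "K2": ForceLawRow(ValueWithError(1.8, 0.6), ValueWithError(0.22, 0.03)),
}

#: ... and from the independent equilibrium-amplitude route.
AMPLITUDE_ROUTE_CONSTANTS: dict[str, ForceLawRow] = {
    "Kd": ForceLawRow(ValueWithError(4.1, 1.4), ValueWithError(0.33, 0.04)),
    "Kd1": ForceLawRow(ValueWithError(11.0, 4.0), ValueWithError(0.25, 0.04)),
    "K2": ForceLawRow(ValueWithError(2.7, 0.8), ValueWithError(0.08, 0.05)),
}

#: Ligand geometry at saturation: one ligand per 4 bp, two intercalating
#: moieties per ligand.
SITE_SIZE_BP = 4
MOIETIES_PER_LIGAND = 2

#: Experimental condition grid of the constant-force protocol.
FORCES_PN = (20.0, 30.0, 50.0)
CONCENTRATIONS_NM = (1.0, 3.0, 5.0, 7.0)


def kinetic_truth() -> dict[str, BellParams]:
    """The four zero-force Bell laws of the kinetic parameter set."""
    return {name: row.bell for name, row in RATE_PARAMS.items()}


def zero_force_rates() -> ElementaryRates:
    """Zero-force elementary rates of the kinetic parameter set."""
    return ElementaryRates(
        k1=RATE_PARAMS["k1"].k0.value,
        k_m1=RATE_PARAMS["k_m1"].k0.value,
        k2=RATE_PARAMS["k2"].k0.value,
        k_m2=RATE_PARAMS["k_m2"].k0.value,
        force=0.0,
    )


@dataclass(frozen=True)
class PublishedParameters:
    wlc: dict[str, PolymerRow]
    rates: dict[str, BellRow]
    kinetic_constants: dict[str, ForceLawRow]
    amplitude_constants: dict[str, ForceLawRow]
    site_size_bp: int
    moieties_per_ligand: int
    forces: tuple[float, ...]
    concentrations: tuple[float, ...]


def published_parameters() -> PublishedParameters:
    """All published parameter bundles as one typed record."""
    return PublishedParameters(
        wlc=dict(WLC_PARAMS),
        rates=dict(RATE_PARAMS),
        kinetic_constants=dict(KINETIC_ROUTE_CONSTANTS),
        amplitude_constants=dict(AMPLITUDE_ROUTE_CONSTANTS),
        site_size_bp=SITE_SIZE_BP,
        moieties_per_ligand=MOIETIES_PER_LIGAND,
        forces=FORCES_PN,
        concentrations=CONCENTRATIONS_NM,
    )
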