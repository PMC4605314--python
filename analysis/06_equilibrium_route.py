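"""Binding constants by two independent routes, and their consistency.

Kinetic route: equilibrium constants from the decomposed elementary
rates per force, extrapolated to zero force with the exponential force
law.  Equilibrium route: occupancy-isotherm and amplitude-ratio fits of
the same traces' equilibrium amplitudes.  Writes the per-force constants,
zero-force force-law fits, and a side-by-side consistency report.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from threadkin.inference import consistency_report, equilibrium_route, fit_force_law
from threadkin.kinetics import ElementaryRates, equilibrium_from_rates
from threadkin.synthetic import saturated_excess_extension

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--rates", type=Path, default=RESULTS / "rates_per_force.json")
    parser.add_argument("--trace-fits", type=Path, default=RESULTS / "trace_fits.csv")
    parser.add_argument("--out", type=Path, default=RESULTS / "equilibrium.json")
    args = parser.parse_args()

    # kinetic route: K(F) from rates, then log-linear force laws
    per_force = json.loads(args.rates.read_text())
    const_rows = {"Kd": [], "Kd1": [], "K2": []}
    for dec in per_force.values():
        rates = ElementaryRates(**dec["rates"])
        eq = equilibrium_from_rates(rates)
        for name, value in (("Kd", eq.Kd), ("Kd1", eq.Kd1), ("K2", eq.K2)):
            const_rows[name].append((rates.force, value))
    kinetic_laws = {n: fit_force_law(rows) for n, rows in const_rows.items()}

    # equilibrium route: occupancy and amplitude-ratio fits of the amplitudes
    fits = pd.read_csv(args.trace_fits)
    occupancy, ratios = {}, {}
    for force, sub in fits.groupby("force_pN"):
        dx_sat = saturated_excess_extension(force)
        occupancy[force] = (sub["conc_nM"].to_numpy(),
                            (sub["dx_eq"] / dx_sat).to_numpy())
        ratios[force] = (sub["conc_nM"].to_numpy(),
                         (sub["dx_f"] / sub["dx_s"]).to_numpy())
    eq_result = equilibrium_route(occupancy, ratios)

    kin = {n: (law.law.K0, law.uncertainties["K0"]) for n, law in kinetic_laws.items()}
    eqd = {n: (law.law.K0, law.uncertainties["K0"]) for n, law in eq_result.laws.items()}
    report = consistency_report(kin, eqd)

    payload = {
        "kinetic_laws": {n: law.to_dict() for n, law in kinetic_laws.items()},
        "equilibrium_laws": {n: law.to_dict() for n, law in eq_result.laws.items()},
        "per_force_equilibrium": eq_result.per_force.to_dict(orient="records"),
        "consistency": report.reset_index().to_dict(orient="records"),
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(payload, indent=2))
    print(report.to_string())
    print(f"\nequilibrium analysis -> {args.out}")


if __name__ == "__main__":
    main()
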