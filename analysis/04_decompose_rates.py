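"""Elementary two-step rates from the concentration series at each force.

Reads results/trace_fits.csv and decomposes (k_f, k_s) versus ligand
concentration into (k1, k-1, k2, k-2) per force, fitting the exact
eigenvalue relations of the two-step scheme; also reports the
pre-equilibrium quality ratio per condition.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from threadkin.inference import ConditionSeries, decompose_rates

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--trace-fits", type=Path, default=RESULTS / "trace_fits.csv")
    parser.add_argument("--out", type=Path, default=RESULTS / "rates_per_force.json")
    args = parser.parse_args()

    fits = pd.read_csv(args.trace_fits)
    payload = {}
    for force, sub in fits.groupby("force_pN"):
        series = ConditionSeries(
            force=force,
            concentrations=sub["conc_nM"].to_numpy(),
            k_f=sub["k_f"].to_numpy(),
            k_s=sub["k_s"].to_numpy(),
            sigma_k_f=sub["k_f_err"].to_numpy(),
            sigma_k_s=sub["k_s_err"].to_numpy(),
        )
        dec = decompose_rates(series, method="exact")
        payload[f"F{force:g}"] = dec.to_dict()
        r = dec.rates
        print(f"F = {force:g} pN: k1 {r.k1:.3e} nM^-1 s^-1, k-1 {r.k_m1:.3e} s^-1, "
              f"k2 {r.k2:.3e} s^-1, k-2 {r.k_m2:.3e} s^-1 "
              f"(pre-eq ratio {min(dec.preequilibrium_ratios.values()):.1f}-"
              f"{max(dec.preequilibrium_ratios.values()):.1f})")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(payload, indent=2))
    print(f"\nrates -> {args.out}")


if __name__ == "__main__":
    main()
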