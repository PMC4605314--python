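"""Zero-force free-energy landscape of the two-step intercalation.

Builds the five-state profile (non-intercalated, TS1, mono, TS2, bis)
versus complex elongation from the published zero-force rates, distances
and binding constants, at the reference concentration C = Kd = 15 nM and
at C = Kd1 = 35 nM, with attempt rate 1 s^-1.  Writes the landscape
tables under results/.
"""

import argparse
from pathlib import Path

from threadkin import fixtures, io_text
from threadkin.landscape import LandscapeSpec, build_landscape

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--attempt-rate", type=float, default=1.0)
    parser.add_argument("--out-dir", type=Path, default=RESULTS)
    args = parser.parse_args()

    rates0 = fixtures.zero_force_rates()
    distances = {n: row.x_dagger.value for n, row in fixtures.RATE_PARAMS.items()}
    kd = fixtures.KINETIC_ROUTE_CONSTANTS["Kd"].K0.value
    kd1 = fixtures.KINETIC_ROUTE_CONSTANTS["Kd1"].K0.value

    args.out_dir.mkdir(parents=True, exist_ok=True)
    for conc in (kd, kd1):
        spec = LandscapeSpec(rates0=rates0, distances=distances, Kd=kd, Kd1=kd1,
                             concentration=conc, attempt_rate=args.attempt_rate)
        landscape = build_landscape(spec)
        path = io_text.write_landscape(
            args.out_dir / f"landscape_C{conc:g}nM.txt", landscape)
        print(f"C = {conc:g} nM (attempt rate {args.attempt_rate:g} s^-1):")
        for s in landscape.states:
            print(f"  {s.label:5s} elongation {s.elongation:5.2f} nm  "
                  f"energy {s.energy:6.2f} kBT")
        print(f"  -> {path}")


if __name__ == "__main__":
    main()
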