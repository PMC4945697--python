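#!/usr/bin/env python
"""Descending-aorta flow split: simulation vs PC-MRI-style measurements.

Runs the baseline dissected network with the synthetic inflow, extracts the
true/false-lumen mean flows at the three descending stations, and builds two
comparison tables:

* the surrogate simulation against the reference measurement set, and
* the reference CFD constants (51.4/38.7/12.7 cm^3/s) against the same
  measurements — reproducing the published error arithmetic exactly.

Writes results/comparison_surrogate.csv and results/comparison_reference.csv.
"""

from pathlib import Path

from dissectflow.compare import (REFERENCE_SIMULATED_MEANS,
                                 build_comparison_report,
                                 load_reference_measurements)
from dissectflow.network import build_network, lumen_flow_split, simulate
from dissectflow.synthetic import InflowSpec, fixture_configs, generate_inflow

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    measurements = load_reference_measurements()
    inflow = generate_inflow(InflowSpec())

    topo = build_network(fixture_configs()["dissected_baseline"])
    sol = simulate(topo, inflow)
    print(f"baseline dissected network converged in {sol.n_cycles} cycles")
    for station in ("proximal", "medial", "distal"):
        s = lumen_flow_split(sol, station)
        print(f"  {station:8s}: TL {s['fraction_TL']:4.1f} % / "
              f"FL {s['fraction_FL']:4.1f} %  (total {s['total'] / 1000:.1f} cm^3/s)")

    surrogate = build_comparison_report(sol, measurements)
    surrogate.to_csv(OUT / "comparison_surrogate.csv")
    print("\nsurrogate vs measurements (three-station average errors, %):")
    for lumen, err in surrogate.average_errors.items():
        print(f"  {lumen:6s}: {err:+6.1f}")

    reference = build_comparison_report(REFERENCE_SIMULATED_MEANS, measurements)
    reference.to_csv(OUT / "comparison_reference.csv")
    print("\nreference CFD constants vs measurements (per station, %):")
    print(reference.display().to_string(index=False))
    for lumen in ("TL", "FL"):
        fm = reference.fractions_measured[lumen]
        fs = reference.fractions_simulated[lumen]
        print(f"{lumen} fraction: measured {fm.display} % ({fm.value:.1f}), "
              f"simulated {fs.display} % ({fs.value:.1f})")


if __name__ == "__main__":
    main()
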