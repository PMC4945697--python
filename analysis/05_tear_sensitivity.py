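#!/usr/bin/env python
"""Sensitivity of the haemodynamics to the number of connecting tears.

Simulates the baseline dissected network (17 tears), the minimal-tears
variant (entry and exit only) and the maximal-tears variant (two extra
thoracic tears) with the same inflow, and tabulates mean/peak lumen flows
and peak pressures at the probe just proximal to the coeliac trunk, plus the
largest instantaneous interluminal pressure difference per variant.

Writes results/tear_sensitivity.csv.
"""

from pathlib import Path

import numpy as np

from dissectflow.network import build_network, simulate, tear_sensitivity_study
from dissectflow.synthetic import InflowSpec, fixture_configs, generate_inflow

OUT = Path(__file__).resolve().parents[1] / "results"


def max_interluminal_dp(sol) -> float:
    return max(float(np.abs(sol.node_pressure[f"tl{i}"].values
                            - sol.node_pressure[f"fl{i}"].values).max())
               for i in range(1, 7))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    inflow = generate_inflow(InflowSpec())
    cfgs = fixture_configs()

    study = tear_sensitivity_study(
        cfgs["dissected_baseline"],
        {"minimal_tears": cfgs["minimal_tears"],
         "maximal_tears": cfgs["maximal_tears"]},
        inflow,
    )
    study.to_csv(OUT / "tear_sensitivity.csv")

    print("changes at the visceral probe relative to the 17-tear baseline (%):")
    cols = ["TL_mean_flow_pct_change", "TL_peak_flow_pct_change",
            "TL_peak_pressure_pct_change", "FL_mean_flow_pct_change"]
    print(study[cols].round(2).to_string())

    print("\nlargest interluminal pressure difference (mmHg):")
    for name in ("minimal_tears", "dissected_baseline", "maximal_tears"):
        sol = simulate(build_network(cfgs[name]), inflow)
        print(f"  {name:20s}: {max_interluminal_dp(sol) / 133.32:.3f}")
    print("\nremoving the secondary tears forces the visceral demand through "
          "the narrow true lumen (TL flow up, TL peak pressure down), while "
          "adding thoracic tears barely perturbs the baseline.")


if __name__ == "__main__":
    main()
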