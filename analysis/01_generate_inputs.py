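#!/usr/bin/env python
"""Generate every input the downstream analyses consume.

Writes the synthetic PC-MRI-like aortic inflow (stroke volume 94 mL, period
1.3 s, 25 gated phases), the reference per-lumen descending-aorta
measurement set, and the four network fixture configurations to
results/inputs/.
"""

from pathlib import Path

import yaml

from dissectflow.synthetic import (InflowSpec, fixture_configs,
                                   generate_inflow, generate_measurements,
                                   reference_measurement_spec)
from dissectflow.waveform import write_waveform_csv

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    inflow = generate_inflow(InflowSpec())
    write_waveform_csv(inflow, OUT / "inflow.csv")
    print(f"inflow: net volume {inflow.integral():.1f} mm^3 per beat, "
          f"mean {inflow.mean():.1f} mm^3/s, peak {inflow.metrics()['peak']:.0f}")

    measurements = generate_measurements(reference_measurement_spec())
    measurements.to_frame().to_csv(OUT / "measurements.csv", index=False)
    print(f"measurements: totals "
          f"{[round(measurements.total[l] / 1000, 1) for l in measurements.locations]}"
          " cm^3/s at proximal/medial/distal")

    for name, cfg in fixture_configs().items():
        (OUT / f"{name}.yaml").write_text(yaml.safe_dump(cfg))
        print(f"fixture {name}: {len(cfg.get('tears', []))} tears, "
              f"{len(cfg['outlets'])} outlets")


if __name__ == "__main__":
    main()
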