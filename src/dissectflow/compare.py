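"""Measurement-vs-simulation comparison arithmetic.

Per-lumen cycle-mean flows measured by 2D PC-MRI at three descending-aorta
stations (proximal, medial, distal) are compared against simulated means:
signed relative errors per station and lumen, three-station averages, and
the true/false-lumen flow fractions.  Fractions are reported both as the
ratio of three-station means (the display convention) and as the mean of
per-station ratios.

Display rounding follows clinical reporting practice — one decimal for
percent errors, integers for lumen fractions — while unrounded values are
retained in the data model, so reports are exactly reproducible yet lossless.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "LOCATIONS",
    "LumenMeasurementSet",
    "ComparisonReport",
    "relative_error",
    "lumen_fraction",
    "FractionResult",
    "build_comparison_report",
    "load_reference_measurements",
    "REFERENCE_SIMULATED_MEANS",
]

LOCATIONS = ("proximal", "medial", "distal")

#: Demonstration simulated descending-aorta means (mm^3/s) accompanying the
#: reference clinical measurement set: the reference CFD study predicted
#: uniform means across the three stations.
REFERENCE_SIMULATED_MEANS = {
    loc: {"TL": 12700.0, "FL": 38700.0, "total": 51400.0} for loc in LOCATIONS
}


@dataclass
class LumenMeasurementSet:
    """Cycle-mean flows (mm^3/s) per station for true lumen, false lumen and
    their total; totals are recomputed as TL + FL when not supplied and
    checked for 1 % consistency when they are."""

    tl: dict[str, float]
    fl: dict[str, float]
    total: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if set(self.tl) != set(self.fl):
            raise ValueError("TL and FL must cover the same locations")
        if any(v < 0 for v in (*self.tl.values(), *self.fl.values())):
            raise ValueError("mean flows must be non-negative")
        sums = {loc: self.tl[loc] + self.fl[loc] for loc in self.tl}
        if self.total is None:
            self.total = sums
        else:
            for loc, tot in self.total.items():
                if abs(tot - sums[loc]) > 0.01 * tot:
                    raise ValueError(
                        f"{loc}: total {tot} inconsistent with TL+FL {sums[loc]}"
                    )

    @property
    def locations(self) -> tuple:
        return tuple(self.tl)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for loc in self.locations:
            for lumen, values in (("TL", self.tl), ("FL", self.fl),
                                  ("total", self.total)):
                rows.append({"location": loc, "lumen": lumen,
                             "mean_flow_mm3_s": values[loc]})
        return pd.DataFrame(rows)

    @classmethod
    def from_csv(cls, path) -> "LumenMeasurementSet":
        table = pd.read_csv(path)
        by_lumen = {
            lumen: {r.location: float(r.mean_flow_mm3_s)
                    for r in table.itertuples() if r.lumen == lumen}
            for lumen in ("TL", "FL", "total")
        }
        return cls(tl=by_lumen["TL"], fl=by_lumen["FL"],
                   total=by_lumen["total"] or None)


def load_reference_measurements() -> LumenMeasurementSet:
    """Packaged PC-MRI descending-aorta measurement set (three stations)."""
    src = resources.files("dissectflow.data") / "descending_flow_measurements.csv"
    with resources.as_file(src) as p:
        return LumenMeasurementSet.from_csv(p)


def relative_error(sim: float, meas: float) -> float:
    """Signed percent error ``100 (sim - meas) / meas``."""
    if meas == 0:
        raise ValueError("measured value must be nonzero")
    return 100.0 * (sim - meas) / meas


@dataclass(frozen=True)
class FractionResult:
    value: float            # ratio of means, percent, unrounded
    display: int            # rounded for display
    mean_of_ratios: float   # alternative convention, percent


def lumen_fraction(lumen_means, total_means) -> FractionResult:
    """Share of total flow carried by one lumen, percent.

    Primary convention: ratio of the across-station means.  The mean of
    per-station ratios is reported alongside.
    """
    lumen = np.asarray(list(lumen_means), dtype=float)
    total = np.asarray(list(total_means), dtype=float)
    if lumen.size != total.size:
        raise ValueError("lumen and total lists must have equal length")
    value = 100.0 * lumen.mean() / total.mean()
    mor = float(np.mean(100.0 * lumen / total))
    return FractionResult(value=value, display=round(value), mean_of_ratios=mor)


@dataclass
class ComparisonReport:
    """Per-station, per-lumen measured vs simulated means with errors."""

    table: pd.DataFrame                     # location, lumen, measured, simulated, rel_error_pct
    average_errors: dict[str, float]        # lumen -> mean error over stations
    fractions_measured: dict[str, FractionResult]
    fractions_simulated: dict[str, FractionResult]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["rel_error_pct_display"] = out["rel_error_pct"].round(1)
        out.to_csv(path, index=False, lineterminator="\n")

    def display(self) -> pd.DataFrame:
        """Rounded view in cm^3/s: one decimal on errors, as conventionally
        printed."""
        out = self.table.copy()
        out["measured_cm3_s"] = (out.pop("measured") / 1000).round(1)
        out["simulated_cm3_s"] = (out.pop("simulated") / 1000).round(1)
        out["rel_error_pct"] = out["rel_error_pct"].round(1)
        return out


def _simulated_means(simulated, measurements: LumenMeasurementSet,
                     station_map: dict | None) -> dict:
    """Normalise the simulated input to {location: {TL, FL, total}} (mm^3/s)."""
    if hasattr(simulated, "element_flow"):  # NetworkSolution duck type
        from .network import lumen_flow_split
        if station_map is None:
            station_map = {loc: loc for loc in measurements.locations}
        out = {}
        for loc in measurements.locations:
            if loc not in station_map:
                raise KeyError(f"measurement location {loc!r} not mapped to a probe")
            split = lumen_flow_split(simulated, station_map[loc])
            out[loc] = {"TL": split["Q_TL"], "FL": split["Q_FL"],
                        "total": split["total"]}
        return out
    out = {}
    for loc in measurements.locations:
        if loc not in simulated:
            raise KeyError(f"no simulated values for location {loc!r}")
        entry = dict(simulated[loc])
        entry.setdefault("total", entry["TL"] + entry["FL"])
        out[loc] = entry
    return out


def build_comparison_report(simulated, measurements: LumenMeasurementSet,
                            station_map: dict | None = None) -> ComparisonReport:
    """Full comparison table from simulated means and a measurement set.

    ``simulated`` is either a network solution (probed through
    ``station_map``: measurement location -> probe station) or a plain mapping
    ``{location: {"TL": q, "FL": q[, "total": q]}}`` in mm^3/s.
    """
    sim = _simulated_means(simulated, measurements, station_map)
    rows = []
    for loc in measurements.locations:
        meas = {"TL": measurements.tl[loc], "FL": measurements.fl[loc],
                "total": measurements.total[loc]}
        for lumen in ("TL", "FL", "total"):
            rows.append({
                "location": loc, "lumen": lumen,
                "measured": meas[lumen], "simulated": sim[loc][lumen],
                "rel_error_pct": relative_error(sim[loc][lumen], meas[lumen]),
            })
    table = pd.DataFrame(rows)
    average_errors = {
        lumen: float(table.loc[table.lumen == lumen, "rel_error_pct"].mean())
        for lumen in ("TL", "FL", "total")
    }
    locs = measurements.locations
    fractions_measured = {
        "TL": lumen_fraction([measurements.tl[l] for l in locs],
                             [measurements.total[l] for l in locs]),
        "FL": lumen_fraction([measurements.fl[l] for l in locs],
                             [measurements.total[l] for l in locs]),
    }
    fractions_simulated = {
        "TL": lumen_fraction([sim[l]["TL"] for l in locs],
                             [sim[l]["total"] for l in locs]),
        "FL": lumen_fraction([sim[l]["FL"] for l in locs],
                             [sim[l]["total"] for l in locs]),
    }
    return ComparisonReport(table=table, average_errors=average_errors,
                            fractions_measured=fractions_measured,
                            fractions_simulated=fractions_simulated)
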