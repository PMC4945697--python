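"""Synthetic inputs emulating the study's patient data.

Every input the pipeline consumes can be generated here without any
download:

* a gated PC-MRI-like aortic inflow waveform (stroke volume 94 mL, period
  1.3 s i.e. 47 beats/min, 25 phases at 52 ms, half-sine systolic pulse with
  an optional early-diastolic backflow lobe),
* per-lumen descending-aorta "measurements" (the reference clinical mean
  levels, optionally perturbed by seeded multiplicative noise),
* the four network fixture configurations (undissected, baseline dissected
  with 17 tears, maximal tears with 19, minimal tears with 2), and
* a single-Windkessel afterload for stand-alone heart experiments.

All generators are pure functions of their specification (and seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compare import LumenMeasurementSet, load_reference_measurements
from .waveform import Waveform
from .windkessel import WindkesselParams

__all__ = [
    "InflowSpec",
    "MeasurementSpec",
    "generate_inflow",
    "generate_measurements",
    "reference_measurement_spec",
    "fixture_configs",
    "single_rcr_afterload",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("undissected", "dissected_baseline", "maximal_tears",
                 "minimal_tears")


# ---------------------------------------------------------------------------
# inflow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InflowSpec:
    """Aortic-root inflow specification (canonical units)."""

    stroke_volume: float = 94_000.0   # mm^3 per beat
    period: float = 1.3               # s (47 beats/min)
    systolic_fraction: float = 0.33   # ejection duration / period
    backflow_fraction: float = 0.0    # early-diastolic reverse volume / SV
    n_samples: int = 25               # gated phases (52 ms at the defaults)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stroke_volume <= 0 or self.period <= 0:
            raise ValueError("stroke volume and period must be positive")
        if not (0 < self.systolic_fraction < 1):
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if self.backflow_fraction < 0:
            raise ValueError("backflow_fraction must be non-negative")
        if self.backflow_fraction >= 1.0:
            raise ValueError("backflow volume must be smaller than the "
                             "forward volume")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")


def generate_inflow(spec: InflowSpec = InflowSpec()) -> Waveform:
    """Synthesise the periodic aortic inflow waveform.

    Half-sine forward pulse over the systolic window, optional negative
    half-sine lobe immediately after it carrying ``backflow_fraction`` of the
    stroke volume, zero elsewhere.  The sampled waveform is renormalised so
    its trapezoid net integral equals the stroke volume exactly.
    """
    T = spec.period
    t_sys = spec.systolic_fraction * T
    times = np.linspace(0.0, T, spec.n_samples, endpoint=False)

    forward = np.where(times <= t_sys,
                       np.sin(np.pi * np.minimum(times, t_sys) / t_sys), 0.0)
    t_back = 0.4 * t_sys  # duration of the early-diastolic reverse lobe
    in_back = (times > t_sys) & (times <= t_sys + t_back)
    backward = np.where(in_back, -np.sin(np.pi * (times - t_sys) / t_back), 0.0)

    def _integral(vals: np.ndarray) -> float:
        return Waveform(times, vals, T).integral()

    i_fwd = _integral(forward)
    target_back = spec.backflow_fraction * spec.stroke_volume
    if target_back > 0:
        i_back = -_integral(backward)
        if i_back <= 0:
            raise ValueError("backflow lobe unresolved on this sample grid; "
                             "increase n_samples")
        backward *= target_back / i_back
    else:
        backward[:] = 0.0
    forward *= (spec.stroke_volume + target_back) / i_fwd
    return Waveform(times, forward + backward, T)


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementSpec:
    """Per-lumen mean-flow levels (mm^3/s) plus multiplicative noise.

    ``total_means`` may be given when the reported totals carry their own
    (rounded) values rather than being exactly TL + FL; left ``None``, totals
    are recomputed from the lumen means.
    """

    tl_means: dict
    fl_means: dict
    total_means: dict | None = None
    noise_sd: float = 0.0   # relative s.d. of the multiplicative noise
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in (*self.tl_means.values(), *self.fl_means.values())):
            raise ValueError("mean levels must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def reference_measurement_spec(noise_sd: float = 0.0,
                               seed: int = 0) -> MeasurementSpec:
    """Specification whose noiseless output is the packaged clinical set."""
    ref = load_reference_measurements()
    return MeasurementSpec(tl_means=dict(ref.tl), fl_means=dict(ref.fl),
                           total_means=dict(ref.total),
                           noise_sd=noise_sd, seed=seed)


def generate_measurements(spec: MeasurementSpec) -> LumenMeasurementSet:
    """Draw one measurement set.

    Lumen means receive independent multiplicative Gaussian perturbations;
    reported totals, when specified, are scaled by the same relative change
    as TL + FL so the set stays internally consistent (and exact at zero
    noise).
    """
    rng = np.random.default_rng(spec.seed)

    def perturb(means: dict) -> dict:
        out = {}
        for loc, m in means.items():
            factor = (1.0 + spec.noise_sd * rng.standard_normal()
                      if spec.noise_sd else 1.0)
            out[loc] = m * max(factor, 0.0)
        return out

    tl, fl = perturb(spec.tl_means), perturb(spec.fl_means)
    totals = None
    if spec.total_means is not None:
        totals = {
            loc: spec.total_means[loc] * (tl[loc] + fl[loc])
            / (spec.tl_means[loc] + spec.fl_means[loc])
            for loc in spec.total_means
        }
    return LumenMeasurementSet(tl=tl, fl=fl, total=totals)


# ---------------------------------------------------------------------------
# single-Windkessel afterload for stand-alone heart studies
# ---------------------------------------------------------------------------

def single_rcr_afterload() -> WindkesselParams:
    """Lumped systemic afterload for heart-only experiments.

    Total resistance 0.184 g/(mm^4 s) gives ~92 mmHg mean pressure at a
    cardiac output of 4.4 L/min; the proximal share (0.008) approximates the
    aortic characteristic impedance; compliance 11 mm^4 s^2/g (~1.5 mL/mmHg)
    sets a diastolic decay time of ~1.9 s.
    """
    return WindkesselParams(Rp=0.008, C=11.0, Rd=0.176, Pd=0.0)


# ---------------------------------------------------------------------------
# network fixtures
# ---------------------------------------------------------------------------

# Compartmental geometry of the surrogate aorta (radii/lengths in mm).  The
# true lumen is made narrower than the false lumen; the pair (6.2, 8.5) was
# fixed once by the shipped calibration driver so the demonstration
# descending-aorta flow split lands near 25/75 (TL/FL).
_TRUNK = [
    # name, from, to, radius, length
    ("asc_aorta", "aortic_root", "arch_a", 14.0, 60.0),
    ("arch_1", "arch_a", "arch_b", 12.0, 40.0),
    ("arch_2", "arch_b", "desc_start", 11.0, 30.0),
]
_TL_RADIUS = 6.2
_FL_RADIUS = 8.5
_DESC_RADIUS = 10.5          # undissected descending aorta
_CHAIN_LENGTHS = [55.0, 55.0, 55.0, 40.0, 40.0]   # nodes 1..6
_SEPTUM_THICKNESS = 2.0      # tear channel length, mm (assumed)
_SECONDARY_TEAR_AREA = 20.0  # mm^2 each (assumed; not imaged reliably)
_ENTRY_TEAR_AREA = 135.0     # mm^2
_EXIT_TEAR_AREA = 68.0       # mm^2

# outlet -> attachment node key; "U<k>" resolves to the upper trunk,
# "L<k>" to lumen node k (TL/FL chosen by perfusion side), "I" to the
# iliac junction.
_OUTLET_NODES = {
    "RCCA": ("arch_a", None), "RSCA": ("arch_a", None),
    "LCCA": ("arch_b", None), "LSCA": ("arch_b", None),
    # visceral branches perfused from the true lumen
    "Hepatic": (4, "TL"), "Splenic": (4, "TL"), "M Coeliac": (4, "TL"),
    "SMA": (4, "TL"), "R Renal 1": (5, "TL"), "R Renal 2": (5, "TL"),
    # branches perfused from the false lumen
    "L Renal": (5, "FL"), "IMA": (5, "FL"),
    "M Sacral 1": (6, "FL"), "M Sacral 2": (6, "FL"),
    # iliac outlets past the distal end of the dissection
    "L Int Iliac": ("iliac_j", None), "R Int Iliac": ("iliac_j", None),
    "L Ext Iliac": ("iliac_j", None), "R Ext Iliac": ("iliac_j", None),
}


def _chain_segments(prefix: str, radius: float, lumen: str) -> list[dict]:
    segs = []
    for k, length in enumerate(_CHAIN_LENGTHS, start=1):
        segs.append({
            "name": f"{prefix}_{k}_{k + 1}", "from": f"{prefix}{k}",
            "to": f"{prefix}{k + 1}", "radius": radius, "length": length,
            "lumen": lumen,
        })
    return segs


def _outlet_entries(dissected: bool) -> list[dict]:
    out = []
    for name, (node, side) in _OUTLET_NODES.items():
        if isinstance(node, int):
            if dissected:
                prefix = "tl" if side == "TL" else "fl"
            else:
                prefix = "d"
            node = f"{prefix}{node}"
        out.append({"name": name, "node": node})
    return out


def _base_config(name: str) -> dict:
    return {
        "name": name,
        "blood": {"rho": 1.060e-3, "mu": 4.0e-3},
        "inlet": {"node": "aortic_root"},
        "segments": [dict(zip(("name", "from", "to", "radius", "length"), row))
                     for row in _TRUNK],
    }


def _secondary_tears() -> list[dict]:
    tears = []
    idx = 1
    for station in (4, 5, 6):   # clustered in the visceral region
        for _ in range(5):
            tears.append({
                "name": f"sec_tear_{idx}", "from": f"tl{station}",
                "to": f"fl{station}", "area": _SECONDARY_TEAR_AREA,
                "length": _SEPTUM_THICKNESS, "role": "secondary",
            })
            idx += 1
    return tears


def _dissected_config(name: str, tears: list[dict]) -> dict:
    cfg = _base_config(name)
    cfg["segments"] += [
        {"name": "desc_to_tl", "from": "desc_start", "to": "tl1",
         "radius": 10.0, "length": 10.0, "lumen": "true_lumen"},
        *_chain_segments("tl", _TL_RADIUS, "true_lumen"),
        *_chain_segments("fl", _FL_RADIUS, "false_lumen"),
        {"name": "tl_to_iliac", "from": "tl6", "to": "iliac_j",
         "radius": 8.0, "length": 40.0, "lumen": "trunk"},
    ]
    cfg["tears"] = tears
    cfg["outlets"] = _outlet_entries(dissected=True)
    cfg["probes"] = {
        "proximal": ("tl_1_2", "fl_1_2"),
        "medial": ("tl_2_3", "fl_2_3"),
        "distal": ("tl_3_4", "fl_3_4"),
        "visceral": ("tl_3_4", "fl_3_4"),
    }
    cfg["probe_nodes"] = {
        "proximal": ("tl2", "fl2"), "medial": ("tl3", "fl3"),
        "distal": ("tl4", "fl4"), "visceral": ("tl4", "fl4"),
    }
    return cfg


def fixture_configs() -> dict[str, dict]:
    """The four packaged network configurations.

    ``dissected_baseline`` carries the primary entry (135 mm^2) and exit
    (68 mm^2) tears plus 15 secondary tears (17 total); ``maximal_tears``
    adds two thoracic tears (19); ``minimal_tears`` keeps only entry and
    exit (2); ``undissected`` is a single descending chain with no tears.
    """
    entry = {"name": "entry_tear", "from": "tl1", "to": "fl1",
             "area": _ENTRY_TEAR_AREA, "length": _SEPTUM_THICKNESS,
             "role": "entry"}
    exit_ = {"name": "exit_tear", "from": "tl6", "to": "fl6",
             "area": _EXIT_TEAR_AREA, "length": _SEPTUM_THICKNESS,
             "role": "exit"}
    thoracic = [
        {"name": "thoracic_tear_1", "from": "tl2", "to": "fl2",
         "area": _SECONDARY_TEAR_AREA, "length": _SEPTUM_THICKNESS,
         "role": "secondary"},
        {"name": "thoracic_tear_2", "from": "tl3", "to": "fl3",
         "area": _SECONDARY_TEAR_AREA, "length": _SEPTUM_THICKNESS,
         "role": "secondary"},
    ]

    undissected = _base_config("undissected")
    undissected["segments"] += [
        {"name": "desc_to_d", "from": "desc_start", "to": "d1",
         "radius": 10.5, "length": 10.0, "lumen": "trunk"},
        *_chain_segments("d", _DESC_RADIUS, "trunk"),
        {"name": "d_to_iliac", "from": "d6", "to": "iliac_j",
         "radius": 8.0, "length": 40.0, "lumen": "trunk"},
    ]
    undissected["tears"] = []
    undissected["outlets"] = _outlet_entries(dissected=False)
    undissected["probes"] = {}
    undissected["probe_nodes"] = {
        "proximal": ("d2", "d2"), "medial": ("d3", "d3"),
        "distal": ("d4", "d4"), "visceral": ("d4", "d4"),
    }

    return {
        "undissected": undissected,
        "dissected_baseline": _dissected_config(
            "dissected_baseline", [entry, exit_, *_secondary_tears()]),
        "maximal_tears": _dissected_config(
            "maximal_tears", [entry, exit_, *_secondary_tears(), *thoracic]),
        "minimal_tears": _dissected_config("minimal_tears", [entry, exit_]),
    }
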