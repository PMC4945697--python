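"""Periodic waveform container with metrics and CSV I/O.

A :class:`Waveform` is a uniformly or non-uniformly sampled periodic signal:
a strictly increasing time grid spanning one period, the sample values, and
the period itself.  Evaluation between samples is piecewise linear and the
signal wraps around, matching the character of ECG-gated phase-contrast MRI
data (25 gated phases at 52 ms resolution).  Cycle means use trapezoid
quadrature including the wrap-around segment, which is exact for piecewise
linear signals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .units import MMHG

__all__ = [
    "Waveform",
    "WaveformError",
    "waveform_mean",
    "waveform_metrics",
    "read_waveform_csv",
    "write_waveform_csv",
]


class WaveformError(ValueError):
    """Raised for degenerate or malformed waveforms and waveform files."""


@dataclass
class Waveform:
    """Periodic signal: ``times`` (s, starting at 0), ``values``, ``period`` (s)."""

    times: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise WaveformError("times and values must be one-dimensional")
        if self.times.size != self.values.size:
            raise WaveformError("times and values must have equal length")
        if self.times.size < 2:
            raise WaveformError("waveform needs at least 2 samples")
        if not np.isfinite(self.times).all() or not np.isfinite(self.values).all():
            raise WaveformError("waveform contains non-finite entries")
        if self.period <= 0:
            raise WaveformError(f"period must be positive, got {self.period}")
        if self.times[0] != 0.0:
            raise WaveformError(f"times must start at 0, got {self.times[0]}")
        if np.any(np.diff(self.times) <= 0):
            bad = int(np.argmax(np.diff(self.times) <= 0)) + 1
            raise WaveformError(f"times must be strictly increasing (row {bad})")
        if self.times[-1] > self.period * (1 + 1e-12):
            raise WaveformError(
                f"last sample time {self.times[-1]} exceeds period {self.period}"
            )

    # -- evaluation ------------------------------------------------------
    def __call__(self, t):
        """Periodic piecewise-linear evaluation, ``w(t) = w(t mod period)``."""
        tt = np.mod(t, self.period)
        # Extend the grid with the wrapped first sample at t = period so the
        # final segment interpolates toward the start of the next cycle.
        if self.times[-1] < self.period:
            xs = np.append(self.times, self.period)
            ys = np.append(self.values, self.values[0])
        else:
            xs, ys = self.times, self.values
        return np.interp(tt, xs, ys)

    # -- metrics ---------------------------------------------------------
    def integral(self) -> float:
        """Integral over one period (trapezoid, wrap-around segment included)."""
        core = float(np.trapezoid(self.values, self.times))
        wrap_dt = self.period - self.times[-1]
        if wrap_dt > 0:
            core += 0.5 * (self.values[-1] + self.values[0]) * wrap_dt
        return core

    def mean(self) -> float:
        """Cycle mean, integral / period."""
        return self.integral() / self.period

    def metrics(self) -> dict:
        """``{mean, peak, min, pulse}`` over one period.

        For a piecewise-linear signal the extremes occur at the samples.
        """
        peak = float(self.values.max())
        vmin = float(self.values.min())
        return {
            "mean": self.mean(),
            "peak": peak,
            "min": vmin,
            "pulse": peak - vmin,
        }

    def resample(self, n: int) -> "Waveform":
        ts = np.linspace(0.0, self.period, n, endpoint=False)
        return Waveform(ts, self(ts), self.period)

    @classmethod
    def constant(cls, value: float, period: float = 1.0, n: int = 2) -> "Waveform":
        ts = np.linspace(0.0, period, n, endpoint=False)
        return cls(ts, np.full(n, float(value)), period)


def waveform_mean(w: Waveform) -> float:
    """Cycle mean of ``w`` (same units as its values)."""
    return w.mean()


def waveform_metrics(w: Waveform) -> dict:
    """Mean, peak, min and pulse (= peak - min) of ``w``."""
    return w.metrics()


# -- CSV I/O -------------------------------------------------------------
#
# Format: optional comment lines ``# period=<s>`` and ``# units=mmHg|mL_per_s``
# followed by a ``time_s,value`` header and the samples.  Values are stored in
# canonical units unless a units comment is present.

_UNIT_SCALES = {"mmHg": MMHG, "mL_per_s": 1000.0}


def read_waveform_csv(path) -> Waveform:
    """Read a waveform CSV, converting annotated units to canonical ones."""
    period = None
    scale = 1.0
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    data_row = 0
    for i, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("period="):
                period = float(body.split("=", 1)[1])
            elif body.startswith("units="):
                unit = body.split("=", 1)[1].strip()
                if unit not in _UNIT_SCALES:
                    raise WaveformError(f"{path}: unknown units {unit!r} (line {i})")
                scale = _UNIT_SCALES[unit]
            continue
        if line.lower().replace(" ", "") == "time_s,value":
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise WaveformError(f"{path}: malformed row {i}: {line!r}")
        try:
            t, v = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise WaveformError(f"{path}: non-numeric row {i}: {line!r}") from exc
        if not (np.isfinite(t) and np.isfinite(v)):
            raise WaveformError(f"{path}: NaN/inf at row {i}")
        if rows and t <= rows[-1][0]:
            raise WaveformError(f"{path}: time not increasing at row {i} (t={t})")
        rows.append((t, v))
        data_row += 1
    if data_row < 2:
        raise WaveformError(f"{path}: fewer than 2 samples")
    times = np.array([r[0] for r in rows])
    values = np.array([r[1] for r in rows]) * scale
    if period is None:
        period = float(times[-1])
        times = times.copy()
        # Without an explicit period the last sample defines it; keep it as
        # the final grid point (wrap segment has zero length).
    return Waveform(times, values, period)


def write_waveform_csv(w: Waveform, path, units: str | None = None) -> None:
    """Write ``w``; with ``units`` given, values are converted on output."""
    scale = 1.0
    buf = io.StringIO()
    buf.write(f"# period={float(w.period)!r}\n")
    if units is not None:
        if units not in _UNIT_SCALES:
            raise WaveformError(f"unknown units {units!r}")
        scale = _UNIT_SCALES[units]
        buf.write(f"# units={units}\n")
    buf.write("time_s,value\n")
    for t, v in zip(w.times, w.values / scale):
        buf.write(f"{float(t)!r},{float(v)!r}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
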