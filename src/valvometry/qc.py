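"""Sensor quality control.

Hall-effect valvometers fail in two characteristic ways: saltwater intrusion
or shorting drives the output from its ~2500 mV operating range to one of the
supply rails (~0 or ~5000 mV), and broken solder welds or pinched contacts
produce a flat trace with no diurnal signal. Both are detected here and the
affected spans are masked (set NaN) — never repaired — before any behavioral
statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal

from .series import ValveSeries

#: Fraction of periodogram power that must fall in the 20-28 h band for a
#: window to count as having a diurnal signal. Committed from
#: scripts/calibrate_qc.py: white noise puts ~0.0005 (1-min grid) to ~0.03
#: (1-h grid) of its power there, a clean diurnal trace >0.5.
DEFAULT_POWER_RATIO_MIN = 0.15

DIURNAL_BAND_H = (20.0, 28.0)


@dataclass
class QcFlag:
    clam_id: int
    kind: str  # rail_high | rail_low | flatline | diurnal_loss
    start: pd.Timestamp
    end: pd.Timestamp
    detail: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"QcFlag start {self.start} not before end {self.end}")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class QcReport:
    flags: list[QcFlag] = field(default_factory=list)
    masked_fraction: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "flags": [
                {**asdict(f), "start": str(f.start), "end": str(f.end)}
                for f in self.flags
            ],
            "masked_fraction": {str(k): v for k, v in self.masked_fraction.items()},
        }


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def detect_rail_fault(
    series: ValveSeries,
    low_mv: float = 100.0,
    high_mv: float = 4900.0,
    min_duration_s: float = 300.0,
) -> list[QcFlag]:
    """Flag spans stuck at a supply rail.

    Every maximal run of at least ``min_duration_s`` during which the voltage
    stays at or below ``low_mv`` (rail_low) or at or above ``high_mv``
    (rail_high) is flagged; shorter excursions are treated as electrical
    noise. NaNs break runs.
    """
    if len(series) == 0:
        raise ValueError("detect_rail_fault: empty series")
    v = series.voltage_mv
    idx = series.timestamps
    flags: list[QcFlag] = []
    for kind, mask in (
        ("rail_low", np.isfinite(v) & (v <= low_mv)),
        ("rail_high", np.isfinite(v) & (v >= high_mv)),
    ):
        for i0, i1 in _runs(mask):
            start, last = idx[i0], idx[i1 - 1]
            end = last + pd.Timedelta(seconds=series.nominal_period_s)
            if (end - start).total_seconds() >= min_duration_s:
                flags.append(
                    QcFlag(
                        clam_id=series.clam_id, kind=kind, start=start, end=end,
                        detail=f"{i1 - i0} samples at {'<=' if kind == 'rail_low' else '>='}"
                               f"{low_mv if kind == 'rail_low' else high_mv:.0f} mV",
                    )
                )
    flags.sort(key=lambda f: f.start)
    return flags


def diurnal_band_fraction(values: np.ndarray, dt_s: float) -> float:
    """Fraction of (mean-removed) periodogram power in the 20-28 h band.

    Returns 0.0 for a zero-variance window.
    """
    x = values[np.isfinite(values)]
    if x.size < 8:
        return 0.0
    x = x - x.mean()
    if not (x != 0).any():
        return 0.0
    freqs, power = signal.periodogram(x, fs=1.0 / dt_s)
    freqs, power = freqs[1:], power[1:]  # drop DC
    total = power.sum()
    if total <= 0:
        return 0.0
    lo_f = 1.0 / (DIURNAL_BAND_H[1] * 3600.0)
    hi_f = 1.0 / (DIURNAL_BAND_H[0] * 3600.0)
    band = (freqs >= lo_f) & (freqs <= hi_f)
    return float(power[band].sum() / total)


def detect_diurnal_loss(
    series: ValveSeries,
    window_days: int = 3,
    power_ratio_min: float = DEFAULT_POWER_RATIO_MIN,
    step_days: int = 1,
) -> list[QcFlag]:
    """Flag windows whose spectrum has lost the diurnal (20-28 h) peak.

    A window of ``window_days`` slides in steps of ``step_days``; any window
    whose diurnal band fraction (see :func:`diurnal_band_fraction`) falls
    below ``power_ratio_min`` is flagged, and overlapping/adjacent flagged
    windows are merged. Flat (zero-variance) windows always flag.
    """
    span = (series.timestamps[-1] - series.timestamps[0]).total_seconds()
    if span < window_days * 86400:
        raise ValueError(
            f"series spans {span / 86400:.2f} d, shorter than window_days={window_days}"
        )
    dt_s = series.nominal_period_s
    t0 = series.timestamps[0]
    flagged: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    wlen = pd.Timedelta(days=window_days)
    step = pd.Timedelta(days=step_days)
    wstart = t0
    while wstart + wlen <= series.timestamps[-1] + pd.Timedelta(seconds=dt_s):
        wend = wstart + wlen
        chunk = series.data[(series.data.index >= wstart) & (series.data.index < wend)]
        frac = diurnal_band_fraction(chunk.to_numpy(), dt_s)
        if frac < power_ratio_min:
            flagged.append((wstart, wend))
        wstart = wstart + step
    # merge overlapping / touching windows
    merged: list[list[pd.Timestamp]] = []
    for s, e in flagged:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [
        QcFlag(
            clam_id=series.clam_id, kind="diurnal_loss", start=s, end=e,
            detail=f"20-28 h band power fraction < {power_ratio_min}",
        )
        for s, e in merged
    ]


def apply_flags(series: ValveSeries, flags: list[QcFlag]) -> ValveSeries:
    """Return a copy with flagged spans masked to NaN."""
    data = series.data.copy()
    for f in flags:
        if f.clam_id != series.clam_id:
            continue
        data[(data.index >= f.start) & (data.index < f.end)] = np.nan
    return ValveSeries(
        clam_id=series.clam_id, data=data, nominal_period_s=series.nominal_period_s
    )


def run_qc(
    series_list: list[ValveSeries],
    low_mv: float = 100.0,
    high_mv: float = 4900.0,
    min_duration_s: float = 300.0,
    window_days: int = 3,
    power_ratio_min: float = DEFAULT_POWER_RATIO_MIN,
    check_diurnal: bool = True,
) -> tuple[list[ValveSeries], QcReport]:
    """Run rail-fault (and optionally diurnal-loss) detection and mask flags.

    Returns the masked series and a :class:`QcReport` whose
    ``masked_fraction`` is total flagged duration over span duration per clam.
    """
    report = QcReport()
    masked: list[ValveSeries] = []
    for s in series_list:
        flags = detect_rail_fault(s, low_mv, high_mv, min_duration_s)
        span_s = (s.timestamps[-1] - s.timestamps[0]).total_seconds() + s.nominal_period_s
        if check_diurnal and span_s >= window_days * 86400:
            flags += detect_diurnal_loss(s, window_days, power_ratio_min)
        # flagged coverage via a boolean union over samples (kinds may overlap)
        cover = np.zeros(len(s), dtype=bool)
        idx = s.timestamps
        for f in flags:
            cover |= (idx >= f.start) & (idx < f.end)
        report.flags.extend(sorted(flags, key=lambda f: (f.kind, f.start)))
        report.masked_fraction[s.clam_id] = float(cover.mean()) if len(s) else 0.0
        masked.append(apply_flags(s, flags))
    return masked, report
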