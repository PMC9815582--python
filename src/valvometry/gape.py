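"""Daily z-score normalization, percent closure, and light-regime partitioning.

Raw sensor voltage drifts day to day (magnets "walk", neighboring clams
interfere), so each local calendar day is standardized on its own:

    z_t   = (mV_t - mu_day) / SD_day
    pct_t = (z_t - z_daymin) / (z_daymax - z_daymin) * 100

Percent closure rescales every day's range to 0 (most open) .. 100 (most
closed). Polarity is installation-dependent (magnet/sensor geometry can flip
the sign); ``auto`` orients z so that dark-hours closure exceeds bright-hours
closure, the universal pattern for photosymbiotic giant clams.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import EnvSeries, ValveSeries

log = logging.getLogger(__name__)

DARK_MAX_PAR = 5.0     # hourly-mean PAR below which a clock-hour is "dark"
BRIGHT_MIN_PAR = 100.0  # instantaneous PAR above which an instant is "bright"


class DegenerateDayWarning(UserWarning):
    """A calendar day was dropped (zero variance or insufficient coverage)."""


@dataclass
class GapeSeries:
    """Normalized gape for one clam: daily z-score and percent closure."""

    clam_id: int
    z: pd.Series
    pct_closure: pd.Series | None = None
    day_params: pd.DataFrame = field(default_factory=pd.DataFrame)
    dropped_days: list = field(default_factory=list)
    polarity: str = "closure_positive"
    grid_s: float = 60.0

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.z.index


@dataclass
class LightPartition:
    """Light-regime label (dark / low_light / bright) per grid instant."""

    regime: pd.Series  # values in {"dark", "low_light", "bright"}
    dark_max: float = DARK_MAX_PAR
    bright_min: float = BRIGHT_MIN_PAR
    n_gap_filled: int = 0

    def regime_at(self, timestamps: pd.DatetimeIndex) -> pd.Series:
        """Label arbitrary instants by the nearest labeled grid instant."""
        pos = self.regime.index.get_indexer(timestamps, method="nearest")
        return pd.Series(self.regime.to_numpy()[pos], index=timestamps)


def daily_zscore(
    series: ValveSeries,
    polarity: str = "closure_positive",
    partition: LightPartition | None = None,
    min_coverage: float = 0.5,
    ddof: int = 1,
) -> GapeSeries:
    """Standardize each local calendar day of a (QC-masked) voltage series.

    Days with less than ``min_coverage`` of their expected samples, or with
    zero variance, are dropped with a :class:`DegenerateDayWarning` rather
    than an exception. ``ddof=1`` gives the sample standard deviation.

    ``polarity="auto"`` requires a :class:`LightPartition` and flips the sign
    of z if needed so the dark-hours median exceeds the bright-hours median
    (more closed at night).
    """
    if polarity not in ("closure_positive", "closure_negative", "auto"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if polarity == "auto" and partition is None:
        raise ValueError("polarity='auto' requires a light partition")

    data = series.data
    grid_s = series.nominal_period_s
    expected_per_day = 86400.0 / grid_s
    dates = data.index.normalize()

    z_parts = []
    rows = []
    dropped = []
    for day, chunk in data.groupby(dates):
        valid = chunk.dropna()
        if len(valid) < min_coverage * expected_per_day:
            dropped.append(day.date())
            warnings.warn(
                f"clam {series.clam_id} {day.date()}: coverage "
                f"{len(valid)}/{expected_per_day:.0f} below minimum; day dropped",
                DegenerateDayWarning,
                stacklevel=2,
            )
            continue
        mu = float(valid.mean())
        sd = float(valid.std(ddof=ddof))
        if sd == 0 or not np.isfinite(sd):
            dropped.append(day.date())
            warnings.warn(
                f"clam {series.clam_id} {day.date()}: zero daily SD; day dropped",
                DegenerateDayWarning,
                stacklevel=2,
            )
            continue
        z = (chunk - mu) / sd
        z_parts.append(z)
        rows.append(
            {"date": day.date(), "mu_mv": mu, "sd_mv": sd,
             "z_min": float(z.min()), "z_max": float(z.max()),
             "n_valid": len(valid)}
        )
    if not z_parts:
        raise ValueError(f"clam {series.clam_id}: no usable days")
    z = pd.concat(z_parts).sort_index()
    params = pd.DataFrame(rows).set_index("date")

    sign = -1.0 if polarity == "closure_negative" else 1.0
    if polarity == "auto":
        reg = partition.regime_at(z.index)
        dark_med = z[reg.to_numpy() == "dark"].median()
        bright_med = z[reg.to_numpy() == "bright"].median()
        if np.isfinite(dark_med) and np.isfinite(bright_med) and dark_med < bright_med:
            sign = -1.0
            log.info("clam %d: auto polarity flipped sign", series.clam_id)
    if sign < 0:
        z = -z
        params[["z_min", "z_max"]] = -params[["z_max", "z_min"]].to_numpy()

    return GapeSeries(
        clam_id=series.clam_id, z=z, day_params=params, dropped_days=dropped,
        polarity=polarity, grid_s=grid_s,
    )


def percent_closure(gape: GapeSeries) -> GapeSeries:
    """Fill ``pct_closure`` from z using each day's own extrema.

    By construction every complete day spans the full 0-100 range. Days whose
    z is constant (z_min == z_max) are dropped with a warning.
    """
    z = gape.z
    dates = z.index.normalize()
    parts = []
    keep_days = []
    for day, chunk in z.groupby(dates):
        finite = chunk.dropna()
        if finite.empty:
            continue
        zmin, zmax = float(finite.min()), float(finite.max())
        if zmin == zmax:
            warnings.warn(
                f"clam {gape.clam_id} {day.date()}: z_min == z_max; day dropped",
                DegenerateDayWarning,
                stacklevel=2,
            )
            continue
        parts.append((chunk - zmin) / (zmax - zmin) * 100.0)
        keep_days.append(day.date())
    if not parts:
        raise ValueError(f"clam {gape.clam_id}: no days usable for percent closure")
    pct = pd.concat(parts).sort_index()
    gape.pct_closure = pct
    gape.z = z[z.index.normalize().isin([pd.Timestamp(d) for d in keep_days])]
    return gape


def light_partition(
    par: EnvSeries,
    dark_max: float = DARK_MAX_PAR,
    bright_min: float = BRIGHT_MIN_PAR,
) -> LightPartition:
    """Label every PAR grid instant dark / low_light / bright.

    dark: the containing clock-hour's mean PAR is below ``dark_max``;
    bright: instantaneous PAR above ``bright_min``; low_light: the rest.
    Instants with missing PAR inherit the label of the nearest labeled
    instant and are counted.
    """
    if par.variable != "PAR":
        raise ValueError(f"light_partition needs a PAR series, got {par.variable}")
    s = par.data
    hourly = s.resample("1h").mean()
    hour_of = s.index.floor("1h")
    hmean = hourly.reindex(hour_of).to_numpy()
    v = s.to_numpy()

    regime = np.full(len(s), "low_light", dtype=object)
    regime[hmean < dark_max] = "dark"
    regime[(v > bright_min) & ~(hmean < dark_max)] = "bright"

    missing = ~np.isfinite(v) | ~np.isfinite(hmean)
    n_gap = int(missing.sum())
    reg = pd.Series(regime, index=s.index)
    if n_gap:
        good = reg[~missing]
        if good.empty:
            raise ValueError("light_partition: no labelable instants")
        pos = good.index.get_indexer(s.index[missing], method="nearest")
        reg.iloc[np.flatnonzero(missing)] = good.to_numpy()[pos]
    return LightPartition(regime=reg, dark_max=dark_max, bright_min=bright_min,
                          n_gap_filled=n_gap)


def closure_by_regime(
    gapes: list[GapeSeries] | GapeSeries,
    partition: LightPartition,
    statistic: str = "mean",
    sd: bool = True,
) -> pd.DataFrame:
    """Per-regime summary of percent closure, per clam and pooled.

    Returns a frame indexed by (clam, regime) with the requested statistic
    (``mean`` or ``median``), optional SD, and n. An empty regime gives NaN.
    Regimes also include ``light_present`` = not dark (the union of bright
    and low_light), the contrast used for the dark-vs-light comparison.
    """
    if isinstance(gapes, GapeSeries):
        gapes = [gapes]
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")

    rows = []
    pooled: dict[str, list[np.ndarray]] = {}
    regimes = ["dark", "low_light", "bright", "light_present"]
    for g in gapes:
        if g.pct_closure is None:
            raise ValueError(f"clam {g.clam_id}: pct_closure not computed")
        reg = partition.regime_at(g.pct_closure.index).to_numpy()
        for r in regimes:
            sel = (reg != "dark") if r == "light_present" else (reg == r)
            vals = g.pct_closure.to_numpy()[sel]
            vals = vals[np.isfinite(vals)]
            pooled.setdefault(r, []).append(vals)
            rows.append(_summary_row(g.clam_id, r, vals, statistic, sd))
    for r in regimes:
        vals = np.concatenate(pooled[r]) if pooled.get(r) else np.array([])
        rows.append(_summary_row("pooled", r, vals, statistic, sd))
    return pd.DataFrame(rows).set_index(["clam", "regime"])


def _summary_row(clam, regime, vals, statistic, sd):
    row = {"clam": clam, "regime": regime, "n": len(vals)}
    if len(vals) == 0:
        row[statistic] = np.nan
        if sd:
            row["sd"] = np.nan
        return row
    row[statistic] = float(np.mean(vals) if statistic == "mean" else np.median(vals))
    if sd:
        row["sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
    return row
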