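"""Reading raw valvometer logs and environmental CSVs, and grid alignment.

The valve-log dialect is tab-delimited text: first column an ISO-8601 local
timestamp, remaining columns integer millivolt readings, optional header row.
Environmental loggers are assumed to have been exported to CSV with a header,
one timestamp column and one value column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import AlignedDataset, EnvSeries, ValveSeries

log = logging.getLogger(__name__)

#: Fraction of unparseable rows above which a valve log is considered a
#: corrupted serial capture rather than one with occasional garbled lines.
MAX_BAD_ROW_FRACTION = 0.10


@dataclass
class ReadReport:
    path: str
    n_rows: int
    n_skipped: int
    detail: str = ""


def read_valve_log(
    path,
    column_map: dict[int, int] | None = None,
    timezone: str | None = None,
) -> tuple[list[ValveSeries], ReadReport]:
    """Read a tab-delimited valve log into one :class:`ValveSeries` per sensor.

    Parameters
    ----------
    path : path-like
        Tab-delimited text file: timestamp, then one integer-mV column per sensor.
    column_map : dict, optional
        Maps sensor column position (0 = first column after the timestamp) to a
        clam id. Defaults to identity numbering from 1.
    timezone : str, optional
        Recorded for provenance only; timestamps are kept as naive local time.

    Returns
    -------
    (series_list, report)
        Unparseable rows are skipped and counted; more than 10% unparseable
        rows, an empty file, or non-monotone timestamps are hard errors.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"empty valve log: {path}")

    # Optional single header row: first field not parseable as a timestamp.
    first_fields = lines[0].split("\t")
    if pd.isna(pd.to_datetime(first_fields[0], errors="coerce")):
        lines = lines[1:]
        if not lines:
            raise ValueError(f"valve log contains only a header: {path}")

    n_sensors = len(lines[0].split("\t")) - 1
    if n_sensors < 1:
        raise ValueError(f"valve log has no sensor columns: {path}")

    times: list = []
    rows: list[list[float]] = []
    n_skipped = 0
    for ln in lines:
        fields = ln.split("\t")
        if len(fields) != n_sensors + 1:
            n_skipped += 1
            continue
        ts = pd.to_datetime(fields[0], errors="coerce")
        if pd.isna(ts):
            n_skipped += 1
            continue
        try:
            vals = [float(f) for f in fields[1:]]
        except ValueError:
            n_skipped += 1
            continue
        times.append(ts)
        rows.append(vals)

    n_total = len(lines)
    if n_skipped / n_total > MAX_BAD_ROW_FRACTION:
        raise ValueError(
            f"{path}: {n_skipped}/{n_total} rows unparseable (> "
            f"{MAX_BAD_ROW_FRACTION:.0%}); corrupted serial capture?"
        )
    if not times:
        raise ValueError(f"{path}: no parseable data rows")

    index = pd.DatetimeIndex(times)
    if len(index) > 1:
        diffs = np.diff(index.view("i8"))
        if (diffs <= 0).any():
            bad = int(np.flatnonzero(diffs <= 0)[0]) + 1
            raise ValueError(
                f"{path}: timestamps non-monotone after parsing at data row {bad} "
                f"({index[bad]})"
            )
    arr = np.asarray(rows, dtype=float)

    if column_map is None:
        column_map = {i: i + 1 for i in range(n_sensors)}
    series = []
    period = float(np.median(np.diff(index.view("i8"))) / 1e9) if len(index) > 1 else 5.0
    for col, clam_id in sorted(column_map.items()):
        if col >= n_sensors:
            raise ValueError(f"column_map refers to column {col}; log has {n_sensors}")
        series.append(
            ValveSeries(
                clam_id=clam_id,
                data=pd.Series(arr[:, col], index=index),
                nominal_period_s=period,
            )
        )
    report = ReadReport(str(path), n_rows=len(index), n_skipped=n_skipped)
    log.info("read %s: %d rows, %d skipped", path, len(index), n_skipped)
    return series, report


def read_env_csv(
    path,
    variable: str,
    units: str = "",
    timestamp_column: str | None = None,
    value_column: str | None = None,
) -> tuple[EnvSeries, ReadReport]:
    """Read one environmental variable from a headered CSV.

    Negative PAR/RFU readings (sensor dark-noise) are clipped to zero and
    counted in the report. The nominal sampling period is inferred from the
    median timestamp spacing.
    """
    from .series import ENV_VARIABLES

    if variable not in ENV_VARIABLES:
        raise ValueError(
            f"unknown variable {variable!r}; expected one of {sorted(ENV_VARIABLES)}"
        )
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"empty environmental CSV: {path}")
    ts_col = timestamp_column or df.columns[0]
    val_col = value_column or (
        variable if variable in df.columns else df.columns[1]
    )
    ts = pd.to_datetime(df[ts_col], errors="coerce")
    vals = pd.to_numeric(df[val_col], errors="coerce")
    keep = ts.notna()
    ts, vals = ts[keep], vals[keep]
    if vals.notna().sum() == 0:
        raise ValueError(f"{path}: value column {val_col!r} is all-missing")

    n_clipped = 0
    if variable in ("PAR", "chlorophyll_a", "phycoerythrin"):
        neg = vals < 0
        n_clipped = int(neg.sum())
        vals = vals.clip(lower=0.0)

    series = EnvSeries(
        variable=variable,
        data=pd.Series(vals.to_numpy(dtype=float), index=pd.DatetimeIndex(ts)),
        units=units,
    )
    report = ReadReport(
        str(path), n_rows=len(series), n_skipped=int((~keep).sum()),
        detail=f"{n_clipped} negative values clipped to 0",
    )
    report.n_clipped = n_clipped
    return series, report


def _window_average(s: pd.Series, grid_s: float) -> pd.Series:
    """Average into non-overlapping left-closed windows of grid_s seconds.

    Windows with no finite samples come out NaN (explicit missing marker).
    """
    out = s.resample(pd.Timedelta(seconds=grid_s), origin="epoch").mean()
    return out


def align(
    valve: list[ValveSeries],
    env: list[EnvSeries],
    valve_grid_s: float = 60.0,
    env_grid_s: float = 900.0,
) -> AlignedDataset:
    """Average all series onto common regular grids over their shared span.

    Valve series are averaged into non-overlapping ``valve_grid_s`` windows
    (the field convention of minute-averaging for wavelet work is
    ``valve_grid_s=60``); environmental series onto ``env_grid_s`` windows.
    The output is restricted to the intersection of all input spans; nothing
    is extrapolated.
    """
    if not valve:
        raise ValueError("align requires at least one valve series")
    starts = [v.span()[0] for v in valve] + [e.span()[0] for e in env]
    ends = [v.span()[1] for v in valve] + [e.span()[1] for e in env]
    t0, t1 = max(starts), min(ends)
    if t0 >= t1:
        raise ValueError(
            f"no temporal overlap between inputs (latest start {t0}, earliest end {t1})"
        )

    valve_out: dict[int, ValveSeries] = {}
    for v in valve:
        avg = _window_average(v.data, valve_grid_s)
        avg = avg[(avg.index >= t0) & (avg.index <= t1)]
        valve_out[v.clam_id] = ValveSeries(
            clam_id=v.clam_id, data=avg, nominal_period_s=valve_grid_s
        )
    env_out: dict[str, EnvSeries] = {}
    for e in env:
        grid = valve_grid_s if e.variable == "PAR" and env_grid_s > valve_grid_s else env_grid_s
        avg = _window_average(e.data, grid)
        avg = avg[(avg.index >= t0) & (avg.index <= t1)]
        if e.variable in ("PAR", "chlorophyll_a", "phycoerythrin"):
            avg = avg.clip(lower=0.0)  # averaging cannot create negatives; guard NaN edge
        env_out[e.variable] = EnvSeries(
            variable=e.variable, data=avg, units=e.units, nominal_period_s=grid
        )
    return AlignedDataset(
        valve=valve_out, env=env_out, span=(t0, t1),
        valve_grid_s=valve_grid_s, env_grid_s=env_grid_s,
    )
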