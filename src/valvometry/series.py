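"""Shared time-series containers for the valvometry pipeline.

All series are pandas Series with a timezone-naive DatetimeIndex in the fixed
local clock of the deployment (no DST shifts). Missing ticks are represented
explicitly as NaN; nothing in the pipeline interpolates at ingest time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Known environmental variables and their units.
ENV_VARIABLES = {
    "PAR": "umol photons/m2/s",
    "pH": "pH units",
    "DO": "mg/L",
    "temperature": "degC",
    "chlorophyll_a": "RFU",
    "phycoerythrin": "RFU",
}

VOLTAGE_RANGE_MV = (0.0, 5000.0)


def _check_index(index: pd.Index, what: str) -> pd.DatetimeIndex:
    if not isinstance(index, pd.DatetimeIndex):
        raise TypeError(f"{what} requires a DatetimeIndex, got {type(index).__name__}")
    if index.tz is not None:
        raise ValueError(f"{what} timestamps must be timezone-naive local clock time")
    if len(index) > 1 and not index.is_monotonic_increasing:
        bad = int(np.flatnonzero(np.diff(index.view("i8")) <= 0)[0]) + 1
        raise ValueError(f"{what} timestamps not strictly increasing at row {bad}")
    if index.has_duplicates:
        raise ValueError(f"{what} timestamps contain duplicates")
    return index


@dataclass
class ValveSeries:
    """Raw Hall-sensor output for one clam: millivolts on a (nominally) regular grid.

    NaN marks a missing tick or a QC-masked sample.
    """

    clam_id: int
    data: pd.Series
    nominal_period_s: float = 5.0

    def __post_init__(self) -> None:
        _check_index(self.data.index, "ValveSeries")
        vals = self.data.to_numpy(dtype=float)
        self.data = pd.Series(vals, index=self.data.index, name=f"clam{self.clam_id}")
        lo, hi = VOLTAGE_RANGE_MV
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError(
                f"ValveSeries clam {self.clam_id}: voltages outside [{lo}, {hi}] mV"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def voltage_mv(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum())

    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.data.index[0], self.data.index[-1]


@dataclass
class EnvSeries:
    """One environmental variable (PAR, pH, DO, temperature, chlorophyll-a RFU,
    phycoerythrin RFU) on its own time grid."""

    variable: str
    data: pd.Series
    units: str = ""
    nominal_period_s: float | None = None

    def __post_init__(self) -> None:
        if self.variable not in ENV_VARIABLES:
            raise ValueError(
                f"unknown environmental variable {self.variable!r}; "
                f"expected one of {sorted(ENV_VARIABLES)}"
            )
        _check_index(self.data.index, f"EnvSeries[{self.variable}]")
        self.data = pd.Series(
            self.data.to_numpy(dtype=float), index=self.data.index, name=self.variable
        )
        if not self.units:
            self.units = ENV_VARIABLES[self.variable]
        if self.nominal_period_s is None and len(self.data) > 1:
            self.nominal_period_s = float(
                np.median(np.diff(self.data.index.view("i8"))) / 1e9
            )
        vals = self.data.to_numpy()
        finite = vals[np.isfinite(vals)]
        if self.variable in ("PAR", "chlorophyll_a", "phycoerythrin"):
            if finite.size and finite.min() < 0:
                raise ValueError(f"{self.variable} must be non-negative")
        if self.variable == "DO" and finite.size and finite.min() <= 0:
            raise ValueError("DO must be strictly positive")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.data.index[0], self.data.index[-1]


@dataclass
class AlignedDataset:
    """Valve and environmental series averaged onto common regular grids and
    restricted to the time span covered by every input."""

    valve: dict[int, ValveSeries]
    env: dict[str, EnvSeries]
    span: tuple[pd.Timestamp, pd.Timestamp]
    valve_grid_s: float
    env_grid_s: float
    meta: dict = field(default_factory=dict)

    @property
    def clam_ids(self) -> list[int]:
        return sorted(self.valve)
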