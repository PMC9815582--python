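"""Closure-event ("valve-clap") delineation and summaries.

A closure event is a sudden transient rise in the daily z-score: the peak
must be the strict maximum of a centered moving window (3 points by default,
so that a clap spanning >15 s at 5-s logging is resolved but single-sample
noise is not), must stand out from its surroundings by at least
``min_prominence_z`` daily standard deviations, and its extent runs to the
half-prominence recrossings on either side (the event's "reopening").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gape import GapeSeries, LightPartition

#: Nocturnal behavior window: clams are partially closed and clapping between
#: 2 PM and 4 AM local; the complement (4 AM-2 PM) is peak daylight.
NIGHT_START_H = 14
NIGHT_END_H = 4


@dataclass
class ClosureEvent:
    clam_id: int
    peak_time: pd.Timestamp
    start: pd.Timestamp
    end: pd.Timestamp
    duration_s: float
    peak_z: float
    prominence_z: float
    peak_pct: float = float("nan")
    regime_at_peak: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.peak_time <= self.end):
            raise ValueError("event peak outside its span")
        if self.duration_s <= 0:
            raise ValueError("event duration must be positive")


def _segments(z: pd.Series) -> list[tuple[np.ndarray, pd.DatetimeIndex]]:
    """Split into contiguous finite runs (QC-masked spans break segments)."""
    finite = np.isfinite(z.to_numpy())
    segs = []
    d = np.diff(finite.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if finite.size and finite[0]:
        starts.insert(0, 0)
    if finite.size and finite[-1]:
        stops.append(finite.size)
    for i0, i1 in zip(starts, stops):
        segs.append((z.to_numpy()[i0:i1], z.index[i0:i1]))
    return segs


def _candidate_peaks(x: np.ndarray, window_points: int) -> np.ndarray:
    """Indices that are the earliest argmax of their centered window.

    argmax returns the first occurrence, so requiring argmax == center both
    makes the center the window maximum and breaks ties to the earliest index.
    """
    half = window_points // 2
    if len(x) < window_points:
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(x, window_points)
    return np.flatnonzero(windows.argmax(axis=1) == half) + half


def _prominence(x: np.ndarray, i: int) -> float:
    """Peak height above the higher of the two flanking base minima.

    Each base is the minimum between the peak and the nearest strictly higher
    sample (or the segment edge)."""
    p = x[i]
    j = i - 1
    left = p
    while j >= 0 and x[j] <= p:
        left = min(left, x[j])
        j -= 1
    k = i + 1
    right = p
    while k < len(x) and x[k] <= p:
        right = min(right, x[k])
        k += 1
    return p - max(left, right)


def _walk_to_level(x: np.ndarray, i: int, level: float) -> tuple[int, int]:
    """First indices at or below `level` walking outward from peak i."""
    j = i - 1
    while j > 0 and x[j] > level:
        j -= 1
    k = i + 1
    while k < len(x) - 1 and x[k] > level:
        k += 1
    return j, k


def detect_events(
    gape: GapeSeries,
    min_prominence_z: float = 1.0,
    reopen_fraction: float = 0.5,
    window_points: int = 3,
    partition: LightPartition | None = None,
) -> list[ClosureEvent]:
    """Delineate closure events in a clam's z-score series.

    A sample is a candidate peak iff it is the maximum of its centered
    ``window_points``-point window with ties broken to the earliest index;
    candidates with prominence below ``min_prominence_z`` are discarded.
    Event start/end are the nearest recrossings, walking outward from the
    peak, of the level ``peak_z - reopen_fraction * prominence``; events with
    overlapping spans are merged keeping the higher peak.
    """
    if window_points < 3 or window_points % 2 == 0:
        raise ValueError("window_points must be an odd integer >= 3")
    if not 0 < reopen_fraction <= 1:
        raise ValueError("reopen_fraction must be in (0, 1]")

    events: list[ClosureEvent] = []
    for x, idx in _segments(gape.z):
        if len(x) < window_points:
            continue
        raw: list[ClosureEvent] = []
        for i in _candidate_peaks(x, window_points):
            prom = _prominence(x, i)
            if prom < min_prominence_z:
                continue
            level = x[i] - reopen_fraction * prom
            j, k = _walk_to_level(x, i, level)
            raw.append(
                ClosureEvent(
                    clam_id=gape.clam_id,
                    peak_time=idx[i], start=idx[j], end=idx[k],
                    duration_s=(idx[k] - idx[j]).total_seconds(),
                    peak_z=float(x[i]), prominence_z=float(prom),
                )
            )
        events.extend(_merge_overlapping(raw))

    if gape.pct_closure is not None:
        pct = gape.pct_closure
        for ev in events:
            if ev.peak_time in pct.index:
                ev.peak_pct = float(pct.loc[ev.peak_time])
    if partition is not None:
        times = pd.DatetimeIndex([ev.peak_time for ev in events])
        if len(times):
            reg = partition.regime_at(times).to_numpy()
            for ev, r in zip(events, reg):
                ev.regime_at_peak = str(r)
    events.sort(key=lambda e: e.peak_time)
    return events


def _merge_overlapping(events: list[ClosureEvent]) -> list[ClosureEvent]:
    """Merge span-overlapping events: union span, keep the higher peak."""
    if not events:
        return []
    events = sorted(events, key=lambda e: (e.start, e.peak_time))
    out = [events[0]]
    for ev in events[1:]:
        cur = out[-1]
        if ev.start <= cur.end:
            winner, loser = (cur, ev) if cur.peak_z >= ev.peak_z else (ev, cur)
            merged = ClosureEvent(
                clam_id=winner.clam_id,
                peak_time=winner.peak_time,
                start=min(cur.start, ev.start),
                end=max(cur.end, ev.end),
                duration_s=(max(cur.end, ev.end) - min(cur.start, ev.start)).total_seconds(),
                peak_z=winner.peak_z,
                prominence_z=max(cur.prominence_z, ev.prominence_z),
            )
            out[-1] = merged
        else:
            out.append(ev)
    return out


def is_night(ts: pd.Timestamp) -> bool:
    """True inside the nocturnal window [14:00, 04:00 next day)."""
    return ts.hour >= NIGHT_START_H or ts.hour < NIGHT_END_H


def daily_counts(
    events: list[ClosureEvent], pooling: str = "pooled"
) -> pd.DataFrame:
    """Per-calendar-day event counts with a day/night split.

    ``pooling='per_clam'`` gives one row per (date, clam); ``'pooled'`` one
    row per date. count_day + count_night == closure_count always.
    """
    if pooling not in ("pooled", "per_clam"):
        raise ValueError("pooling must be 'pooled' or 'per_clam'")
    rows = []
    for ev in events:
        rows.append(
            {
                "date": ev.peak_time.date(),
                "clam_id": ev.clam_id,
                "night": is_night(ev.peak_time),
                "duration_s": ev.duration_s,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["closure_count", "median_duration_s", "count_day", "count_night"]
        )
    keys = ["date"] if pooling == "pooled" else ["date", "clam_id"]
    agg = df.groupby(keys).agg(
        closure_count=("night", "size"),
        median_duration_s=("duration_s", "median"),
        count_night=("night", "sum"),
    )
    agg["count_night"] = agg["count_night"].astype(int)
    agg["count_day"] = agg["closure_count"] - agg["count_night"]
    return agg


def duration_histogram(
    events: list[ClosureEvent], bin_edges_s: np.ndarray | list
) -> dict:
    """Histogram of event durations plus the fraction shorter than 100 s."""
    if not events:
        raise ValueError("duration_histogram: no events")
    durations = np.array([ev.duration_s for ev in events])
    counts, edges = np.histogram(durations, bins=np.asarray(bin_edges_s, dtype=float))
    return {
        "counts": counts,
        "bin_edges_s": edges,
        "n_events": len(durations),
        "fraction_below_100s": float((durations < 100.0).mean()),
        "median_s": float(np.median(durations)),
    }


def rank_sum_test(group_a: np.ndarray, group_b: np.ndarray) -> dict:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    The statistic W is reported as the rank sum of the first group (so for
    complete separation [1,2,3] vs [4,5,6] it is the minimal 6).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test: both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U1 -> rank sum
    return {"W": w, "U": float(res.statistic), "p": float(res.pvalue),
            "n_a": int(a.size), "n_b": int(b.size)}


def compare_durations(
    events: list[ClosureEvent], grouping: str = "day_vs_night"
) -> pd.DataFrame:
    """Rank-sum comparison of event durations, day vs night, per clam and pooled."""
    if grouping != "day_vs_night":
        raise ValueError(f"unknown grouping {grouping!r}")
    df = pd.DataFrame(
        {
            "clam_id": [ev.clam_id for ev in events],
            "duration_s": [ev.duration_s for ev in events],
            "night": [is_night(ev.peak_time) for ev in events],
        }
    )
    rows = []
    groups = [("pooled", df)] + [(cid, g) for cid, g in df.groupby("clam_id")]
    for label, g in groups:
        night = g.loc[g["night"], "duration_s"].to_numpy()
        day = g.loc[~g["night"], "duration_s"].to_numpy()
        if night.size == 0 or day.size == 0:
            rows.append({"clam": label, "W": np.nan, "p": np.nan,
                         "n_night": night.size, "n_day": day.size})
            continue
        res = rank_sum_test(night, day)
        rows.append({"clam": label, "W": res["W"], "p": res["p"],
                     "n_night": night.size, "n_day": day.size})
    return pd.DataFrame(rows).set_index("clam")


def events_to_frame(events: list[ClosureEvent]) -> pd.DataFrame:
    """Tabular view (one row per event) for CSV export."""
    return pd.DataFrame(
        {
            "clam_id": [e.clam_id for e in events],
            "peak_time": [e.peak_time for e in events],
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "duration_s": [e.duration_s for e in events],
            "peak_z": [e.peak_z for e in events],
            "prominence_z": [e.prominence_z for e in events],
            "peak_pct": [e.peak_pct for e in events],
            "regime": [e.regime_at_peak for e in events],
        }
    )
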