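"""Reading, correcting and aggregating multimode plate-reader exports.

The native dialect is tidy long form, one reading per row::

    well,condition,channel,time_hr,value
    A1,control,OD600,0.0,0.041

with channels ``OD600`` and ``FL``.  A wide-matrix reader (one time column
plus one column per well, a separate layout CSV mapping wells to conditions)
covers common instrument exports.  OD readings from shallow microplate wells
are put on the standard 1 cm path by multiplying with a pre-calibrated factor
(default 2.39).  Replicate wells are aggregated pointwise into mean and
standard error of the mean; the aggregated curves feed the derivative/peak
pipeline and the Gompertz fit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .derivatives import Curve, forward_diff, hanning_smooth
from .errors import FormatError, InvalidInputError
from .gompertz import GompertzFit, fit_gompertz
from .peaks import PeakSummary, find_peak

__all__ = [
    "LONG_COLUMNS",
    "PlateDataset",
    "ConditionCurve",
    "ConditionAnalysis",
    "load_plate_csv",
    "load_wide_csv",
    "correct_od",
    "subtract_blank",
    "aggregate",
    "analyze_condition",
]

LONG_COLUMNS = ["well", "condition", "channel", "time_hr", "value"]
DEFAULT_PATHLENGTH_FACTOR = 2.39
CHANNELS = ("OD600", "FL")


@dataclass
class PlateDataset:
    """Per-well time series in long form with shared uniform time grids."""

    data: pd.DataFrame  # columns LONG_COLUMNS
    interval: float  # sampling period, hr
    pathlength_factor: float = 1.0  # correction already applied to OD values
    negative_od_wells: tuple[str, ...] = ()

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["condition"]))

    @property
    def wells(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["well"]))

    def times(self, channel: str) -> np.ndarray:
        sel = self.data[self.data["channel"] == channel]
        if sel.empty:
            raise InvalidInputError(f"no data for channel {channel!r}")
        first_well = sel["well"].iloc[0]
        return sel.loc[sel["well"] == first_well, "time_hr"].to_numpy()


def _validate_grid(df: pd.DataFrame) -> float:
    """Check one shared uniform grid per channel; return the sampling period."""
    dup = df.duplicated(subset=["well", "channel", "time_hr"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"duplicate reading for well {row['well']!r} channel {row['channel']!r} "
            f"at time {row['time_hr']}"
        )
    intervals = set()
    for channel, chan_df in df.groupby("channel"):
        grids = {}
        for well, well_df in chan_df.groupby("well"):
            t = well_df["time_hr"].to_numpy()
            if t.size < 2:
                raise FormatError(f"well {well!r} channel {channel!r} has fewer than 2 points")
            if np.any(np.diff(t) <= 0):
                raise FormatError(f"non-monotone times in well {well!r} channel {channel!r}")
            steps = np.diff(t)
            if np.any(np.abs(steps - steps[0]) > 1e-9 * max(steps[0], 1.0)):
                raise FormatError(f"non-uniform time grid in well {well!r} channel {channel!r}")
            grids[well] = t
        reference = next(iter(grids.values()))
        for well, t in grids.items():
            if t.size != reference.size or not np.allclose(t, reference, rtol=0, atol=1e-9):
                raise FormatError(
                    f"well {well!r} channel {channel!r} is not on the shared time grid "
                    f"({t.size} vs {reference.size} points)"
                )
        intervals.add(round(float(reference[1] - reference[0]), 12))
    if len(intervals) != 1:
        raise FormatError(f"channels disagree on the sampling interval: {sorted(intervals)}")
    return intervals.pop()


def load_plate_csv(path, layout_map: dict[str, str] | None = None) -> PlateDataset:
    """Read a tidy long-form export; optionally (re)assign conditions.

    ``layout_map`` maps well ids to condition labels; wells absent from a
    provided map are dropped (the skipped ids are recorded on the dataset's
    data attrs for the run log).
    """
    try:
        df = pd.read_csv(path, dtype={"well": str, "condition": str, "channel": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; expected {LONG_COLUMNS}")
    df = df[LONG_COLUMNS].copy()
    if df[["time_hr", "value"]].isna().any().any():
        bad = df[df[["time_hr", "value"]].isna().any(axis=1)].index[0]
        raise FormatError(f"{path}: non-numeric or missing entry at data row {bad + 1}")
    dropped: list[str] = []
    if layout_map is not None:
        keep = df["well"].isin(layout_map)
        dropped = sorted(set(df.loc[~keep, "well"]))
        df = df[keep].copy()
        df["condition"] = df["well"].map(layout_map)
    df = df.sort_values(["channel", "well", "time_hr"], kind="mergesort").reset_index(drop=True)
    interval = _validate_grid(df)
    df.attrs["unmapped_wells"] = dropped
    return PlateDataset(data=df, interval=interval)


def load_wide_csv(path, layout_map: dict[str, str], channel: str = "OD600") -> PlateDataset:
    """Read a wide export (time column + one column per well) for one channel."""
    if channel not in CHANNELS:
        raise InvalidInputError(f"channel must be one of {CHANNELS}, got {channel!r}")
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: wide format needs a time column plus well columns")
    time_col = df.columns[0]
    long = df.melt(id_vars=[time_col], var_name="well", value_name="value")
    long = long.rename(columns={time_col: "time_hr"})
    long = long[long["well"].isin(layout_map)].copy()
    if long.empty:
        raise FormatError(f"{path}: no well columns match the layout map")
    long["condition"] = long["well"].map(layout_map)
    long["channel"] = channel
    long = long[LONG_COLUMNS].sort_values(["well", "time_hr"], kind="mergesort")
    interval = _validate_grid(long)
    return PlateDataset(data=long.reset_index(drop=True), interval=interval)


def correct_od(
    dataset: PlateDataset, factor: float = DEFAULT_PATHLENGTH_FACTOR
) -> PlateDataset:
    """Multiply OD readings by the path-length factor; FL is untouched.

    Wells whose corrected OD dips below zero (blank over-subtraction) are
    flagged on the returned dataset, never clipped.
    """
    if factor <= 0:
        raise InvalidInputError(f"path-length factor must be > 0, got {factor}")
    df = dataset.data.copy()
    od_mask = df["channel"] == "OD600"
    df.loc[od_mask, "value"] = df.loc[od_mask, "value"] * factor
    negative = df[od_mask & (df["value"] < 0)]["well"]
    return replace(
        dataset,
        data=df,
        pathlength_factor=dataset.pathlength_factor * factor,
        negative_od_wells=tuple(sorted(set(dataset.negative_od_wells) | set(negative))),
    )


def subtract_blank(dataset: PlateDataset, blank_condition: str) -> PlateDataset:
    """Subtract the blank condition's mean curve per channel, then drop it."""
    df = dataset.data
    if blank_condition not in dataset.conditions:
        raise InvalidInputError(f"blank condition {blank_condition!r} not in dataset")
    out = []
    for channel, chan_df in df.groupby("channel"):
        blank = (
            chan_df[chan_df["condition"] == blank_condition]
            .groupby("time_hr")["value"]
            .mean()
        )
        rest = chan_df[chan_df["condition"] != blank_condition].copy()
        rest["value"] = rest["value"] - rest["time_hr"].map(blank).to_numpy()
        out.append(rest)
    merged = pd.concat(out).sort_values(["channel", "well", "time_hr"], kind="mergesort")
    return replace(dataset, data=merged.reset_index(drop=True))


@dataclass
class ConditionCurve:
    """Replicate-aggregated curve: pointwise mean with SEM = SD/sqrt(n)."""

    condition: str
    channel: str
    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_replicates: int

    @property
    def single_replicate(self) -> bool:
        return self.n_replicates == 1

    @property
    def curve(self) -> Curve:
        return Curve(self.times, self.mean, label=f"{self.condition}:{self.channel}")


def aggregate(dataset: PlateDataset, condition: str, channel: str) -> ConditionCurve:
    """Pointwise mean and SEM over the replicate wells of one condition."""
    sel = dataset.data[
        (dataset.data["condition"] == condition) & (dataset.data["channel"] == channel)
    ]
    if sel.empty:
        raise InvalidInputError(f"no wells for condition {condition!r} channel {channel!r}")
    wide = sel.pivot(index="time_hr", columns="well", values="value")
    n = wide.shape[1]
    mean = wide.mean(axis=1).to_numpy()
    sem = (
        np.zeros_like(mean)
        if n == 1
        else (wide.std(axis=1, ddof=1) / np.sqrt(n)).to_numpy()
    )
    return ConditionCurve(
        condition=condition,
        channel=channel,
        times=wide.index.to_numpy(dtype=float),
        mean=mean,
        sem=sem,
        n_replicates=n,
    )


@dataclass
class ConditionAnalysis:
    """Outputs of the derivative pipeline for one aggregated curve."""

    condition: str
    channel: str
    smoothed: Curve
    derivative: Curve  # dOD/dt for OD600, d2FL/dt2 for FL
    peak: PeakSummary
    gompertz: GompertzFit | None = None  # OD channel only


def analyze_condition(
    cond_curve: ConditionCurve,
    smooth_window: int = 11,
    od_ceiling: float | None = 1.0,
    search_window: tuple[float, float] | None = None,
    resmooth: bool = False,
) -> ConditionAnalysis:
    """Smooth, differentiate and peak-summarize one aggregated curve.

    OD600: Hann smoothing, first derivative, peak, plus a Gompertz fit of
    ln(OD/OD0) on the unsmoothed mean truncated at ``od_ceiling``.  FL: Hann
    smoothing, second derivative (optionally re-smoothed between the two
    differencings), peak.  ``search_window`` can exclude early-time artifact
    peaks (e.g. nanoparticle interference).
    """
    raw = cond_curve.curve
    smoothed = hanning_smooth(raw, window=smooth_window)
    if cond_curve.channel == "OD600":
        deriv = forward_diff(smoothed)
        gomp = fit_gompertz(raw, od_ceiling=od_ceiling)
    elif cond_curve.channel == "FL":
        first = forward_diff(smoothed)
        if resmooth:
            first = hanning_smooth(first, window=min(smooth_window, len(first) - (1 - len(first) % 2)))
        deriv = forward_diff(first)
        gomp = None
    else:
        raise InvalidInputError(f"unknown channel {cond_curve.channel!r}")
    peak = find_peak(deriv, search_window=search_window)
    return ConditionAnalysis(
        condition=cond_curve.condition,
        channel=cond_curve.channel,
        smoothed=smoothed,
        derivative=deriv,
        peak=peak,
        gompertz=gomp,
    )
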