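"""Turn raw RR-interval and acceleration streams into an aligned 30-s sample grid.

The grid is the substrate for everything downstream: each row is one
``window_s``-second window carrying the window's RMSSD (ms), mean tri-axial
acceleration (g), the day and clock hour it falls in, and a sleep flag.
Missingness is flagged with NaN, never dropped, so window indices stay
contiguous and row counts are conserved by every operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86400.0

GRID_COLUMNS = ["index", "day", "hour", "rmssd_ms", "acc_g", "asleep"]


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def _check_monotone(times: np.ndarray, what: str) -> None:
    if times.size == 0:
        raise ValueError(f"empty {what}")
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{what} times must be strictly increasing; "
            f"first violation at sample {bad[0] + 1} (t={times[bad[0] + 1]:g} s)"
        )


@dataclass
class RRSeries:
    """A participant's ordered interbeat-interval series.

    ``time_s`` is seconds from session start for each beat; ``rr_ms`` the
    interval ending at that beat. Implausible intervals (outside
    ``rr_bounds_ms``) are flagged via :meth:`plausible_mask`, not removed.
    """

    participant_id: str
    time_s: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = _as_float_array(self.time_s, "time_s")
        self.rr_ms = _as_float_array(self.rr_ms, "rr_ms")
        if self.time_s.shape != self.rr_ms.shape:
            raise ValueError("time_s and rr_ms must have equal length")
        _check_monotone(self.time_s, "RR series")
        if np.any(self.rr_ms <= 0):
            raise ValueError("rr_ms must be strictly positive")

    def plausible_mask(self, rr_bounds_ms: tuple[float, float] = (300.0, 2000.0)) -> np.ndarray:
        lo, hi = rr_bounds_ms
        return (self.rr_ms >= lo) & (self.rr_ms <= hi)


@dataclass
class AccelSeries:
    """Raw tri-axial (or pre-averaged single-channel) acceleration samples in g."""

    participant_id: str
    time_s: np.ndarray
    ax_g: np.ndarray | None = None
    ay_g: np.ndarray | None = None
    az_g: np.ndarray | None = None
    acc_g: np.ndarray | None = None  # pre-averaged magnitude channel

    def __post_init__(self) -> None:
        self.time_s = _as_float_array(self.time_s, "time_s")
        _check_monotone(self.time_s, "acceleration series")
        if self.acc_g is not None:
            self.acc_g = _as_float_array(self.acc_g, "acc_g")
            if self.acc_g.shape != self.time_s.shape:
                raise ValueError("acc_g and time_s must have equal length")
            if np.any(self.acc_g < 0):
                raise ValueError("pre-averaged acc_g must be non-negative")
        else:
            if self.ax_g is None or self.ay_g is None or self.az_g is None:
                raise ValueError("provide either acc_g or all of ax_g, ay_g, az_g")
            for name in ("ax_g", "ay_g", "az_g"):
                arr = _as_float_array(getattr(self, name), name)
                if arr.shape != self.time_s.shape:
                    raise ValueError(f"{name} and time_s must have equal length")
                setattr(self, name, arr)


@dataclass
class SampleGrid:
    """The aligned 30-s lattice of (RMSSD, acceleration, day, hour, sleep).

    ``frame`` columns: index (contiguous ints from 0), day (1-based), hour
    (0-23 clock hour within day), rmssd_ms, acc_g (NaN = missing), asleep
    (bool). A row with either value NaN counts as missing downstream.
    24 h of complete data at the default 30-s window is 2880 rows.
    """

    participant_id: str
    window_s: float
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in GRID_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"grid frame lacks columns {missing}")
        self.frame = self.frame.loc[:, GRID_COLUMNS].reset_index(drop=True)
        idx = self.frame["index"].to_numpy()
        if idx.size and np.any(np.diff(idx) != 1):
            raise ValueError("window index must be contiguous")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def missing_mask(self) -> np.ndarray:
        f = self.frame
        return (f["rmssd_ms"].isna() | f["acc_g"].isna()).to_numpy()

    def copy(self) -> "SampleGrid":
        return SampleGrid(self.participant_id, self.window_s, self.frame.copy())


def _empty_grid_frame(n_windows: int, window_s: float) -> pd.DataFrame:
    index = np.arange(n_windows, dtype=int)
    day = (index * window_s // SECONDS_PER_DAY).astype(int) + 1
    hour = ((index * window_s // 3600.0) % 24).astype(int)
    return pd.DataFrame(
        {
            "index": index,
            "day": day,
            "hour": hour,
            "rmssd_ms": np.full(n_windows, np.nan),
            "acc_g": np.full(n_windows, np.nan),
            "asleep": np.zeros(n_windows, dtype=bool),
        }
    )


def _n_windows(t_last: float, window_s: float) -> int:
    return int(np.floor(t_last / window_s)) + 1


def compute_rmssd_windows(
    rr: RRSeries,
    window_s: float = 30.0,
    rr_bounds_ms: tuple[float, float] = (300.0, 2000.0),
    min_beats: int = 3,
) -> SampleGrid:
    """Windowed RMSSD: sqrt(mean of squared successive RR differences).

    Windows are half-open [k*w, (k+1)*w) from session start; a difference pair
    contributes only when both beats fall in the same window and both are
    physiologically plausible, so masked beats break difference chains and no
    pair straddles a window boundary. Windows with fewer than ``min_beats``
    plausible beats (or no usable pair) are missing.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    plaus = rr.plausible_mask(rr_bounds_ms)
    win = np.floor(rr.time_s / window_s).astype(int)
    n_win = _n_windows(rr.time_s[-1], window_s)

    beats_per_win = np.bincount(win[plaus], minlength=n_win)

    # successive pairs: beats i and i+1, both plausible, same window
    same_win = win[:-1] == win[1:]
    pair_ok = same_win & plaus[:-1] & plaus[1:]
    diffs = np.diff(rr.rr_ms)
    pair_win = win[:-1][pair_ok]
    sq = diffs[pair_ok] ** 2
    n_pairs = np.bincount(pair_win, minlength=n_win)
    sumsq = np.bincount(pair_win, weights=sq, minlength=n_win)

    rmssd = np.full(n_win, np.nan)
    ok = (beats_per_win >= min_beats) & (n_pairs > 0)
    rmssd[ok] = np.sqrt(sumsq[ok] / n_pairs[ok])

    frame = _empty_grid_frame(n_win, window_s)
    frame["rmssd_ms"] = rmssd
    return SampleGrid(rr.participant_id, window_s, frame)


def aggregate_acceleration(
    acc: AccelSeries,
    window_s: float = 30.0,
    magnitude: str = "mean_abs",
) -> SampleGrid:
    """Mean per-window movement magnitude in g.

    Each raw sample is reduced to a scalar: the mean of the three axes'
    absolute values (``magnitude='mean_abs'``, the default) or the Euclidean
    norm (``'euclidean'``); a pre-averaged ``acc_g`` channel is used as-is.
    Windows containing no samples are missing.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if acc.acc_g is not None:
        per_sample = acc.acc_g
    elif magnitude == "mean_abs":
        per_sample = (np.abs(acc.ax_g) + np.abs(acc.ay_g) + np.abs(acc.az_g)) / 3.0
    elif magnitude == "euclidean":
        per_sample = np.sqrt(acc.ax_g**2 + acc.ay_g**2 + acc.az_g**2)
    else:
        raise ValueError(f"unknown magnitude rule {magnitude!r}")

    win = np.floor(acc.time_s / window_s).astype(int)
    n_win = _n_windows(acc.time_s[-1], window_s)
    counts = np.bincount(win, minlength=n_win)
    sums = np.bincount(win, weights=per_sample, minlength=n_win)
    mean = np.full(n_win, np.nan)
    np.divide(sums, counts, out=mean, where=counts > 0)

    frame = _empty_grid_frame(n_win, window_s)
    frame["acc_g"] = mean
    return SampleGrid(acc.participant_id, window_s, frame)


def build_sample_grid(
    rmssd_part: SampleGrid,
    acc_part: SampleGrid,
    sleep: list[tuple[float, float]] | None = None,
    day_boundaries: list[float] | None = None,
) -> SampleGrid:
    """Join the RMSSD and acceleration partial grids on window index.

    A window is asleep iff its midpoint falls in a sleep interval
    [start_s, end_s). Days default to consecutive 24-h blocks from session
    start; explicit ``day_boundaries`` (seconds) override that, with day d
    covering [boundary[d-1], boundary[d]).
    """
    if rmssd_part.window_s != acc_part.window_s:
        raise ValueError(
            f"window_s mismatch: {rmssd_part.window_s} vs {acc_part.window_s}"
        )
    if rmssd_part.participant_id != acc_part.participant_id:
        raise ValueError("participant mismatch between partial grids")
    w = rmssd_part.window_s
    n_win = max(len(rmssd_part), len(acc_part))
    frame = _empty_grid_frame(n_win, w)
    frame.loc[: len(rmssd_part) - 1, "rmssd_ms"] = rmssd_part.frame["rmssd_ms"].to_numpy()
    frame.loc[: len(acc_part) - 1, "acc_g"] = acc_part.frame["acc_g"].to_numpy()

    mid = (frame["index"].to_numpy() + 0.5) * w
    if sleep:
        asleep = np.zeros(n_win, dtype=bool)
        for start_s, end_s in sleep:
            asleep |= (mid >= start_s) & (mid < end_s)
        frame["asleep"] = asleep
    if day_boundaries is not None:
        edges = np.asarray(day_boundaries, dtype=float)
        frame["day"] = np.searchsorted(edges, mid, side="right") + 1
    return SampleGrid(rmssd_part.participant_id, w, frame)
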