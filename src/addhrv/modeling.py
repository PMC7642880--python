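"""Individualized inverse regression of RMSSD on movement, and the seven
fitting-subset strategies that differentiate the detection methods.

The model is a per-participant straight line

    expected_rmssd = b0 + b1 * acceleration

with b0 the RMSSD expected at zero movement and b1 (typically negative, the
"inverse" HRV-movement relation) the change per g. Alongside each fit the
standard error of the mean (SEM) of the observed RMSSD over the fitting
subset is recorded; the detector's threshold is expressed in units of this
SEM. The seven methods differ only in which windows enter the fit:

========================  ====================================================
method                    fitting subset
========================  ====================================================
calibration               scripted lab activities, stress tasks excluded
calibration_extended      scripted lab activities including stress tasks
hourly10                  first ``lead_min`` minutes of each (day, hour)
full                      every window of the day (or whole session)
threehour10               first ``lead_min`` minutes of hours h-1, h, h+1
bins                      first 5-min run inside each movement quartile
nextday                   all of day d-1, applied to day d
========================  ====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy import stats

from .preprocessing import SampleGrid

METHODS = (
    "calibration",
    "hourly10",
    "full",
    "threehour10",
    "bins",
    "calibration_extended",
    "nextday",
)

CALIBRATION_ACTIVITIES = (
    "sit_video",
    "stand_count",
    "lie_count",
    "cycle",
    "clench_tense",
    "read_aloud",
    "stairs",
)

#: activities present only in the extended calibration protocol
STRESS_ACTIVITIES = frozenset({"clench_tense", "read_aloud"})


class ModelForm(str, Enum):
    LINEAR = "linear"
    RECIPROCAL = "reciprocal"


@dataclass(frozen=True)
class MethodConfig:
    """Parameters shared by fitting and detection.

    lead_min: minutes used from the start of each hour (hourly10/threehour10).
    bin_min: minutes of consecutive data forming one movement bin.
    k_sem: detection threshold in SEM multiples.
    min_episode_min: minimum episode duration in minutes.
    """

    method: str = "full"
    lead_min: float = 10.0
    bin_min: float = 5.0
    k_sem: float = 2.0
    min_episode_min: float = 7.5
    window_s: float = 30.0
    model_form: ModelForm = ModelForm.LINEAR
    reciprocal_eps: float = 0.01
    full_scope: str = "day"  # "day" or "session"

    def __post_init__(self) -> None:
        for name in ("lead_min", "bin_min", "k_sem", "min_episode_min", "window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.full_scope not in ("day", "session"):
            raise ValueError("full_scope must be 'day' or 'session'")

    @property
    def min_episode_windows(self) -> int:
        return int(np.ceil(self.min_episode_min * 60.0 / self.window_s))

    @property
    def lead_windows(self) -> int:
        return int(round(self.lead_min * 60.0 / self.window_s))

    @property
    def bin_windows(self) -> int:
        return int(round(self.bin_min * 60.0 / self.window_s))


@dataclass(frozen=True)
class Scope:
    """Which windows a fit governs during detection.

    kind "hour": (day, hour). kind "day": all of `day` (full, bins).
    kind "session": every window (full with full_scope="session",
    calibration methods). kind "previous-day": fitted on day-1 data,
    governs `day`.
    """

    kind: str
    day: int | None = None
    hour: int | None = None

    def governs(self, day: int, hour: int) -> bool:
        if self.kind == "session":
            return True
        if self.kind in ("day", "previous-day"):
            return day == self.day
        if self.kind == "hour":
            return day == self.day and hour == self.hour
        raise ValueError(f"unknown scope kind {self.kind!r}")


@dataclass
class RegressionFit:
    """One fitted inverse regression model plus its detection threshold unit."""

    participant_id: str
    scope: Scope
    b0_ms: float
    b1: float
    sem_ms: float
    n: int
    valid: bool
    method: str | None = None


@dataclass(frozen=True)
class CalibrationSegment:
    participant_id: str
    activity: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.activity not in CALIBRATION_ACTIVITIES:
            raise ValueError(f"unknown calibration activity {self.activity!r}")
        if not self.end_s > self.start_s:
            raise ValueError("calibration segment must have end_s > start_s")


@dataclass(frozen=True)
class MovementBin:
    quartile: int  # 1..4
    start_index: int
    length: int


def fit_regression(
    acc_g: np.ndarray,
    rmssd_ms: np.ndarray,
    scope: Scope,
    participant_id: str = "",
) -> RegressionFit:
    """Ordinary least squares of RMSSD on acceleration over one subset.

    ``sem_ms`` is the standard error of the mean of the observed RMSSD
    (sample SD with n-1 denominator over sqrt(n)) -- the spread of the data
    entering the fit, not the regression standard error. A subset with fewer
    than two samples or constant acceleration yields ``valid=False`` (a
    degenerate design, not an error); an empty subset is an error.
    """
    acc_g = np.asarray(acc_g, dtype=float)
    rmssd_ms = np.asarray(rmssd_ms, dtype=float)
    if acc_g.size == 0:
        raise ValueError("cannot fit regression on an empty subset")
    if acc_g.shape != rmssd_ms.shape:
        raise ValueError("acc_g and rmssd_ms must have equal length")
    n = acc_g.size
    sem = float(np.std(rmssd_ms, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    degenerate = n < 2 or np.unique(acc_g).size < 2
    if degenerate:
        return RegressionFit(participant_id, scope, float("nan"), float("nan"), sem, n, False)
    res = stats.linregress(acc_g, rmssd_ms)
    return RegressionFit(
        participant_id, scope, float(res.intercept), float(res.slope), sem, n, True
    )


def _present_mask(grid: SampleGrid) -> np.ndarray:
    return ~grid.missing_mask


def find_movement_bins(
    grid: SampleGrid,
    cfg: MethodConfig,
    days: list[int] | None = None,
    quartile_edges: np.ndarray | None = None,
) -> list[MovementBin]:
    """First qualifying run of ``bin_min`` consecutive minutes per movement quartile.

    Quartile boundaries (25/50/75th percentiles) are computed from the
    participant's non-missing acceleration over the whole grid unless
    ``quartile_edges`` is given; runs may be restricted to ``days``. Ranges
    are half-open -- Q1 [min, P25), Q2 [P25, P50), Q3 [P50, P75) -- except
    the top quartile Q4 [P75, max], so a boundary value goes to the upper
    quartile. Quartiles with no qualifying run are simply absent.
    """
    f = grid.frame
    present = _present_mask(grid)
    acc = f["acc_g"].to_numpy()
    acc_all = acc[present]
    if acc_all.size < 4 or np.unique(acc_all).size < 4:
        raise ValueError("need at least 4 distinct non-missing acceleration values")
    if quartile_edges is None:
        quartile_edges = np.percentile(acc_all, [25, 50, 75])
    p25, p50, p75 = quartile_edges
    in_quartile = [
        present & (acc < p25),
        present & (acc >= p25) & (acc < p50),
        present & (acc >= p50) & (acc < p75),
        present & (acc >= p75),
    ]
    if days is not None:
        day_ok = f["day"].isin(days).to_numpy()
        in_quartile = [m & day_ok for m in in_quartile]

    length = cfg.bin_windows
    index = f["index"].to_numpy()
    bins: list[MovementBin] = []
    for q, mask in enumerate(in_quartile, start=1):
        start = _first_run(mask, length)
        if start is not None:
            bins.append(MovementBin(q, int(index[start]), length))
    return bins


def _first_run(mask: np.ndarray, length: int) -> int | None:
    """Position of the first run of ``length`` consecutive True values."""
    run = 0
    for i, ok in enumerate(mask):
        run = run + 1 if ok else 0
        if run == length:
            return i - length + 1
    return None


def select_fitting_subsets(
    grid: SampleGrid,
    cfg: MethodConfig,
    calib: list[CalibrationSegment] | None = None,
) -> list[tuple[Scope, np.ndarray]]:
    """Map a method to its (scope, window-index array) fitting subsets.

    Index arrays refer to the grid's ``index`` column and include missing
    windows; missingness is resolved at fit time so subset *positions* depend
    only on the lattice, never on the data values.
    """
    f = grid.frame
    if len(f) == 0:
        raise ValueError("empty sample grid")
    index = f["index"].to_numpy()
    day = f["day"].to_numpy()
    hour = f["hour"].to_numpy()
    days = sorted(np.unique(day).tolist())
    w = grid.window_s
    windows_per_hour = int(round(3600.0 / w))
    offset_in_hour = index % windows_per_hour
    method = cfg.method

    subsets: list[tuple[Scope, np.ndarray]] = []
    if method == "hourly10":
        lead = offset_in_hour < cfg.lead_windows
        for d in days:
            for h in sorted(np.unique(hour[day == d]).tolist()):
                sel = index[(day == d) & (hour == h) & lead]
                subsets.append((Scope("hour", d, h), sel))
    elif method == "full":
        if cfg.full_scope == "session":
            subsets.append((Scope("session"), index.copy()))
        else:
            for d in days:
                subsets.append((Scope("day", d), index[day == d]))
    elif method == "threehour10":
        lead = offset_in_hour < cfg.lead_windows
        for d in days:
            hours = sorted(np.unique(hour[day == d]).tolist())
            first, last = hours[0], hours[-1]
            for h in hours:
                if h == first and len(hours) > 1:
                    trio = hours[:2]
                elif h == last and len(hours) > 1:
                    trio = hours[-2:]
                else:
                    trio = [hh for hh in (h - 1, h, h + 1) if hh in hours]
                sel = index[(day == d) & np.isin(hour, trio) & lead]
                subsets.append((Scope("hour", d, h), sel))
    elif method == "bins":
        acc_all = f["acc_g"].to_numpy()[_present_mask(grid)]
        if acc_all.size < 4 or np.unique(acc_all).size < 4:
            raise ValueError("need at least 4 distinct non-missing acceleration values")
        edges = np.percentile(acc_all, [25, 50, 75])
        for d in days:
            found = find_movement_bins(grid, cfg, days=[d], quartile_edges=edges)
            if not found:
                subsets.append((Scope("day", d), np.empty(0, dtype=int)))
                continue
            sel = np.concatenate(
                [np.arange(b.start_index, b.start_index + b.length) for b in found]
            )
            subsets.append((Scope("day", d), np.sort(sel)))
    elif method in ("calibration", "calibration_extended"):
        if not calib:
            raise ValueError(f"method {method!r} requires calibration segments")
        segments = [
            s
            for s in calib
            if method == "calibration_extended" or s.activity not in STRESS_ACTIVITIES
        ]
        mid = (index + 0.5) * w
        sel_mask = np.zeros(len(f), dtype=bool)
        for s in segments:
            sel_mask |= (mid >= s.start_s) & (mid < s.end_s)
        subsets.append((Scope("session"), index[sel_mask]))
    elif method == "nextday":
        for d in days:
            if d - 1 in days:
                subsets.append((Scope("previous-day", d), index[day == d - 1]))
    else:  # pragma: no cover - guarded by MethodConfig
        raise ValueError(f"unknown method {method!r}")
    return subsets


def fit_method(
    grid: SampleGrid,
    cfg: MethodConfig,
    calib: list[CalibrationSegment] | None = None,
) -> list[RegressionFit]:
    """Fit every subset of the configured method; degenerate subsets give
    ``valid=False`` fits that downstream detection simply skips."""
    f = grid.frame
    present = _present_mask(grid)
    pos_of_index = {int(i): p for p, i in enumerate(f["index"].to_numpy())}
    fits: list[RegressionFit] = []
    for scope, sel in select_fitting_subsets(grid, cfg, calib):
        pos = np.array([pos_of_index[int(i)] for i in sel], dtype=int)
        pos = pos[present[pos]] if pos.size else pos
        if pos.size == 0:
            fit = RegressionFit(
                grid.participant_id, scope, float("nan"), float("nan"), float("nan"), 0, False
            )
        else:
            fit = fit_regression(
                f["acc_g"].to_numpy()[pos],
                f["rmssd_ms"].to_numpy()[pos],
                scope,
                grid.participant_id,
            )
        fit.method = cfg.method
        fits.append(fit)
    return fits


def config_for(method: str, **overrides) -> MethodConfig:
    """Convenience constructor: defaults with the method switched."""
    return replace(MethodConfig(), method=method, **overrides)
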