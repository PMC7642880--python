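"""CSV interfaces.

All pipeline artifacts round-trip through plain CSV so labs can inspect or
substitute any stage. Missing values are empty strings. Readers validate
schemas and raise errors naming the file and column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .detection import Episode
from .evaluation import SelfReport
from .modeling import CalibrationSegment, RegressionFit, Scope
from .preprocessing import GRID_COLUMNS, AccelSeries, RRSeries, SampleGrid


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _read_csv(path, cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, cols, path)
    return df


def read_beats(path) -> dict[str, RRSeries]:
    df = _read_csv(path, ["participant_id", "time_s", "rr_ms"])
    out = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        try:
            out[str(pid)] = RRSeries(str(pid), sub["time_s"].to_numpy(), sub["rr_ms"].to_numpy())
        except ValueError as e:
            raise ValueError(f"{path}: participant {pid}: {e}") from e
    return out


def write_beats(series: dict[str, RRSeries], path) -> None:
    frames = [
        pd.DataFrame({"participant_id": pid, "time_s": s.time_s, "rr_ms": s.rr_ms})
        for pid, s in series.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_accel(path) -> dict[str, AccelSeries]:
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "time_s"], path)
    triaxial = {"ax_g", "ay_g", "az_g"}.issubset(df.columns)
    if not triaxial and "acc_g" not in df.columns:
        raise ValueError(f"{path}: need either ax_g/ay_g/az_g or acc_g")
    out = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        try:
            if triaxial:
                out[str(pid)] = AccelSeries(
                    str(pid),
                    sub["time_s"].to_numpy(),
                    sub["ax_g"].to_numpy(),
                    sub["ay_g"].to_numpy(),
                    sub["az_g"].to_numpy(),
                )
            else:
                out[str(pid)] = AccelSeries(
                    str(pid), sub["time_s"].to_numpy(), acc_g=sub["acc_g"].to_numpy()
                )
        except ValueError as e:
            raise ValueError(f"{path}: participant {pid}: {e}") from e
    return out


def read_sleep(path) -> dict[str, list[tuple[float, float]]]:
    df = _read_csv(path, ["participant_id", "start_s", "end_s"])
    out: dict[str, list[tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.participant_id), []).append((float(row.start_s), float(row.end_s)))
    return out


def write_grid(grids: dict[str, SampleGrid], path) -> None:
    frames = []
    for pid, g in grids.items():
        f = g.frame.copy()
        f.insert(0, "participant_id", pid)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_grid(path, window_s: float = 30.0) -> dict[str, SampleGrid]:
    df = _read_csv(path, ["participant_id"] + GRID_COLUMNS)
    out = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        f = sub[GRID_COLUMNS].reset_index(drop=True)
        f["asleep"] = f["asleep"].astype(bool)
        out[str(pid)] = SampleGrid(str(pid), window_s, f)
    return out


def read_calibration(path) -> dict[str, list[CalibrationSegment]]:
    df = _read_csv(path, ["participant_id", "activity", "start_s", "end_s"])
    out: dict[str, list[CalibrationSegment]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            seg = CalibrationSegment(
                str(row.participant_id), str(row.activity), float(row.start_s), float(row.end_s)
            )
        except ValueError as e:
            raise ValueError(f"{path}: row {i}: {e}") from e
        out.setdefault(seg.participant_id, []).append(seg)
    return out


def write_calibration(calib: dict[str, list[CalibrationSegment]], path) -> None:
    rows = [
        {
            "participant_id": s.participant_id,
            "activity": s.activity,
            "start_s": s.start_s,
            "end_s": s.end_s,
        }
        for segs in calib.values()
        for s in segs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


FIT_COLUMNS = [
    "participant_id",
    "method",
    "scope_kind",
    "scope_day",
    "scope_hour",
    "b0_ms",
    "b1",
    "sem_ms",
    "n",
    "valid",
]


def write_fits(fits: list[RegressionFit], path) -> None:
    rows = [
        {
            "participant_id": f.participant_id,
            "method": f.method,
            "scope_kind": f.scope.kind,
            "scope_day": f.scope.day,
            "scope_hour": f.scope.hour,
            "b0_ms": f.b0_ms,
            "b1": f.b1,
            "sem_ms": f.sem_ms,
            "n": f.n,
            "valid": f.valid,
        }
        for f in fits
    ]
    pd.DataFrame(rows, columns=FIT_COLUMNS).to_csv(path, index=False)


def read_fits(path) -> list[RegressionFit]:
    df = _read_csv(path, FIT_COLUMNS)
    fits = []
    for row in df.itertuples(index=False):
        scope = Scope(
            str(row.scope_kind),
            None if pd.isna(row.scope_day) else int(row.scope_day),
            None if pd.isna(row.scope_hour) else int(row.scope_hour),
        )
        fits.append(
            RegressionFit(
                str(row.participant_id),
                scope,
                float(row.b0_ms),
                float(row.b1),
                float(row.sem_ms),
                int(row.n),
                bool(row.valid),
                str(row.method),
            )
        )
    return fits


EPISODE_COLUMNS = [
    "participant_id",
    "method",
    "day",
    "onset_index",
    "onset_hour",
    "length_windows",
    "duration_min",
    "mean_deficit_ms",
]


def write_episodes(episodes: list[Episode], path, window_s: float = 30.0) -> None:
    rows = [
        {
            "participant_id": e.participant_id,
            "method": e.method,
            "day": e.day,
            "onset_index": e.onset_index,
            "onset_hour": e.onset_hour,
            "length_windows": e.length,
            "duration_min": e.duration_min(window_s),
            "mean_deficit_ms": e.mean_deficit_ms,
        }
        for e in episodes
    ]
    pd.DataFrame(rows, columns=EPISODE_COLUMNS).to_csv(path, index=False)


def read_episodes(path) -> list[Episode]:
    df = _read_csv(path, EPISODE_COLUMNS)
    return [
        Episode(
            str(r.participant_id),
            str(r.method),
            int(r.day),
            int(r.onset_index),
            int(r.length_windows),
            int(r.onset_hour),
            float(r.mean_deficit_ms),
        )
        for r in df.itertuples(index=False)
    ]


REPORT_COLUMNS = ["participant_id", "day", "hour", "stressed", "worried", "reported_minutes"]


def write_reports(reports: list[SelfReport], path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "day": r.day,
            "hour": r.hour,
            "stressed": r.stressed,
            "worried": r.worried,
            "reported_minutes": r.reported_minutes,
        }
        for r in reports
    ]
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False)


def read_reports(path) -> list[SelfReport]:
    df = _read_csv(path, REPORT_COLUMNS)
    out = []
    for i, r in enumerate(df.itertuples(index=False)):
        if not (0 <= int(r.hour) <= 23):
            raise ValueError(f"{path}: row {i}, column hour: {r.hour} outside 0-23")
        out.append(
            SelfReport(
                str(r.participant_id),
                int(r.day),
                int(r.hour),
                bool(r.stressed),
                bool(r.worried),
                None if pd.isna(r.reported_minutes) else float(r.reported_minutes),
            )
        )
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
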