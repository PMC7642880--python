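"""Run detection: episodes of reduced additional HRV.

A window is *deficient* when observed RMSSD sits at or below the
movement-predicted RMSSD minus ``k_sem`` standard errors of the mean
(inclusive, so a deficit of exactly k_sem * SEM counts). A maximal run of
consecutive deficient windows lasting at least ``min_episode_min`` minutes
(7.5 min = 15 windows at 30 s) is an episode. Missing windows and failures
under a new governing fit break runs; runs may cross hour and day
boundaries and are attributed to the day/hour of their onset. Reporting
rules then drop episodes whose onset falls in sleep and keep only the first
episode per (day, hour).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modeling import MethodConfig, ModelForm, RegressionFit
from .preprocessing import SampleGrid


@dataclass
class Episode:
    """One detected run of movement-unexplained RMSSD reduction."""

    participant_id: str
    method: str
    day: int
    onset_index: int
    length: int
    onset_hour: int
    mean_deficit_ms: float

    @property
    def end_index(self) -> int:
        """One past the last window of the run."""
        return self.onset_index + self.length

    def duration_min(self, window_s: float = 30.0) -> float:
        return self.length * window_s / 60.0

    def overlaps(self, onset_index: int, length: int) -> bool:
        return self.onset_index < onset_index + length and onset_index < self.end_index


def predict_expected(
    fit: RegressionFit,
    acc_g,
    model_form: ModelForm = ModelForm.LINEAR,
    reciprocal_eps: float = 0.01,
):
    """Movement-expected RMSSD under a fitted model.

    Linear form: b0 + b1 * acc. The reciprocal sensitivity form replaces the
    regressor by 1/(acc + eps).
    """
    if not fit.valid:
        raise ValueError("cannot predict from an invalid fit")
    acc = np.asarray(acc_g, dtype=float)
    if model_form == ModelForm.RECIPROCAL:
        out = fit.b0_ms + fit.b1 / (acc + reciprocal_eps)
    else:
        out = fit.b0_ms + fit.b1 * acc
    return float(out) if np.isscalar(acc_g) else out


def governing_fit_indices(grid: SampleGrid, fits: list[RegressionFit]) -> np.ndarray:
    """For each grid row, the position of the fit whose scope governs it, or -1.

    Every window must be governed by at most one fit; overlapping scopes are
    an error.
    """
    day = grid.frame["day"].to_numpy()
    hour = grid.frame["hour"].to_numpy()
    out = np.full(len(grid), -1, dtype=int)
    for k, fit in enumerate(fits):
        mask = np.fromiter(
            (fit.scope.governs(int(d), int(h)) for d, h in zip(day, hour)),
            dtype=bool,
            count=len(grid),
        )
        if np.any(out[mask] != -1):
            raise ValueError("overlapping fit scopes: a window maps to two fits")
        out[mask] = k
    return out


def deficiency_mask(
    grid: SampleGrid, fits: list[RegressionFit], cfg: MethodConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(deficient, deficit_ms) per window; deficit is expected - actual."""
    f = grid.frame
    rmssd = f["rmssd_ms"].to_numpy()
    acc = f["acc_g"].to_numpy()
    gov = governing_fit_indices(grid, fits)
    deficient = np.zeros(len(f), dtype=bool)
    deficit = np.full(len(f), np.nan)
    for k, fit in enumerate(fits):
        if not fit.valid:
            continue
        rows = (gov == k) & ~np.isnan(rmssd) & ~np.isnan(acc)
        if not rows.any():
            continue
        expected = predict_expected(fit, acc[rows], cfg.model_form, cfg.reciprocal_eps)
        d = expected - rmssd[rows]
        deficit[rows] = d
        deficient[rows] = d >= cfg.k_sem * fit.sem_ms
    return deficient, deficit


def detect_runs(
    grid: SampleGrid, fits: list[RegressionFit], cfg: MethodConfig
) -> list[Episode]:
    """Raw episodes: maximal runs of >= min_episode_windows deficient windows."""
    f = grid.frame
    deficient, deficit = deficiency_mask(grid, fits, cfg)
    index = f["index"].to_numpy()
    day = f["day"].to_numpy()
    hour = f["hour"].to_numpy()
    min_len = cfg.min_episode_windows

    episodes: list[Episode] = []
    n = len(f)
    i = 0
    while i < n:
        if not deficient[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and deficient[j + 1]:
            j += 1
        length = j - i + 1
        if length >= min_len:
            episodes.append(
                Episode(
                    participant_id=grid.participant_id,
                    method=cfg.method,
                    day=int(day[i]),
                    onset_index=int(index[i]),
                    length=length,
                    onset_hour=int(hour[i]),
                    mean_deficit_ms=float(np.mean(deficit[i : j + 1])),
                )
            )
        i = j + 1
    return episodes


def filter_episodes(raw: list[Episode], grid: SampleGrid) -> list[Episode]:
    """Reporting rules: drop sleep-onset episodes, keep first per (day, hour)."""
    asleep = dict(
        zip(grid.frame["index"].to_numpy().tolist(), grid.frame["asleep"].to_numpy().tolist())
    )
    awake = [e for e in raw if not asleep.get(e.onset_index, False)]
    kept: dict[tuple[int, int], Episode] = {}
    for e in sorted(awake, key=lambda e: e.onset_index):
        kept.setdefault((e.day, e.onset_hour), e)
    return sorted(kept.values(), key=lambda e: e.onset_index)


def detect_episodes(
    grid: SampleGrid, fits: list[RegressionFit], cfg: MethodConfig
) -> list[Episode]:
    """Full detection: raw runs then the sleep and first-per-hour filters."""
    return filter_episodes(detect_runs(grid, fits, cfg), grid)
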