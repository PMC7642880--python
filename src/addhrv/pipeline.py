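"""End-to-end orchestration: fit -> detect -> evaluate over a cohort.

This is the library-level entry the CLI, the examples and the acceptance
machinery all share: given per-participant grids (plus calibration segments
and self-reports where available), run any subset of the seven methods and
collect fits, episodes and the three comparison analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .detection import Episode, detect_runs, filter_episodes
from .evaluation import (
    MatchSummary,
    SelfReport,
    count_episodes,
    day_correlations,
    match_episodes,
    summarize_counts,
    summarize_matches,
)
from .modeling import METHODS, CalibrationSegment, MethodConfig, RegressionFit, fit_method
from .preprocessing import SampleGrid

log = logging.getLogger("addhrv")


@dataclass
class CohortInputs:
    grids: dict[str, SampleGrid]
    calibration: dict[str, list[CalibrationSegment]] = field(default_factory=dict)
    reports: list[SelfReport] = field(default_factory=list)


@dataclass
class MethodResult:
    method: str
    fits: list[RegressionFit]
    raw_episodes: list[Episode]
    episodes: list[Episode]  # sleep-filtered, first-per-hour
    count_table: pd.DataFrame
    count_summary: pd.DataFrame
    correlations: pd.DataFrame
    matches: MatchSummary | None


def analyze_method(
    inputs: CohortInputs,
    cfg: MethodConfig,
    match_window_hours: int = 1,
    match_denominator: str = "cohort",
) -> MethodResult:
    """Run one method over every participant and evaluate it."""
    participants = sorted(inputs.grids)
    fits: list[RegressionFit] = []
    raw: list[Episode] = []
    kept: list[Episode] = []
    for pid in participants:
        grid = inputs.grids[pid]
        calib = inputs.calibration.get(pid)
        if cfg.method in ("calibration", "calibration_extended") and not calib:
            raise ValueError(f"method {cfg.method!r} requires calibration segments for {pid}")
        pfits = fit_method(grid, cfg, calib)
        n_valid = sum(f.valid for f in pfits)
        if n_valid == 0:
            log.warning("%s/%s: no valid fits (e.g. single-day grid with nextday)", pid, cfg.method)
        praw = detect_runs(grid, pfits, cfg)
        pkept = filter_episodes(praw, grid)
        log.info(
            "%s/%s: %d fits (%d valid), %d raw runs, %d episodes kept",
            pid, cfg.method, len(pfits), n_valid, len(praw), len(pkept),
        )
        fits.extend(pfits)
        raw.extend(praw)
        kept.extend(pkept)

    days = sorted({int(d) for g in inputs.grids.values() for d in g.frame["day"].unique()})
    table = count_episodes(kept, participants, days, methods=[cfg.method])
    summary = summarize_counts(table)
    corr = day_correlations(table)
    matches = None
    if inputs.reports:
        per_part = match_episodes(
            kept, inputs.reports, participants, match_window_hours=match_window_hours
        )
        matches = summarize_matches(per_part, cfg.method, denominator=match_denominator)
    return MethodResult(cfg.method, fits, raw, kept, table, summary, corr, matches)


def analyze_cohort(
    inputs: CohortInputs,
    methods: list[str] | None = None,
    base_cfg: MethodConfig | None = None,
    match_window_hours: int = 1,
    match_denominator: str = "cohort",
) -> dict[str, MethodResult]:
    """Run several methods; methods needing absent calibration data are
    skipped with a warning (mirrors reanalyses of studies without a lab
    calibration phase)."""
    if methods is None:
        methods = list(METHODS)
    base = base_cfg or MethodConfig()
    out: dict[str, MethodResult] = {}
    for method in methods:
        cfg = replace(base, method=method)
        if method in ("calibration", "calibration_extended") and not inputs.calibration:
            log.warning("skipping %s: no calibration segments supplied", method)
            continue
        out[method] = analyze_method(inputs, cfg, match_window_hours, match_denominator)
    return out


def comparison_table(results: dict[str, MethodResult]) -> pd.DataFrame:
    """Per-method one-row summary: mean episodes/day and the two match rows."""
    rows = []
    for method, res in results.items():
        mean_per_day = res.count_summary["mean"].mean() if len(res.count_summary) else 0.0
        row = {"method": method, "mean_episodes_per_day": float(mean_per_day)}
        if res.matches is not None:
            row["pct_participants_with_match"] = res.matches.pct_participants_with_match
            row["mean_match_pct"] = (
                res.matches.mean_within_participant_match_pct if res.matches.mean_defined else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
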