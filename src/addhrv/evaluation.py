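"""Method comparison: episode-count tables, between-day temporal-reliability
correlations, and match statistics against hourly self-reported stress/worry.

An episode *matches* a self-report when a report exists for the clock hour of
the episode's onset (same day) with stressed or worried true; stress and
worry are pooled with OR throughout. The two cohort-level summary rows are
the percentage of participants with at least one match (denominator:
everyone in the cohort by default) and the mean within-participant match
percentage over participants that have at least one match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detection import Episode


@dataclass(frozen=True)
class SelfReport:
    """One hourly prompt's answer, covering the clock hour ``hour`` of ``day``."""

    participant_id: str
    day: int
    hour: int
    stressed: bool
    worried: bool
    reported_minutes: float | None = None


@dataclass
class MatchSummary:
    method: str
    pct_participants_with_match: float
    mean_within_participant_match_pct: float
    mean_defined: bool
    detail: pd.DataFrame

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_participants_with_match <= 100.0:
            raise ValueError("percentage outside [0, 100]")
        if self.mean_defined and not (
            0.0 <= self.mean_within_participant_match_pct <= 100.0
        ):
            raise ValueError("percentage outside [0, 100]")


def count_episodes(
    episodes: list[Episode],
    participants: list[str],
    days: list[int],
    methods: list[str] | None = None,
) -> pd.DataFrame:
    """Episode counts per participant x method x day, zero-filled.

    ``participants`` and ``days`` define the full crossing so that
    participants (or days) without episodes appear with count 0. Also usable
    for the per-(method, day) mean/SD summary via :func:`summarize_counts`.
    """
    if methods is None:
        methods = sorted({e.method for e in episodes}) or ["full"]
    rows = pd.DataFrame(
        [(e.participant_id, e.method, e.day) for e in episodes],
        columns=["participant_id", "method", "day"],
    )
    full = pd.MultiIndex.from_product(
        [participants, methods, days], names=["participant_id", "method", "day"]
    )
    counts = (
        rows.groupby(["participant_id", "method", "day"]).size()
        if len(rows)
        else pd.Series(dtype=int)
    )
    counts = counts.reindex(full, fill_value=0).astype(int)
    return counts.rename("count").reset_index()


def summarize_counts(count_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of episode counts over participants, per (method, day)."""
    return (
        count_table.groupby(["method", "day"])["count"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size")
        .reset_index()
    )


def day_correlations(count_table: pd.DataFrame, conf_level: float = 0.95) -> pd.DataFrame:
    """Pearson r between day-pair episode counts, per method, with Fisher-z CI.

    Each row pairs the per-participant counts of two days. Pairs with fewer
    than three participants or a constant day are flagged undefined
    (r = NaN) rather than raising.
    """
    z_crit = stats.norm.ppf(0.5 + conf_level / 2.0)
    out = []
    for method, sub in count_table.groupby("method"):
        wide = sub.pivot(index="participant_id", columns="day", values="count")
        days = sorted(wide.columns)
        for i, d1 in enumerate(days):
            for d2 in days[i + 1 :]:
                pair = wide[[d1, d2]].dropna()
                x, y = pair[d1].to_numpy(float), pair[d2].to_numpy(float)
                n = len(pair)
                defined = n >= 3 and np.std(x) > 0 and np.std(y) > 0
                if defined:
                    r = float(stats.pearsonr(x, y).statistic)
                    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
                    half = z_crit / np.sqrt(n - 3) if n > 3 else np.inf
                    lo, hi = np.tanh(z - half), np.tanh(z + half)
                else:
                    r, lo, hi = np.nan, np.nan, np.nan
                out.append(
                    {
                        "method": method,
                        "day_a": d1,
                        "day_b": d2,
                        "r": r,
                        "ci_low": float(lo) if defined else np.nan,
                        "ci_high": float(hi) if defined else np.nan,
                        "n": n,
                        "defined": defined,
                    }
                )
    return pd.DataFrame(
        out, columns=["method", "day_a", "day_b", "r", "ci_low", "ci_high", "n", "defined"]
    )


def _dedupe(reports: list[SelfReport]) -> dict[tuple[str, int, int], SelfReport]:
    """At most one report per (participant, day, hour); flags pooled with OR."""
    merged: dict[tuple[str, int, int], SelfReport] = {}
    for r in reports:
        key = (r.participant_id, r.day, r.hour)
        if key in merged:
            old = merged[key]
            merged[key] = SelfReport(
                r.participant_id,
                r.day,
                r.hour,
                old.stressed or r.stressed,
                old.worried or r.worried,
                old.reported_minutes if old.reported_minutes is not None else r.reported_minutes,
            )
        else:
            merged[key] = r
    return merged


def match_episodes(
    episodes: list[Episode],
    reports: list[SelfReport],
    participants: list[str] | None = None,
    match_window_hours: int = 1,
) -> pd.DataFrame:
    """Per-participant match statistics between episodes and self-reports.

    An episode is matched iff some report with stressed or worried true
    covers an hour in [onset_hour, onset_hour + match_window_hours) of the
    same day; the default window of 1 means the exact onset hour. The detail
    table also carries the reverse statistic (fraction of positive report
    hours matched by at least one episode).
    """
    if match_window_hours < 1:
        raise ValueError("match_window_hours must be >= 1")
    merged = _dedupe(reports)
    positive = {
        key for key, r in merged.items() if r.stressed or r.worried
    }
    if participants is None:
        participants = sorted(
            {e.participant_id for e in episodes} | {k[0] for k in positive}
        )

    rows = []
    for pid in participants:
        eps = [e for e in episodes if e.participant_id == pid]
        pos = {(d, h) for (p, d, h) in positive if p == pid}
        matched_eps = 0
        hit_reports: set[tuple[int, int]] = set()
        for e in eps:
            hours = {(e.day, e.onset_hour + k) for k in range(match_window_hours)}
            hit = hours & pos
            if hit:
                matched_eps += 1
                hit_reports |= hit
        n_eps = len(eps)
        rows.append(
            {
                "participant_id": pid,
                "n_episodes": n_eps,
                "n_matched": matched_eps,
                "match_pct": 100.0 * matched_eps / n_eps if n_eps else np.nan,
                "n_reports": len(pos),
                "n_reports_matched": len(hit_reports),
                "report_match_pct": 100.0 * len(hit_reports) / len(pos) if pos else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_matches(
    per_participant: pd.DataFrame,
    method: str = "",
    denominator: str = "cohort",
) -> MatchSummary:
    """Cohort summary of the per-participant match table.

    ``denominator`` controls the first row's base: "cohort" (default, all
    participants) or "detected" (only participants with >= 1 detected
    episode). Participants without any match are excluded from the second
    row's mean; if nobody has a match the mean is reported as 0 and flagged
    undefined.
    """
    if len(per_participant) == 0:
        raise ValueError("need at least one participant")
    if denominator not in ("cohort", "detected"):
        raise ValueError("denominator must be 'cohort' or 'detected'")
    has_match = per_participant["n_matched"] > 0
    if denominator == "cohort":
        base = len(per_participant)
    else:
        base = int((per_participant["n_episodes"] > 0).sum())
    pct_with = 100.0 * has_match.sum() / base if base else 0.0
    matched = per_participant.loc[has_match, "match_pct"]
    defined = len(matched) > 0
    mean_pct = float(matched.mean()) if defined else 0.0
    return MatchSummary(method, float(pct_with), mean_pct, defined, per_participant)
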