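"""Synthetic ambulatory cohorts with ground truth.

Each simulated participant carries the statistical structure the detection
pipeline assumes: movement from a Markov chain over four activity states
(rest/walk/cycle/stairs), RMSSD generated from a participant-specific line
b0 + b1*acc plus a circadian term and Gaussian noise, a nightly sleep block
(rest state, elevated baseline), a scripted 7-activity lab-calibration
session on the first waking morning, injected movement-independent RMSSD
dips ("stress episodes") with known onsets, and hourly self-reports that
cover injected episodes only with probability ``report_prob`` -- deliberate
underreporting -- plus a trickle of spurious reports.

Episode depth is parameterized in multiples of the day's realized waking
RMSSD standard deviation, so detectability is controlled relative to the
data's own spread regardless of the noise setting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modeling import CALIBRATION_ACTIVITIES, CalibrationSegment
from .preprocessing import RRSeries, SampleGrid, _empty_grid_frame
from .evaluation import SelfReport

#: mean movement magnitude (g) per activity state
ACTIVITY_STATES = {"rest": 0.02, "walk": 0.25, "cycle": 0.45, "stairs": 0.8}

#: mean dwell time (minutes) before leaving a state
DWELL_MIN = {"rest": 8.0, "walk": 4.0, "cycle": 4.0, "stairs": 1.0}

#: relative probability of entering each state when leaving another
ENTRY_WEIGHTS = {"rest": 0.55, "walk": 0.30, "cycle": 0.10, "stairs": 0.05}

#: movement magnitude (g) during each scripted calibration activity
CALIBRATION_ACC = {
    "sit_video": 0.03,
    "stand_count": 0.05,
    "lie_count": 0.02,
    "cycle": 0.45,
    "clench_tense": 0.04,
    "read_aloud": 0.05,
    "stairs": 0.8,
}

#: calibration activities that perturb RMSSD without movement
STRESSFUL_CALIBRATION = ("clench_tense", "read_aloud")


@dataclass(frozen=True)
class SimParams:
    """Generator configuration; defaults emulate a 6-participant, three
    24-h-session ambulatory study with hourly prompts."""

    n_participants: int = 6
    days: int = 3
    window_s: float = 30.0
    b0_range: tuple[float, float] = (40.0, 70.0)
    b1_range: tuple[float, float] = (-30.0, -10.0)
    noise_sd: float = 3.0
    acc_jitter_sd: float = 0.015
    circadian_amp: float = 5.0
    circadian_trough_hour: float = 3.5
    sleep_hours: tuple[float, float] = (0.0, 7.0)
    sleep_b0_bonus: float = 10.0
    episode_rate: float = 8.0
    episode_depth_sd: float = 3.0
    episode_dur_min: tuple[float, float] = (8.0, 25.0)
    detectable_only: bool = False
    report_prob: float = 0.3
    spurious_report_rate: float = 0.5
    calibration_min: float = 3.0
    calibration_stress_mult: float = 0.8
    missing_days: tuple[tuple[int, int], ...] = ()
    emit_beats: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("b0_range", "b1_range", "episode_dur_min", "sleep_hours"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be well-ordered, got ({lo}, {hi})")
        for name in ("report_prob",):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_participants < 1 or self.days < 1:
            raise ValueError("need at least one participant and one day")
        if self.noise_sd < 0 or self.episode_rate < 0 or self.spurious_report_rate < 0:
            raise ValueError("rates and noise must be non-negative")

    @property
    def windows_per_day(self) -> int:
        return int(round(86400.0 / self.window_s))


@dataclass(frozen=True)
class InjectedEpisode:
    day: int
    onset_index: int
    length: int
    depth_ms: float
    reported: bool

    @property
    def end_index(self) -> int:
        return self.onset_index + self.length


@dataclass
class GroundTruth:
    """What the generator injected, for recall/matching checks."""

    b0_ms: float
    b1: float
    episodes: list[InjectedEpisode]
    reports: list[SelfReport]


@dataclass
class ParticipantRecord:
    participant_id: str
    grid: SampleGrid
    reports: list[SelfReport]
    calibration: list[CalibrationSegment]
    truth: GroundTruth
    rr: RRSeries | None = None


def _simulate_activity(
    rng: np.random.Generator, n_win: int, asleep: np.ndarray, window_s: float
) -> np.ndarray:
    """Markov-chain activity magnitudes; sleep forces the rest state."""
    names = list(ACTIVITY_STATES)
    acc_level = np.array([ACTIVITY_STATES[s] for s in names])
    stay = np.array([1.0 - window_s / (DWELL_MIN[s] * 60.0) for s in names]).clip(0.0, 1.0)
    weights = np.array([ENTRY_WEIGHTS[s] for s in names])

    state = 0  # wake up at rest
    states = np.empty(n_win, dtype=int)
    stay_draw = rng.random(n_win)
    for i in range(n_win):
        if asleep[i]:
            state = 0
        elif stay_draw[i] >= stay[state]:
            w = weights.copy()
            w[state] = 0.0
            state = rng.choice(len(names), p=w / w.sum())
        states[i] = state
    return acc_level[states]


def _choose_flags(rng: np.random.Generator) -> tuple[bool, bool]:
    """Stressed/worried flags with at least one true."""
    stressed = rng.random() < 0.7
    worried = rng.random() < 0.5
    if not (stressed or worried):
        stressed = True
    return stressed, worried


def simulate_participant(
    params: SimParams,
    participant_seed: int | np.random.SeedSequence,
    participant_id: str = "P01",
    participant_no: int = 0,
) -> ParticipantRecord:
    """One participant's grid, self-reports, calibration segments and truth."""
    rng = np.random.default_rng(participant_seed)
    w = params.window_s
    wpd = params.windows_per_day
    n_win = params.days * wpd
    frame = _empty_grid_frame(n_win, w)
    index = frame["index"].to_numpy()
    day = frame["day"].to_numpy()
    hour_f = (index * w / 3600.0) % 24  # fractional clock hour

    lo, hi = params.sleep_hours
    asleep = (hour_f >= lo) & (hour_f < hi)
    frame["asleep"] = asleep

    b0 = rng.uniform(*params.b0_range)
    b1 = rng.uniform(*params.b1_range)

    acc = _simulate_activity(rng, n_win, asleep, w)
    acc = np.clip(acc + rng.normal(0.0, params.acc_jitter_sd, n_win), 0.0, None)

    # scripted calibration on day 1, starting at the first waking hour
    calib_start = params.sleep_hours[1] * 3600.0
    seg_s = params.calibration_min * 60.0
    calibration = []
    t = calib_start
    for activity in CALIBRATION_ACTIVITIES:
        calibration.append(CalibrationSegment(participant_id, activity, t, t + seg_s))
        t += seg_s
    calib_mult = np.ones(n_win)
    mid = (index + 0.5) * w
    for seg in calibration:
        rows = (mid >= seg.start_s) & (mid < seg.end_s)
        acc[rows] = np.clip(
            CALIBRATION_ACC[seg.activity] + rng.normal(0.0, params.acc_jitter_sd, rows.sum()),
            0.0,
            None,
        )
        if seg.activity in STRESSFUL_CALIBRATION:
            calib_mult[rows] = params.calibration_stress_mult
    in_calib = mid < t

    circadian = -params.circadian_amp * np.cos(
        2 * np.pi * (hour_f - params.circadian_trough_hour) / 24.0
    )
    clean = (b0 + b1 * acc + circadian + params.sleep_b0_bonus * asleep) * calib_mult
    rmssd = clean + rng.normal(0.0, params.noise_sd, n_win)

    episodes, reports = _inject_episodes(
        rng, params, rmssd, day, hour_f, asleep, in_calib, participant_id
    )
    for ep in episodes:
        rmssd[ep.onset_index : ep.end_index] -= ep.depth_ms
    rmssd = np.maximum(rmssd, 1.0)

    reports = reports + _spurious_reports(rng, params, participant_id, asleep, day, hour_f)

    frame["rmssd_ms"] = rmssd
    frame["acc_g"] = acc
    for pno, d in params.missing_days:
        if pno == participant_no:
            rows = day == d
            frame.loc[rows, "rmssd_ms"] = np.nan
            frame.loc[rows, "acc_g"] = np.nan

    grid = SampleGrid(participant_id, w, frame)
    truth = GroundTruth(b0, b1, episodes, [r for r in reports])
    rr = _emit_beats(rng, participant_id, rmssd, w) if params.emit_beats else None
    return ParticipantRecord(participant_id, grid, reports, calibration, truth, rr)


def _inject_episodes(rng, params, rmssd, day, hour_f, asleep, in_calib, pid):
    """Movement-independent dips in waking windows, with partial self-reports."""
    w = params.window_s
    dur_lo, dur_hi = params.episode_dur_min
    if params.detectable_only:
        dur_lo = max(dur_lo, 7.5)
    blocked = asleep | in_calib
    episodes: list[InjectedEpisode] = []
    reports: list[SelfReport] = []
    occupied = np.zeros(len(rmssd), dtype=bool)
    for d in np.unique(day):
        rows = day == d
        waking = rows & ~asleep
        if not waking.any():
            continue
        sd_day = float(np.std(rmssd[waking], ddof=1))
        n_ep = rng.poisson(params.episode_rate)
        candidates = np.nonzero(rows & ~blocked)[0]
        for _ in range(n_ep):
            dur = rng.uniform(dur_lo, max(dur_lo, dur_hi))
            length = max(1, int(round(dur * 60.0 / w)))
            for _try in range(50):
                onset = int(rng.choice(candidates))
                span = slice(onset, onset + length)
                if (
                    onset + length <= len(rmssd)
                    and not blocked[span].any()
                    and not occupied[span].any()
                    and (day[span] == d).all()
                ):
                    break
            else:
                continue
            occupied[span] = True
            depth = params.episode_depth_sd * sd_day
            reported = bool(rng.random() < params.report_prob)
            episodes.append(InjectedEpisode(int(d), onset, length, depth, reported))
            if reported:
                stressed, worried = _choose_flags(rng)
                reports.append(
                    SelfReport(
                        pid, int(d), int(hour_f[onset]), stressed, worried, length * w / 60.0
                    )
                )
    episodes.sort(key=lambda e: e.onset_index)
    return episodes, reports


def _spurious_reports(rng, params, pid, asleep, day, hour_f):
    """Stress/worry reports not tied to any injected episode."""
    out: list[SelfReport] = []
    for d in np.unique(day):
        waking_hours = np.unique(hour_f[(day == d) & ~asleep].astype(int))
        if waking_hours.size == 0:
            continue
        for _ in range(rng.poisson(params.spurious_report_rate)):
            stressed, worried = _choose_flags(rng)
            out.append(
                SelfReport(
                    pid,
                    int(d),
                    int(rng.choice(waking_hours)),
                    stressed,
                    worried,
                    float(rng.uniform(5.0, 30.0)),
                )
            )
    return out


def _emit_beats(
    rng: np.random.Generator, pid: str, rmssd: np.ndarray, window_s: float, phi: float = 0.3
) -> RRSeries:
    """RR intervals whose windowed RMSSD tracks the grid, via an AR(1)
    interbeat process with innovation SD matched to the target RMSSD."""
    mean_rr = 800.0
    times, rrs = [], []
    t = 0.0
    dev = 0.0
    n_win = len(rmssd)
    end = n_win * window_s
    while t < end:
        k = min(int(t // window_s), n_win - 1)
        target = rmssd[k] if np.isfinite(rmssd[k]) else 0.0
        sigma = target * np.sqrt((1.0 + phi) / 2.0)
        dev = phi * dev + rng.normal(0.0, sigma) if sigma > 0 else 0.0
        rr = float(np.clip(mean_rr + dev, 300.0, 2000.0))
        t += rr / 1000.0
        times.append(t)
        rrs.append(rr)
    return RRSeries(pid, np.array(times), np.array(rrs))


def simulate_cohort(params: SimParams) -> list[ParticipantRecord]:
    """Independent participants from per-participant seeds derived from the
    master seed."""
    children = np.random.SeedSequence(params.seed).spawn(params.n_participants)
    return [
        simulate_participant(params, child, f"P{i + 1:02d}", i)
        for i, child in enumerate(children)
    ]
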