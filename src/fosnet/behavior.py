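"""Operant-schedule mathematics and per-session behavioral metrics.

Implements the fixed-ratio (FR) and exponential progressive-ratio (PR)
response-ratio schedules used in touchscreen operant chambers, replay of a
session event log into summary metrics (break point, accuracy, latencies,
20-minute touch counts), the stage-advance and stabilization criteria, and
the two group-comparison statistics used on behavioral endpoints: a
pooled-variance two-sample t test and the log-rank test on session-duration
survival curves.

The PR requirement for trial ``m`` is ``round(scale * exp(rate * m) - offset)``
with round-half-away-from-zero; with the defaults (scale = offset = 5,
rate = 0.2) the first eight requirements are 1, 2, 4, 6, 9, 12, 15, 20.
The break point is the requirement of the last reward the subject collected.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "EVENT_KINDS",
    "Event",
    "RatioSchedule",
    "SessionLog",
    "SessionMetrics",
    "SessionValidationError",
    "response_ratio",
    "compute_break_point",
    "session_end_time",
    "compute_metrics",
    "fr_criterion_reached",
    "pr_stable",
    "compare_survival",
    "compare_groups",
    "metrics_frame",
]

EVENT_KINDS = frozenset(
    {"trial_start", "correct_touch", "incorrect_touch", "reward_collected"}
)
TOUCH_KINDS = frozenset({"correct_touch", "incorrect_touch"})

#: Half-open analysis window for early-session touch counts, seconds.
FIRST_WINDOW_S = 1200.0


class SessionValidationError(ValueError):
    """Raised when a session log violates event-ordering invariants."""


@dataclass(frozen=True)
class Event:
    """A single timestamped chamber event (seconds from session start)."""

    time: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SessionValidationError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise SessionValidationError(f"negative event time {self.time}")


@dataclass(frozen=True)
class RatioSchedule:
    """Response-ratio schedule: touches required per reward.

    ``fixed`` schedules require ``fixed_n`` correct touches on every trial.
    ``progressive`` schedules require ``round(scale * e**(rate*m) - offset)``
    touches on trial ``m`` (rounded half away from zero, floored at 1), so the
    requirement grows roughly exponentially with each reward earned.
    """

    kind: str = "progressive"
    fixed_n: int = 1
    rate: float = 0.2
    scale: float = 5.0
    offset: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "progressive"):
            raise ValueError(f"schedule kind must be fixed|progressive, got {self.kind!r}")
        if self.kind == "fixed" and self.fixed_n < 1:
            raise ValueError("fixed_n must be a positive integer")

    @classmethod
    def progressive(cls) -> "RatioSchedule":
        return cls(kind="progressive")

    @classmethod
    def fixed(cls, n: int) -> "RatioSchedule":
        return cls(kind="fixed", fixed_n=n)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def response_ratio(schedule: RatioSchedule, m: int) -> int:
    """Touches required to earn the reward of trial ``m`` (1-based).

    For progressive schedules the full expression ``scale*e**(rate*m) - offset``
    is rounded half away from zero; flooring instead would give 8 rather than
    the canonical 9 at m = 5. Results below 1 are clamped to 1 so the first
    trial is always attainable.
    """
    if m < 1 or m != int(m):
        raise ValueError(f"trial index m must be a positive integer, got {m}")
    if schedule.kind == "fixed":
        return schedule.fixed_n
    value = schedule.scale * math.exp(schedule.rate * m) - schedule.offset
    return max(1, _round_half_away(value))


@dataclass
class SessionLog:
    """Ordered event stream of one operant session.

    A session ends at the first
    ``quit_window``-long period with no panel touch, or at ``max_duration``,
    whichever comes first (both in seconds).
    """

    events: list[Event] = field(default_factory=list)
    schedule: RatioSchedule = field(default_factory=RatioSchedule.progressive)
    max_duration: float = 3600.0
    quit_window: float = 300.0

    def validate(self) -> None:
        """Check ordering and per-trial reward bookkeeping.

        Every ``reward_collected`` must be preceded, within its trial, by at
        least the schedule-required number of correct touches.
        """
        prev_t = 0.0
        trial = 0
        correct_in_trial = 0
        for ev in self.events:
            if ev.time < prev_t:
                raise SessionValidationError(
                    f"event times not non-decreasing at t={ev.time}"
                )
            prev_t = ev.time
            if ev.kind == "trial_start":
                trial += 1
                correct_in_trial = 0
            elif ev.kind == "correct_touch":
                correct_in_trial += 1
            elif ev.kind == "reward_collected":
                if trial == 0:
                    raise SessionValidationError("reward_collected before any trial_start")
                need = response_ratio(self.schedule, trial)
                if correct_in_trial < need:
                    raise SessionValidationError(
                        f"trial {trial}: reward collected after {correct_in_trial} "
                        f"correct touches, schedule requires {need}"
                    )
                correct_in_trial = 0

    # -- CSV contract: columns time_s,event; one file per session ----------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["time_s", "event"])
            for ev in self.events:
                writer.writerow([f"{ev.time:.3f}", ev.kind])

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        schedule: RatioSchedule | None = None,
        max_duration: float = 3600.0,
        quit_window: float = 300.0,
    ) -> "SessionLog":
        events: list[Event] = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"time_s", "event"} <= set(reader.fieldnames):
                raise SessionValidationError(
                    f"{path}: session CSV must have columns time_s,event"
                )
            for i, row in enumerate(reader):
                kind = row["event"].strip()
                if kind not in EVENT_KINDS:
                    raise SessionValidationError(
                        f"{path} row {i + 2}: unknown event kind {kind!r}"
                    )
                events.append(Event(float(row["time_s"]), kind))
        return cls(
            events=events,
            schedule=schedule or RatioSchedule.progressive(),
            max_duration=max_duration,
            quit_window=quit_window,
        )


@dataclass
class SessionMetrics:
    """Summary endpoints of one session.

    ``accuracy`` and ``first_touch_latency_mean`` are NaN when undefined
    (no touches / no touched trials).
    """

    break_point: int
    n_rewards: int
    duration: float
    accuracy: float
    first_touch_latency_mean: float
    correct_first20: int
    incorrect_first20: int
    no_reward: bool = False


def compute_break_point(log: SessionLog) -> int:
    """Response requirement of the last collected reward; 0 if none.

    Sessions with zero rewards get break point 0 by convention so that group
    statistics stay computable; ``compute_metrics`` flags them.
    """
    log.validate()
    n_rewards = sum(1 for ev in log.events if ev.kind == "reward_collected")
    if n_rewards == 0:
        return 0
    return response_ratio(log.schedule, n_rewards)


def session_end_time(log: SessionLog) -> float:
    """Session end: first quiet period of ``quit_window`` seconds, capped.

    Scans inter-touch gaps from t = 0; the first gap longer than the quit
    window ends the session ``quit_window`` seconds after the preceding touch
    (or at ``quit_window`` if the subject never touched). Otherwise the
    session runs to ``max_duration``.
    """
    touches = [ev.time for ev in log.events if ev.kind in TOUCH_KINDS]
    prev = 0.0
    for t in touches:
        if t - prev > log.quit_window:
            return min(prev + log.quit_window, log.max_duration)
        prev = t
    # no touch after the last one: session times out quit_window later
    return min(prev + log.quit_window, log.max_duration)


def compute_metrics(log: SessionLog) -> SessionMetrics:
    """Replay a session log into its summary metrics.

    Accuracy is correct touches over all panel touches. First-touch latency is
    measured per trial from ``trial_start`` to the first touch of either panel
    and averaged over trials that have at least one touch. The early-session
    counts use the half-open window [0, 1200) s.
    """
    log.validate()
    n_correct = sum(1 for ev in log.events if ev.kind == "correct_touch")
    n_incorrect = sum(1 for ev in log.events if ev.kind == "incorrect_touch")
    n_touch = n_correct + n_incorrect

    latencies: list[float] = []
    trial_start_t: float | None = None
    for ev in log.events:
        if ev.kind == "trial_start":
            trial_start_t = ev.time
        elif ev.kind in TOUCH_KINDS and trial_start_t is not None:
            latencies.append(ev.time - trial_start_t)
            trial_start_t = None

    n_rewards = sum(1 for ev in log.events if ev.kind == "reward_collected")
    return SessionMetrics(
        break_point=compute_break_point(log),
        n_rewards=n_rewards,
        duration=session_end_time(log),
        accuracy=(n_correct / n_touch) if n_touch else float("nan"),
        first_touch_latency_mean=float(np.mean(latencies)) if latencies else float("nan"),
        correct_first20=sum(
            1
            for ev in log.events
            if ev.kind == "correct_touch" and ev.time < FIRST_WINDOW_S
        ),
        incorrect_first20=sum(
            1
            for ev in log.events
            if ev.kind == "incorrect_touch" and ev.time < FIRST_WINDOW_S
        ),
        no_reward=n_rewards == 0,
    )


def fr_criterion_reached(session_rewards: Sequence[int], stage: str) -> bool:
    """Stage-advance rule for fixed-ratio pre-training.

    FR1/FR2 advance on a single session with >= 50 reinforcements; FR3
    requires >= 50 on two consecutive (the last two) days.
    """
    if stage not in ("FR1", "FR2", "FR3"):
        raise ValueError(f"stage must be FR1|FR2|FR3, got {stage!r}")
    if not session_rewards:
        raise ValueError("session_rewards must be non-empty")
    if stage in ("FR1", "FR2"):
        return session_rewards[-1] >= 50
    if len(session_rewards) < 2:
        return False
    return session_rewards[-1] >= 50 and session_rewards[-2] >= 50


def pr_stable(rewards_by_day: Sequence[float]) -> tuple[bool, float | None]:
    """Progressive-ratio stabilization rule.

    Performance is stable when each of the last 3 daily reward counts is
    within 10% of their 3-day mean; returns (stable, 3-day mean or None).
    """
    if len(rewards_by_day) < 3:
        raise ValueError("need at least 3 days of PR sessions")
    window = np.asarray(rewards_by_day[-3:], dtype=float)
    mean = float(window.mean())
    if mean == 0:
        return bool(np.all(window == 0)), (0.0 if np.all(window == 0) else None)
    if np.all(np.abs(window - mean) <= 0.1 * mean):
        return True, mean
    return False, None


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float


def compare_survival(
    durations_a: Sequence[float],
    censored_a: Sequence[bool],
    durations_b: Sequence[float],
    censored_b: Sequence[bool],
) -> LogRankResult:
    """Two-group log-rank test on session durations (1 df).

    Sessions that reached the 60-min cap are right-censored; quit-terminated
    sessions are events. Raises if both groups are entirely censored, where
    the statistic is undefined.
    """
    if not len(durations_a) or not len(durations_b):
        raise ValueError("both groups must be non-empty")
    obs_a = ~np.asarray(censored_a, dtype=bool)
    obs_b = ~np.asarray(censored_b, dtype=bool)
    if not obs_a.any() and not obs_b.any():
        raise ValueError("log-rank statistic undefined: all sessions censored")
    res = logrank_test(
        np.asarray(durations_a, dtype=float),
        np.asarray(durations_b, dtype=float),
        event_observed_A=obs_a,
        event_observed_B=obs_b,
    )
    chi2 = float(res.test_statistic)
    if not np.isfinite(chi2):
        # identical all-event groups can yield 0/0 in some versions
        chi2, p = 0.0, 1.0
    else:
        p = float(res.p_value)
    return LogRankResult(chi_square=chi2, p_value=p)


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Independent two-tailed t test; pooled-variance Student's by default.

    Degenerate case: zero pooled variance with equal means is reported as
    t = 0, p = 1; zero variance with unequal means is an error (the statistic
    diverges).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def metrics_frame(
    records: Iterable[tuple[str, str, SessionMetrics]]
) -> pd.DataFrame:
    """Tidy one-row-per-session table: subject, group, then every metric."""
    rows = []
    for subject, group, m in records:
        rows.append(
            {
                "subject": subject,
                "group": group,
                "break_point": m.break_point,
                "n_rewards": m.n_rewards,
                "duration_s": m.duration,
                "accuracy": m.accuracy,
                "first_touch_latency_mean_s": m.first_touch_latency_mean,
                "correct_first20": m.correct_first20,
                "incorrect_first20": m.incorrect_first20,
                "no_reward": m.no_reward,
            }
        )
    return pd.DataFrame(rows)
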