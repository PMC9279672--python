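"""Synthetic c-Fos count tables and operant session logs.

Two generators make every downstream stage testable without animal data:

* ``generate_counts`` draws per-subject region count vectors from a latent
  multivariate normal with a user-specified correlation matrix, mapped to
  counts on a log-normal scale (mean-preserving) and rounded to non-negative
  integers. The latent correlation is the recoverable target: because the
  log-normal map is monotone and the dispersion modest, sample Pearson
  correlations of the counts converge to the latent matrix as subjects grow.

* ``generate_session`` replays a threshold-quitting agent through a ratio
  schedule: the agent works at a fixed touch cadence, misdirects each touch
  to the incorrect panel with a fixed probability, and stops touching
  entirely once the next required ratio exceeds its quitting threshold — so
  the session's break point is known by construction.

The default two-group preset mirrors a sparse-versus-dense connectivity
contrast: the wild-type-like group has near-independent regions with one
correlated orbitofrontal/pallidal module, while the knockout-like group has
uniformly elevated interregional correlation plus a dominant accumbens hub
region correlated with every other region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import Event, RatioSchedule, SessionLog, response_ratio
from .connectivity import AtlasMismatchError, CountTable

__all__ = [
    "DEFAULT_REGION_LABELS",
    "DEFAULT_ATLAS",
    "DEFAULT_REGION_MEANS",
    "RegionAtlas",
    "CountGenConfig",
    "AgentConfig",
    "generate_counts",
    "make_two_group_dataset",
    "wt_preset",
    "ko_preset",
    "generate_session",
]

#: The 20 reward-circuit regions in which c-Fos-positive cells are counted.
DEFAULT_REGION_LABELS: tuple[str, ...] = (
    "VO/LO", "MO", "NAca-m", "NAca-l", "NAcp-m", "NAcp-l", "NAcp-v", "VP",
    "MPOA", "dHip", "vHip", "BLAa", "BLAp", "LHa", "LHp", "VMH", "ARC",
    "VTA", "DR", "MR",
)


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered, unique region labels defining column order everywhere."""

    labels: tuple[str, ...] = DEFAULT_REGION_LABELS

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("atlas must have at least one region")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atlas labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)


DEFAULT_ATLAS = RegionAtlas()

#: Order-of-magnitude per-region mean counts (c-Fos+ cells per region image
#: average); config-overridable placeholders, not measured values.
DEFAULT_REGION_MEANS: dict[str, float] = {
    "VO/LO": 320.0, "MO": 280.0, "NAca-m": 210.0, "NAca-l": 190.0,
    "NAcp-m": 230.0, "NAcp-l": 180.0, "NAcp-v": 170.0, "VP": 150.0,
    "MPOA": 260.0, "dHip": 340.0, "vHip": 300.0, "BLAa": 240.0,
    "BLAp": 220.0, "LHa": 200.0, "LHp": 210.0, "VMH": 160.0,
    "ARC": 250.0, "VTA": 140.0, "DR": 120.0, "MR": 90.0,
}


@dataclass
class CountGenConfig:
    """Configuration of the count generator.

    ``dispersion`` is the coefficient of variation of each region's counts
    across subjects (default 0.3, a typical between-animal spread for
    immediate-early-gene counts). ``latent_correlation`` must be a valid
    correlation matrix (symmetric, unit diagonal, positive semi-definite)
    over the atlas regions.
    """

    atlas: RegionAtlas = DEFAULT_ATLAS
    n_subjects: int = 10
    region_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_MEANS)
    )
    dispersion: float = 0.3
    latent_correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        missing = [l for l in self.atlas.labels if l not in self.region_means]
        if missing:
            raise ValueError(f"region_means missing regions: {missing}")
        if any(self.region_means[l] <= 0 for l in self.atlas.labels):
            raise ValueError("all region means must be positive")
        if self.latent_correlation is None:
            self.latent_correlation = np.eye(len(self.atlas))
        R = np.asarray(self.latent_correlation, dtype=float)
        k = len(self.atlas)
        if R.shape != (k, k):
            raise ValueError(f"latent_correlation must be {k}x{k}, got {R.shape}")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("latent_correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("latent_correlation must have unit diagonal")
        min_eig = float(np.linalg.eigvalsh(R).min())
        if min_eig < -1e-10:
            raise ValueError(
                f"latent_correlation is not positive semi-definite: "
                f"smallest eigenvalue {min_eig:.6g}"
            )
        self.latent_correlation = R


def generate_counts(config: CountGenConfig, group: str = "synthetic") -> CountTable:
    """Draw a subjects x regions count table with the configured structure.

    Latent vectors z ~ N(0, R) are mapped per region to
    ``round(exp(mu + sigma*z))`` with ``sigma**2 = log(1 + cv**2)`` and
    ``mu = log(mean) - sigma**2/2``, so column means equal the configured
    region means in expectation and column CVs equal ``dispersion``.
    Negative rounded values cannot occur (the exponential is positive) but
    the clip keeps the non-negativity contract explicit. Deterministic for a
    given config and seed.
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.atlas)
    z = rng.multivariate_normal(
        np.zeros(k), config.latent_correlation, size=config.n_subjects,
        method="eigh",
    )
    cv = config.dispersion
    sigma = np.sqrt(np.log1p(cv * cv))
    means = np.array([config.region_means[l] for l in config.atlas.labels])
    mu = np.log(means) - 0.5 * sigma * sigma
    counts = np.rint(np.exp(mu[None, :] + sigma * z)).clip(min=0).astype(int)
    values = pd.DataFrame(
        counts,
        index=[f"{group}_{i + 1:03d}" for i in range(config.n_subjects)],
        columns=list(config.atlas.labels),
    )
    values.index.name = "subject_id"
    return CountTable(values=values, group=group)


# ---------------------------------------------------------------------------
# Two-group sparse-vs-dense presets
# ---------------------------------------------------------------------------

_WT_MODULE = ("VO/LO", "MO", "VP", "BLAa", "MR")
_KO_MODULE = ("VP", "BLAa", "MPOA", "LHp", "DR")
_KO_HUB = "NAcp-m"


def _block_correlation(
    atlas: RegionAtlas,
    base: float,
    module: Sequence[str] = (),
    module_r: float = 0.0,
    hub: str | None = None,
    hub_r: float = 0.0,
) -> np.ndarray:
    idx = {l: i for i, l in enumerate(atlas.labels)}
    R = np.full((len(atlas), len(atlas)), base)
    for a in module:
        for b in module:
            if a != b:
                R[idx[a], idx[b]] = module_r
    if hub is not None:
        for l in atlas.labels:
            if l != hub:
                R[idx[hub], idx[l]] = R[idx[l], idx[hub]] = hub_r
    np.fill_diagonal(R, 1.0)
    return R


def wt_preset(n_subjects: int = 20, seed: int = 0) -> CountGenConfig:
    """Sparse wild-type-like preset: near-independent regions plus one
    correlated module (orbitofrontal cortex, ventral pallidum, anterior
    basolateral amygdala, median raphe)."""
    return CountGenConfig(
        n_subjects=n_subjects,
        latent_correlation=_block_correlation(
            DEFAULT_ATLAS, base=0.05, module=_WT_MODULE, module_r=0.65
        ),
        seed=seed,
    )


def ko_preset(n_subjects: int = 18, seed: int = 1) -> CountGenConfig:
    """Dense knockout-like preset: uniformly elevated interregional
    correlation (0.45), a second correlated module, and a dominant medial
    posterior accumbens hub correlated 0.65 with every region."""
    return CountGenConfig(
        n_subjects=n_subjects,
        latent_correlation=_block_correlation(
            DEFAULT_ATLAS, base=0.45, module=_KO_MODULE, module_r=0.65,
            hub=_KO_HUB, hub_r=0.65,
        ),
        seed=seed,
    )


def make_two_group_dataset(
    wt: CountGenConfig | None = None,
    ko: CountGenConfig | None = None,
    seed: int | None = None,
) -> tuple[CountTable, CountTable]:
    """Paired WT-like (sparse) and KO-like (dense) count tables.

    With no arguments, uses the default presets (20 and 18 subjects, the
    correlation sample sizes of the original design; per-mouse sizes of 10
    and 9 are available by passing ``wt_preset(10)`` / ``ko_preset(9)``).
    A bare ``seed`` derives distinct sub-seeds for the two groups.
    """
    if seed is not None:
        wt = replace(wt or wt_preset(), seed=2 * seed)
        ko = replace(ko or ko_preset(), seed=2 * seed + 1)
    wt = wt or wt_preset()
    ko = ko or ko_preset()
    if wt.atlas.labels != ko.atlas.labels:
        raise AtlasMismatchError("the two group configs must share one atlas")
    return generate_counts(wt, group="WT"), generate_counts(ko, group="KO")


# ---------------------------------------------------------------------------
# Threshold-quitting operant agent
# ---------------------------------------------------------------------------


@dataclass
class AgentConfig:
    """A deliberately simple operant agent.

    The agent touches a panel every ``touch_interval`` seconds while engaged,
    sends each touch to the incorrect panel with probability ``error_rate``
    (incorrect touches do not count toward the ratio), and disengages — stops
    touching for good — as soon as the next trial's required ratio exceeds
    ``quit_threshold``. Reward collection takes ``collect_delay`` seconds and
    is followed by a 30-s inter-trial interval.
    """

    quit_threshold: int = 20
    error_rate: float = 0.1
    touch_interval: float = 5.0
    collect_delay: float = 2.0
    iti: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quit_threshold < 0:
            raise ValueError("quit_threshold must be non-negative")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.touch_interval <= 0:
            raise ValueError("touch_interval must be positive")


def generate_session(
    agent: AgentConfig,
    schedule: RatioSchedule | None = None,
    max_duration: float = 3600.0,
    quit_window: float = 300.0,
) -> SessionLog:
    """Simulate one session of the agent on a ratio schedule.

    The resulting log validates against all session invariants; its break
    point equals the largest schedule ratio not exceeding the agent's quit
    threshold (unless the session clock runs out first).
    """
    schedule = schedule or RatioSchedule.progressive()
    rng = np.random.default_rng(agent.seed)
    events: list[Event] = []
    t = 0.0
    m = 1
    while True:
        required = response_ratio(schedule, m)
        if required > agent.quit_threshold or t >= max_duration:
            break
        events.append(Event(t, "trial_start"))
        correct = 0
        truncated = False
        while correct < required:
            t += agent.touch_interval
            if t > max_duration:
                truncated = True
                break
            if rng.random() < agent.error_rate:
                events.append(Event(t, "incorrect_touch"))
            else:
                events.append(Event(t, "correct_touch"))
                correct += 1
        if truncated:
            break
        t += agent.collect_delay
        if t > max_duration:
            break
        events.append(Event(t, "reward_collected"))
        t += agent.iti
        m += 1
    log = SessionLog(
        events=events,
        schedule=schedule,
        max_duration=max_duration,
        quit_window=quit_window,
    )
    log.validate()
    return log
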