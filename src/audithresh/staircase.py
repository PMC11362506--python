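"""Transformed up-down (Levitt) adaptive staircase engine.

The staircase adaptively varies a stimulus difference ("delta") by
multiplication/division: after ``n_down`` consecutive correct responses the
delta is divided by the factor in force (a DOWN step, making the trial
harder); after a single incorrect response it is multiplied by that factor
(an UP step).  A change of step direction is a *reversal*; the deltas logged
at the final reversals estimate the threshold.

An n-down/one-up rule converges on the delta at which the probability of a
down step equals the probability of an up step, i.e. the point ``p`` of the
psychometric function solving ``p**n_down == 1/2`` — 70.7% correct for the
two-down/one-up rule and 79.4% for the three-down/one-up rule.

Step sizes are organised in *phases*: typically a large factor (2) for the
first few reversals to approach the threshold quickly, then a small factor
(sqrt(2)) for fine estimation.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "Direction",
    "MeanType",
    "StaircaseConfig",
    "TrackState",
    "ThresholdEstimate",
    "StaircaseUsageError",
    "InsufficientDataError",
    "new_track",
    "update_track",
    "current_factor",
    "threshold_last_k",
    "threshold_midpoint_runs",
    "compute_threshold",
    "equilibrium_probability",
    "standard_staircase",
    "lab_staircase",
    "quick_staircase",
]

SQRT2 = math.sqrt(2.0)


class StaircaseUsageError(RuntimeError):
    """Raised when the staircase API is misused (e.g. updating a finished track)."""


class InsufficientDataError(ValueError):
    """Raised when a threshold is requested from too few reversals."""


class Direction(enum.Enum):
    NONE = "none"
    UP = "up"
    DOWN = "down"


class MeanType(str, enum.Enum):
    ARITHMETIC = "arithmetic"
    GEOMETRIC = "geometric"


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of one n-down/one-up adaptive track.

    Parameters
    ----------
    n_down
        Number of consecutive correct responses that triggers a DOWN step.
        2 and 3 are the classic rules; any n >= 1 is accepted.
    phases
        Ordered ``(reversal_count, factor)`` pairs.  The i-th reversal is
        collected under the phase whose cumulative count contains i; the
        factor of that phase multiplies/divides delta on every step taken
        while waiting for that reversal.  Default: 4 reversals at factor 2,
        then 8 at sqrt(2).
    start_delta
        Delta presented on the first trial, in experiment units (Hz, dB, ms
        or percent).  Should be comfortably above threshold.
    reversal_threshold_k
        How many of the final reversals enter the threshold average.
    mean_type
        Average the reversal deltas arithmetically (default) or geometrically.
    delta_min, delta_max
        Hard bounds; delta is clamped (never rejected) at them.
    max_trials
        Safety cap: the track finishes unconditionally at this many trials.
    """

    n_down: int = 2
    phases: tuple[tuple[int, float], ...] = ((4, 2.0), (8, SQRT2))
    start_delta: float = 100.0
    reversal_threshold_k: int = 8
    mean_type: MeanType = MeanType.ARITHMETIC
    delta_min: float = 1e-6
    delta_max: float = 1e6
    max_trials: int = 1000

    def __post_init__(self) -> None:
        if self.n_down < 1:
            raise ValueError(f"n_down must be >= 1, got {self.n_down}")
        if not self.phases:
            raise ValueError("phases must not be empty")
        for count, factor in self.phases:
            if count < 1:
                raise ValueError(f"phase reversal_count must be >= 1, got {count}")
            if factor <= 1.0:
                raise ValueError(f"every factor must be > 1, got {factor}")
        if self.start_delta <= 0:
            raise ValueError("start_delta must be positive")
        if not (self.delta_min <= self.start_delta <= self.delta_max):
            raise ValueError(
                f"start_delta {self.start_delta} outside "
                f"[{self.delta_min}, {self.delta_max}]"
            )
        if self.reversal_threshold_k < 1:
            raise ValueError("reversal_threshold_k must be >= 1")
        if self.reversal_threshold_k > self.total_reversals:
            raise ValueError(
                f"reversal_threshold_k ({self.reversal_threshold_k}) exceeds total "
                f"reversals to collect ({self.total_reversals})"
            )
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")
        if self.reversal_threshold_k % 2 == 1:
            # Levitt recommends an even number of reversals to reduce bias.
            warnings.warn(
                "reversal_threshold_k is odd; an even number of reversals is "
                "recommended to reduce estimation bias",
                UserWarning,
                stacklevel=2,
            )

    @property
    def total_reversals(self) -> int:
        return sum(count for count, _ in self.phases)

    def factor_for_reversal(self, reversal_number: int) -> float:
        """Factor in force while collecting the given (1-based) reversal."""
        cumulative = 0
        for count, factor in self.phases:
            cumulative += count
            if reversal_number <= cumulative:
                return factor
        # Beyond the configured total (e.g. max_trials overrun): keep the
        # final phase's factor.
        return self.phases[-1][1]

    @property
    def rule_name(self) -> str:
        return f"{self.n_down}-down/1-up"


@dataclass
class TrackState:
    """Mutable state of one running adaptive track."""

    delta: float
    consecutive_correct: int = 0
    last_direction: Direction = Direction.NONE
    reversals: list[tuple[int, float]] = field(default_factory=list)
    trial_count: int = 0
    finished: bool = False
    clamp_events: list[int] = field(default_factory=list)

    @property
    def reversal_deltas(self) -> list[float]:
        return [delta for _, delta in self.reversals]


@dataclass(frozen=True)
class ThresholdEstimate:
    """A reversal-based threshold, in the experiment's delta units."""

    value: float
    method: str  # "last_k_mean" | "midpoint_of_runs"
    n_reversals_used: int
    complete: bool = True


def new_track(config: StaircaseConfig) -> TrackState:
    """Create a fresh track positioned at the configured start delta."""
    return TrackState(delta=config.start_delta)


def current_factor(state: TrackState, config: StaircaseConfig) -> float:
    """Factor the next step will use.

    Once the i-th reversal is recorded, steps are taken under the phase that
    reversal i+1 falls in: the step immediately following a phase-boundary
    reversal already uses the next phase's factor.
    """
    return config.factor_for_reversal(len(state.reversals) + 1)


def update_track(state: TrackState, config: StaircaseConfig, correct: bool) -> TrackState:
    """Advance the track by one trial outcome (mutates and returns ``state``).

    Correct responses accumulate until ``n_down`` of them trigger a DOWN step
    (delta divided by the factor in force); any incorrect response triggers an
    UP step (delta multiplied).  A step whose direction differs from the
    previous step's direction records a reversal at the *pre-step* delta.  The
    first step of a track (direction still NONE) never records a reversal.

    The track finishes the moment the final configured reversal is recorded —
    that terminal step is not applied — or when ``max_trials`` is reached.
    """
    if state.finished:
        raise StaircaseUsageError("cannot update a finished track")

    state.trial_count += 1

    step: Direction | None = None
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= config.n_down:
            step = Direction.DOWN
            state.consecutive_correct = 0
    else:
        step = Direction.UP
        state.consecutive_correct = 0

    if step is not None:
        is_reversal = (
            state.last_direction is not Direction.NONE
            and step is not state.last_direction
        )
        if is_reversal:
            state.reversals.append((state.trial_count, state.delta))
            if len(state.reversals) >= config.total_reversals:
                # Terminal reversal: stop without applying the step.
                state.last_direction = step
                state.finished = True
                return state
        # Phase advances immediately on recording a boundary reversal.
        factor = current_factor(state, config)
        raw = state.delta / factor if step is Direction.DOWN else state.delta * factor
        clamped = min(max(raw, config.delta_min), config.delta_max)
        if clamped != raw:
            state.clamp_events.append(state.trial_count)
        state.delta = clamped
        state.last_direction = step

    if state.trial_count >= config.max_trials:
        state.finished = True
    return state


def _mean(values: list[float], mean_type: MeanType) -> float:
    if mean_type is MeanType.GEOMETRIC:
        return math.exp(sum(math.log(v) for v in values) / len(values))
    return sum(values) / len(values)


def threshold_last_k(
    reversals: list[float],
    k: int,
    mean_type: MeanType = MeanType.ARITHMETIC,
    complete: bool = True,
) -> ThresholdEstimate:
    """Threshold as the mean of the final ``k`` reversal deltas."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(reversals):
        raise InsufficientDataError(
            f"need {k} reversals, only {len(reversals)} available"
        )
    if k % 2 == 1:
        warnings.warn(
            "averaging an odd number of reversals; an even number is "
            "recommended to reduce estimation bias",
            UserWarning,
            stacklevel=2,
        )
    tail = reversals[-k:]
    return ThresholdEstimate(
        value=_mean(tail, MeanType(mean_type)),
        method="last_k_mean",
        n_reversals_used=k,
        complete=complete,
    )


def threshold_midpoint_runs(
    reversals: list[float],
    n_used: int,
    mean_type: MeanType = MeanType.ARITHMETIC,
) -> ThresholdEstimate:
    """Threshold from midpoints of runs.

    A run is a stretch of steps in one direction, bounded by two reversals;
    its midpoint is the arithmetic mean of those bounding reversal deltas.
    The final ``n_used`` reversals give ``n_used - 1`` midpoints, which are
    averaged (arithmetically by default).
    """
    if n_used % 2 == 1:
        raise ValueError(
            "n_used must be even: thresholds should be computed on an even "
            "number of reversals to reduce estimation bias"
        )
    if n_used < 2:
        raise ValueError("n_used must be >= 2")
    if n_used > len(reversals):
        raise InsufficientDataError(
            f"need {n_used} reversals, only {len(reversals)} available"
        )
    tail = reversals[-n_used:]
    midpoints = [(a + b) / 2.0 for a, b in zip(tail, tail[1:])]
    return ThresholdEstimate(
        value=_mean(midpoints, MeanType(mean_type)),
        method="midpoint_of_runs",
        n_reversals_used=n_used,
    )


def compute_threshold(state: TrackState, config: StaircaseConfig) -> ThresholdEstimate:
    """Reversal-based threshold of a finished (or truncated) track.

    If the track hit ``max_trials`` before collecting all configured
    reversals, the estimate is computed on the reversals available (with a
    warning) and flagged ``complete=False`` rather than discarded.
    """
    deltas = state.reversal_deltas
    if not deltas:
        raise InsufficientDataError("track recorded no reversals")
    complete = len(deltas) >= config.total_reversals
    k = config.reversal_threshold_k
    if not complete:
        warnings.warn(
            f"track truncated at {state.trial_count} trials with only "
            f"{len(deltas)} of {config.total_reversals} reversals; threshold "
            "computed on available reversals",
            UserWarning,
            stacklevel=2,
        )
        k = min(k, len(deltas))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # odd-k warned at config time
        return threshold_last_k(deltas, k, config.mean_type, complete=complete)


def equilibrium_probability(n_down: int) -> float:
    """Performance level an n-down/one-up rule converges to.

    The track is in equilibrium when a DOWN step (n consecutive correct,
    probability ``p**n``) is as likely as an UP step, so ``p**n = 1/2`` and
    the rule tracks ``p = 0.5 ** (1/n)``: 0.707 for n=2, 0.794 for n=3.
    """
    if n_down < 1:
        raise ValueError(f"n_down must be >= 1, got {n_down}")
    return 0.5 ** (1.0 / n_down)


def standard_staircase(**overrides) -> StaircaseConfig:
    """12-reversal track: 4 reversals at factor 2, 8 at sqrt(2), threshold on
    the last 8.  The common full-length laboratory configuration."""
    defaults = dict(
        n_down=2,
        phases=((4, 2.0), (8, SQRT2)),
        start_delta=100.0,
        reversal_threshold_k=8,
    )
    defaults.update(overrides)
    return StaircaseConfig(**defaults)


def lab_staircase(**overrides) -> StaircaseConfig:
    """8-reversal track: 2 reversals at factor 2, 6 at sqrt(2), threshold on
    the last 6.  Used for in-booth frequency-discrimination validation."""
    defaults = dict(
        n_down=2,
        phases=((2, 2.0), (6, SQRT2)),
        start_delta=100.0,
        reversal_threshold_k=6,
    )
    defaults.update(overrides)
    return StaircaseConfig(**defaults)


def quick_staircase(**overrides) -> StaircaseConfig:
    """6-reversal track: 2 reversals at factor 2, 4 at sqrt(2), threshold on
    the last 4.  A ~2-minute screening configuration for public demos."""
    defaults = dict(
        n_down=2,
        phases=((2, 2.0), (4, SQRT2)),
        start_delta=100.0,
        reversal_threshold_k=4,
    )
    defaults.update(overrides)
    return StaircaseConfig(**defaults)
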