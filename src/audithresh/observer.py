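"""Simulated listeners with parametric psychometric functions.

An observer answers forced-choice trials according to

    Psi(delta) = gamma + (1 - gamma - lambda) * F(delta)

where ``gamma`` is the guessing floor (1/n for an nAFC task), ``lambda`` a
lapse rate, and F the detection mechanism — by default a logistic in
log-delta, which matches the multiplicative geometry of the staircase:

    F(delta) = 1 / (1 + exp(-beta * (ln delta - ln alpha)))

``alpha`` is the delta at which F = 0.5 and ``beta`` the slope on the
log-delta axis.  A Weibull alternative (F = 1 - exp(-(delta/alpha)**beta))
is available.  Driving a staircase with such an observer in closed loop
validates that the rule converges on the performance level it is supposed
to track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .staircase import StaircaseConfig, compute_threshold, equilibrium_probability, new_track, update_track
from .experiments import ExperimentSpec, Trial, make_trial, score_response

__all__ = ["PsychometricObserver", "TrackedPerformance", "tracked_performance"]


@dataclass
class PsychometricObserver:
    """Parametric simulated listener.

    Parameters
    ----------
    alpha
        Threshold location in delta units (F(alpha) = 0.5 for the logistic).
        ``math.inf`` makes a zero-sensitivity observer: Psi is identically
        gamma, i.e. pure guessing.
    beta
        Slope on the log-delta axis.
    gamma
        Guess floor; use 1/n_afc for forced choice.
    lapse
        Lapse rate lambda: the probability of an inattentive miss even on an
        easy trial.  Default 0.
    seed
        Seed of the observer's private response RNG.
    model
        "logistic" (default) or "weibull".
    """

    alpha: float
    beta: float = 4.0
    gamma: float = 1.0 / 3.0
    lapse: float = 0.0
    seed: int = 0
    model: str = "logistic"
    _rng: np.random.Generator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")
        if self.gamma + self.lapse >= 1.0:
            raise ValueError("gamma + lapse must be < 1")
        if self.model not in ("logistic", "weibull"):
            raise ValueError(f"unknown model {self.model!r}")
        self._rng = np.random.default_rng(self.seed)

    @classmethod
    def zero_sensitivity(cls, n_afc: int, seed: int = 0) -> "PsychometricObserver":
        """An observer that only ever guesses: Psi(delta) = 1/n_afc."""
        return cls(alpha=math.inf, gamma=1.0 / n_afc, seed=seed)

    def p_correct(self, delta: float) -> float:
        """Psi(delta): probability of a correct response at this delta."""
        if delta <= 0:
            raise ValueError("delta must be positive")
        if math.isinf(self.alpha):
            f = 0.0
        elif self.model == "weibull":
            f = 1.0 - math.exp(-((delta / self.alpha) ** self.beta))
        else:
            f = 1.0 / (1.0 + math.exp(-self.beta * (math.log(delta) - math.log(self.alpha))))
        return self.gamma + (1.0 - self.gamma - self.lapse) * f

    def respond(self, trial: Trial) -> int:
        """Answer a trial: the target with probability Psi(delta), otherwise
        a uniformly random non-target interval."""
        if self._rng.random() < self.p_correct(trial.delta):
            return trial.target_index
        others = [i for i in range(trial.n_afc) if i != trial.target_index]
        return others[int(self._rng.integers(len(others)))]

    def with_seed(self, seed: int) -> "PsychometricObserver":
        """Copy of this observer with a fresh response RNG."""
        return replace(self, seed=seed)


@dataclass(frozen=True)
class TrackedPerformance:
    """Closed-loop convergence summary over replicate tracks."""

    thresholds: np.ndarray
    psi_at_threshold: np.ndarray
    n_trials: np.ndarray
    equilibrium: float

    @property
    def mean_threshold(self) -> float:
        return float(np.mean(self.thresholds))

    @property
    def sd_threshold(self) -> float:
        return float(np.std(self.thresholds, ddof=1))

    @property
    def mean_tracked_p(self) -> float:
        """Mean of Psi evaluated at each replicate's threshold estimate:
        the performance level the staircase empirically tracked."""
        return float(np.mean(self.psi_at_threshold))

    @property
    def sd_tracked_p(self) -> float:
        return float(np.std(self.psi_at_threshold, ddof=1))


def tracked_performance(
    config: StaircaseConfig,
    spec: ExperimentSpec,
    observer: PsychometricObserver,
    n_replicates: int = 500,
    seed: int | None = None,
) -> TrackedPerformance:
    """Run replicate closed-loop tracks and measure what they converge to.

    Each replicate drives a fresh staircase with an independently seeded copy
    of the observer; the replicate's threshold estimate is mapped back
    through the observer's (noise-free) psychometric function, and the mean
    of those Psi values is the empirically tracked performance level, to be
    compared with ``equilibrium_probability(config.n_down)``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(observer.seed if seed is None else seed)
    thresholds = np.empty(n_replicates)
    psi = np.empty(n_replicates)
    n_trials = np.empty(n_replicates, dtype=int)
    for i, child in enumerate(ss.spawn(n_replicates)):
        trial_seed, obs_seed = child.generate_state(2) >> 1  # keep below 2**31
        rng = np.random.default_rng(int(trial_seed))
        obs = observer.with_seed(int(obs_seed))
        track = new_track(config)
        while not track.finished:
            trial = make_trial(spec, track.delta, rng)
            correct = score_response(trial, obs.respond(trial))
            update_track(track, config, correct)
        estimate = compute_threshold(track, config)
        thresholds[i] = estimate.value
        psi[i] = obs.p_correct(estimate.value)
        n_trials[i] = track.trial_count
    return TrackedPerformance(
        thresholds=thresholds,
        psi_at_threshold=psi,
        n_trials=n_trials,
        equilibrium=equilibrium_probability(config.n_down),
    )
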