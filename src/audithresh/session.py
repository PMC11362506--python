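"""Familiarisation, blocks, sessions, and the two CSV datafiles.

A *session* runs one experiment for ``n_blocks`` blocks; each block is one
complete adaptive track and yields a reversal-based threshold; the session
threshold is the arithmetic mean of the block thresholds.  Two datafiles
record the outcome:

* the **reduced** file — participant demographics plus one threshold row per
  block;
* the **extended** file — one row per trial carrying the full event log
  (delta, response, correctness, running reversal count) together with the
  experiment, standard-stimulus and staircase settings, including the block
  seeds.  The extended file is a sufficient statistic for the block: replaying
  it reproduces the identical trial stream.

Responders are any object with ``respond(trial) -> interval index``: a
simulated observer, a scripted list of responses, or an interactive prompt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .experiments import (
    ExperimentName,
    ExperimentSpec,
    Trial,
    builtin_experiment,
    make_trial,
    score_response,
)
from .staircase import (
    MeanType,
    StaircaseConfig,
    ThresholdEstimate,
    compute_threshold,
    current_factor,
    new_track,
    update_track,
)
from .stimuli import NoiseSpec, ToneSpec

__all__ = [
    "ParticipantInfo",
    "TrialRecord",
    "BlockResult",
    "SessionResult",
    "FamiliarisationResult",
    "ScriptedResponder",
    "PatternResponder",
    "run_familiarisation",
    "run_block",
    "run_session",
    "write_reduced_csv",
    "write_extended_csv",
    "replay_extended_csv",
    "EXTENDED_COLUMNS",
    "REDUCED_COLUMNS",
]


@dataclass(frozen=True)
class ParticipantInfo:
    """Optional demographics; every field may be left empty (anonymous
    deployments omit them)."""

    name: str = ""
    surname: str = ""
    age: str = ""
    biological_sex: str = ""
    notes: str = ""


@dataclass(frozen=True)
class TrialRecord:
    """One row of the extended datafile."""

    block_index: int
    trial_index: int
    experiment_name: str
    n_afc: int
    isi_ms: float
    iti_ms: float
    algorithm: str
    factor_in_force: float
    delta: float
    target_index: int
    response_index: int
    correct: bool
    reversal_count_so_far: int
    timestamp_ms: float


@dataclass(frozen=True)
class BlockResult:
    """One block's adaptive track, summarised."""

    block_index: int
    threshold: ThresholdEstimate
    reversal_deltas: list[float]
    n_trials: int
    complete: bool
    seed: int


@dataclass(frozen=True)
class SessionResult:
    spec: ExperimentSpec
    config: StaircaseConfig
    participant: ParticipantInfo
    blocks: list[BlockResult]
    records: list[TrialRecord]
    threshold: float


@dataclass(frozen=True)
class FamiliarisationResult:
    passed: bool
    n_trials: int
    log: list[tuple[float, bool]]  # (delta, correct) per trial


class ScriptedResponder:
    """Replays a fixed sequence of interval indices."""

    def __init__(self, responses: list[int]):
        self._responses = list(responses)
        self._pos = 0

    def respond(self, trial: Trial) -> int:
        if self._pos >= len(self._responses):
            raise RuntimeError("scripted responder ran out of responses")
        response = int(self._responses[self._pos])
        self._pos += 1
        return response


class PatternResponder:
    """Answers correct ('+') or incorrect ('-') following a pattern string.

    Useful for hand-traced staircase sequences: '+' picks the target, '-'
    deterministically picks the next interval after it.
    """

    def __init__(self, pattern: str):
        if set(pattern) - {"+", "-"}:
            raise ValueError("pattern may contain only '+' and '-'")
        self._pattern = pattern
        self._pos = 0

    def respond(self, trial: Trial) -> int:
        if self._pos >= len(self._pattern):
            raise RuntimeError("pattern responder ran out of responses")
        symbol = self._pattern[self._pos]
        self._pos += 1
        if symbol == "+":
            return trial.target_index
        return (trial.target_index + 1) % trial.n_afc


def run_familiarisation(
    spec: ExperimentSpec,
    responder,
    fixed_deltas: list[float] | None = None,
    required_streak: int = 6,
    trial_cap: int = 30,
    start_delta: float = 100.0,
    seed: int = 0,
) -> FamiliarisationResult:
    """Easy fixed-delta trials until a streak of consecutive correct answers.

    Each trial draws one of ``fixed_deltas`` (default: the start delta and
    half of it) at random; an error resets the streak.  The participant
    passes on ``required_streak`` consecutive correct responses and fails if
    the trial cap is reached first.
    """
    if required_streak < 1:
        raise ValueError("required_streak must be >= 1")
    if fixed_deltas is None:
        fixed_deltas = [start_delta, start_delta / 2.0]
    rng = np.random.default_rng(seed)
    streak = 0
    log: list[tuple[float, bool]] = []
    while len(log) < trial_cap:
        delta = float(fixed_deltas[int(rng.integers(len(fixed_deltas)))])
        trial = make_trial(spec, delta, rng)
        correct = score_response(trial, responder.respond(trial))
        log.append((delta, correct))
        streak = streak + 1 if correct else 0
        if streak >= required_streak:
            return FamiliarisationResult(passed=True, n_trials=len(log), log=log)
    return FamiliarisationResult(passed=False, n_trials=len(log), log=log)


def _effective_config(spec: ExperimentSpec, config: StaircaseConfig) -> StaircaseConfig:
    """Tighten the staircase bounds to the experiment's physical bounds."""
    lo = max(config.delta_min, spec.delta_bounds[0])
    hi = min(config.delta_max, spec.delta_bounds[1])
    if (lo, hi) != (config.delta_min, config.delta_max):
        config = replace(config, delta_min=lo, delta_max=hi)
    return config


def _trial_duration_ms(trial: Trial, spec: ExperimentSpec) -> float:
    stim = sum(p.base.duration_ms for p in trial.interval_params)
    return stim + (trial.n_afc - 1) * spec.isi_ms + spec.iti_ms


def run_block(
    spec: ExperimentSpec,
    config: StaircaseConfig,
    responder,
    seed: int = 0,
    block_index: int = 1,
    render_audio: bool = False,
    feedback: bool = False,
) -> tuple[BlockResult, list[TrialRecord]]:
    """One complete adaptive track: make trial, respond, score, update.

    ``seed`` drives target placement and noise tokens.  Timestamps are a
    nominal block clock accumulated from stimulus durations, ISI and ITI
    (simulation does not sleep through the ITI).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # odd-k already warned at config time
        config = _effective_config(spec, config)
    rng = np.random.default_rng(seed)
    track = new_track(config)
    records: list[TrialRecord] = []
    clock_ms = 0.0
    while not track.finished:
        trial = make_trial(spec, track.delta, rng, render_audio=render_audio)
        response = responder.respond(trial)
        correct = score_response(trial, response, feedback=feedback)
        factor = current_factor(track, config)
        delta_presented = track.delta
        update_track(track, config, correct)
        clock_ms += _trial_duration_ms(trial, spec)
        records.append(
            TrialRecord(
                block_index=block_index,
                trial_index=track.trial_count,
                experiment_name=spec.name.value,
                n_afc=spec.n_afc,
                isi_ms=spec.isi_ms,
                iti_ms=spec.iti_ms,
                algorithm=config.rule_name,
                factor_in_force=factor,
                delta=delta_presented,
                target_index=trial.target_index,
                response_index=response,
                correct=correct,
                reversal_count_so_far=len(track.reversals),
                timestamp_ms=clock_ms,
            )
        )
    estimate = compute_threshold(track, config)
    result = BlockResult(
        block_index=block_index,
        threshold=estimate,
        reversal_deltas=track.reversal_deltas,
        n_trials=track.trial_count,
        complete=estimate.complete,
        seed=seed,
    )
    return result, records


def run_session(
    spec: ExperimentSpec,
    config: StaircaseConfig,
    responder,
    n_blocks: int | None = None,
    participant: ParticipantInfo | None = None,
    seed: int = 0,
    block_seeds: list[int] | None = None,
    feedback: bool = False,
) -> SessionResult:
    """Run the blocks of a session and average their thresholds.

    Block seeds are derived from the master ``seed`` unless given explicitly
    (replay passes the seeds recorded in the extended datafile).  Incomplete
    blocks are flagged and excluded from the session mean, with a warning.
    """
    n_blocks = spec.n_blocks if n_blocks is None else n_blocks
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    participant = participant or ParticipantInfo()
    if block_seeds is None:
        block_seeds = [
            int(s >> 1) for s in np.random.SeedSequence(seed).generate_state(n_blocks)
        ]
    elif len(block_seeds) != n_blocks:
        raise ValueError("need one block seed per block")
    blocks: list[BlockResult] = []
    records: list[TrialRecord] = []
    for b, block_seed in enumerate(block_seeds, start=1):
        result, block_records = run_block(
            spec, config, responder, seed=block_seed, block_index=b, feedback=feedback
        )
        blocks.append(result)
        records.extend(block_records)
    complete = [b for b in blocks if b.complete]
    if len(complete) < len(blocks):
        warnings.warn(
            f"{len(blocks) - len(complete)} of {len(blocks)} blocks incomplete; "
            "session threshold averages the complete blocks only",
            UserWarning,
            stacklevel=2,
        )
    used = complete or blocks
    threshold = sum(b.threshold.value for b in used) / len(used)
    return SessionResult(
        spec=spec,
        config=config,
        participant=participant,
        blocks=blocks,
        records=records,
        threshold=threshold,
    )


# --- CSV datafiles ---------------------------------------------------------

REDUCED_COLUMNS = [
    "Name", "Surname", "Age", "BiologicalSex", "Notes",
    "Experiment", "Block", "Threshold", "nTrials", "Complete",
]

EXTENDED_COLUMNS = [
    "Name", "Surname", "Age", "BiologicalSex", "Notes",
    "Experiment", "Block", "Trial",
    "nAFC", "ISI", "ITI", "Reversal threshold", "Algorithm", "Phases",
    "StartDelta", "DeltaMin", "DeltaMax", "MaxTrials", "MeanType", "DeltaUnits",
    "StandardFrequencyHz", "StandardDurationMs", "StandardLevelDbFS",
    "StandardRampMs", "AmModRateHz", "SampleRate", "BlockSeed",
    "Factor", "Delta", "Target", "Response", "Correct", "Reversals",
    "TimestampMs",
]

_DEMOGRAPHIC_COLUMNS = ["Name", "Surname", "Age", "BiologicalSex", "Notes"]


def _phases_to_str(phases: tuple[tuple[int, float], ...]) -> str:
    return ";".join(f"{count}x{factor!r}" for count, factor in phases)


def _phases_from_str(text: str) -> tuple[tuple[int, float], ...]:
    parts = []
    for chunk in text.split(";"):
        count, factor = chunk.split("x")
        parts.append((int(count), float(factor)))
    return tuple(parts)


def write_reduced_csv(session: SessionResult, path) -> None:
    """Demographics plus one threshold row per block."""
    p = session.participant
    rows = [
        {
            "Name": p.name, "Surname": p.surname, "Age": p.age,
            "BiologicalSex": p.biological_sex, "Notes": p.notes,
            "Experiment": session.spec.name.value,
            "Block": b.block_index,
            "Threshold": b.threshold.value,
            "nTrials": b.n_trials,
            "Complete": int(b.complete),
        }
        for b in session.blocks
    ]
    pd.DataFrame(rows, columns=REDUCED_COLUMNS).to_csv(path, index=False)


def write_extended_csv(session: SessionResult, path) -> None:
    """The complete trial-by-trial log, one row per trial.

    Carries the columns of the classic datafile (nAFC, ISI, ITI, Reversal
    threshold, Algorithm, Delta, Correct, Reversals) plus the standard
    stimulus, staircase settings and block seeds that make the file
    replayable.
    """
    spec, config, p = session.spec, session.config, session.participant
    std = spec.standard
    is_tone = isinstance(std, ToneSpec)
    block_seed = {b.block_index: b.seed for b in session.blocks}
    rows = []
    for r in session.records:
        rows.append(
            {
                "Name": p.name, "Surname": p.surname, "Age": p.age,
                "BiologicalSex": p.biological_sex, "Notes": p.notes,
                "Experiment": r.experiment_name,
                "Block": r.block_index,
                "Trial": r.trial_index,
                "nAFC": r.n_afc,
                "ISI": r.isi_ms,
                "ITI": r.iti_ms,
                "Reversal threshold": config.reversal_threshold_k,
                "Algorithm": r.algorithm,
                "Phases": _phases_to_str(config.phases),
                "StartDelta": config.start_delta,
                "DeltaMin": config.delta_min,
                "DeltaMax": config.delta_max,
                "MaxTrials": config.max_trials,
                "MeanType": config.mean_type.value,
                "DeltaUnits": spec.delta_units.value,
                "StandardFrequencyHz": std.frequency if is_tone else "",
                "StandardDurationMs": std.duration_ms,
                "StandardLevelDbFS": std.level_dbfs,
                "StandardRampMs": std.ramp_ms,
                "AmModRateHz": spec.am_mod_rate_hz,
                "SampleRate": spec.sample_rate,
                "BlockSeed": block_seed[r.block_index],
                "Factor": r.factor_in_force,
                "Delta": r.delta,
                "Target": r.target_index,
                "Response": r.response_index,
                "Correct": int(r.correct),
                "Reversals": r.reversal_count_so_far,
                "TimestampMs": r.timestamp_ms,
            }
        )
    pd.DataFrame(rows, columns=EXTENDED_COLUMNS).to_csv(path, index=False)


def replay_extended_csv(path) -> SessionResult:
    """Re-run the session encoded in an extended datafile.

    The experiment, standard stimulus and staircase settings are rebuilt
    from the metadata columns; trial generation is re-seeded with the
    recorded block seeds and the recorded responses are replayed verbatim.
    The result's trial records — and a rewrite of the extended file —
    reproduce the original exactly.
    """
    df = pd.read_csv(path, dtype={c: str for c in _DEMOGRAPHIC_COLUMNS})
    if df.empty:
        raise ValueError(f"no trial rows in {path}")
    first = df.iloc[0]

    def _demo(value) -> str:
        return "" if pd.isna(value) else str(value)

    participant = ParticipantInfo(
        name=_demo(first["Name"]),
        surname=_demo(first["Surname"]),
        age=_demo(first["Age"]),
        biological_sex=_demo(first["BiologicalSex"]),
        notes=_demo(first["Notes"]),
    )
    name = ExperimentName(first["Experiment"])
    if pd.isna(first["StandardFrequencyHz"]):
        standard: ToneSpec | NoiseSpec = NoiseSpec(
            duration_ms=float(first["StandardDurationMs"]),
            level_dbfs=float(first["StandardLevelDbFS"]),
            ramp_ms=float(first["StandardRampMs"]),
        )
    else:
        standard = ToneSpec(
            frequency=float(first["StandardFrequencyHz"]),
            duration_ms=float(first["StandardDurationMs"]),
            level_dbfs=float(first["StandardLevelDbFS"]),
            ramp_ms=float(first["StandardRampMs"]),
        )
    spec = builtin_experiment(
        name,
        standard=standard,
        n_afc=int(first["nAFC"]),
        isi_ms=float(first["ISI"]),
        iti_ms=float(first["ITI"]),
        am_mod_rate_hz=float(first["AmModRateHz"]),
        sample_rate=int(first["SampleRate"]),
        n_blocks=int(df["Block"].nunique()),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        config = StaircaseConfig(
            n_down=int(str(first["Algorithm"]).split("-")[0]),
            phases=_phases_from_str(str(first["Phases"])),
            start_delta=float(first["StartDelta"]),
            reversal_threshold_k=int(first["Reversal threshold"]),
            mean_type=MeanType(first["MeanType"]),
            delta_min=float(first["DeltaMin"]),
            delta_max=float(first["DeltaMax"]),
            max_trials=int(first["MaxTrials"]),
        )
    block_ids = sorted(df["Block"].unique())
    block_seeds = [int(df.loc[df["Block"] == b, "BlockSeed"].iloc[0]) for b in block_ids]
    responses = [int(x) for x in df.sort_values(["Block", "Trial"])["Response"]]
    responder = ScriptedResponder(responses)
    return run_session(
        spec,
        config,
        responder,
        n_blocks=len(block_ids),
        participant=participant,
        block_seeds=block_seeds,
    )
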