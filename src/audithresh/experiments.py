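"""The six built-in forced-choice experiments and mI-nAFC trial assembly.

Each experiment measures a discrimination or detection threshold by varying
one physical parameter (the *delta*) of a variable stimulus against a fixed
standard:

=====================  ==============================  ========
experiment             delta controls                  units
=====================  ==============================  ========
freq_disc_tone         frequency increment             Hz
intensity_disc_tone    level increment                 dB
duration_disc_tone     duration increment (tone)       ms
duration_disc_noise    duration increment (noise)      ms
gap_detection_noise    silent-gap duration             ms
am_detection_noise     sinusoidal AM depth             percent
=====================  ==============================  ========

A trial presents ``n_afc`` intervals — one variable at a uniformly random
position, the rest standards — separated by the inter-stimulus interval
(ISI).  The variable is always the "greater" stimulus: higher frequency,
higher level, longer, or carrying the gap/modulation that the standard lacks.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .stimuli import (
    DEFAULT_SAMPLE_RATE,
    NoiseSpec,
    ToneSpec,
    Waveform,
    amplitude_modulate,
    insert_gap,
    pure_tone,
    white_noise,
)

__all__ = [
    "ExperimentName",
    "DeltaUnits",
    "ExperimentSpec",
    "StimulusParams",
    "Trial",
    "builtin_experiment",
    "BUILTIN_EXPERIMENTS",
    "variable_from_delta",
    "standard_params",
    "render_stimulus",
    "make_trial",
    "score_response",
]


class ExperimentName(str, enum.Enum):
    FREQ_DISC_TONE = "freq_disc_tone"
    INTENSITY_DISC_TONE = "intensity_disc_tone"
    DURATION_DISC_TONE = "duration_disc_tone"
    DURATION_DISC_NOISE = "duration_disc_noise"
    GAP_DETECTION_NOISE = "gap_detection_noise"
    AM_DETECTION_NOISE = "am_detection_noise"


class DeltaUnits(str, enum.Enum):
    HZ = "Hz"
    DB = "dB"
    MS = "ms"
    PERCENT = "percent"


_EXPECTED_UNITS = {
    ExperimentName.FREQ_DISC_TONE: DeltaUnits.HZ,
    ExperimentName.INTENSITY_DISC_TONE: DeltaUnits.DB,
    ExperimentName.DURATION_DISC_TONE: DeltaUnits.MS,
    ExperimentName.DURATION_DISC_NOISE: DeltaUnits.MS,
    ExperimentName.GAP_DETECTION_NOISE: DeltaUnits.MS,
    ExperimentName.AM_DETECTION_NOISE: DeltaUnits.PERCENT,
}


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: the standard stimulus, what delta means, trial layout."""

    name: ExperimentName
    standard: ToneSpec | NoiseSpec
    delta_units: DeltaUnits
    delta_bounds: tuple[float, float]
    n_afc: int = 3
    isi_ms: float = 500.0
    iti_ms: float = 500.0
    n_blocks: int = 1
    feedback: bool = False
    am_mod_rate_hz: float = 20.0
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        name = ExperimentName(self.name)
        units = DeltaUnits(self.delta_units)
        if _EXPECTED_UNITS[name] is not units:
            raise ValueError(
                f"{name.value} varies {_EXPECTED_UNITS[name].value}, "
                f"not {units.value}"
            )
        lo, hi = self.delta_bounds
        if not (0 < lo < hi):
            raise ValueError(f"delta_bounds must satisfy 0 < min < max, got {self.delta_bounds}")
        if name is ExperimentName.GAP_DETECTION_NOISE and hi >= self.standard.duration_ms:
            raise ValueError("gap delta_max must be shorter than the standard noise")
        if name is ExperimentName.AM_DETECTION_NOISE and hi > 100.0:
            raise ValueError("AM depth delta_max cannot exceed 100 percent")
        if self.n_afc < 2:
            raise ValueError("n_afc must be >= 2")
        if self.isi_ms < 0 or self.iti_ms < 0:
            raise ValueError("ISI and ITI must be >= 0")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    @property
    def needs_noise(self) -> bool:
        return isinstance(self.standard, NoiseSpec)


@dataclass(frozen=True)
class StimulusParams:
    """Fully-resolved parameters of one interval's stimulus.

    ``gap_ms``/``am_depth_percent`` are zero for unmanipulated stimuli, so an
    interval differs from the standard only in the field its experiment
    manipulates.
    """

    base: ToneSpec | NoiseSpec
    gap_ms: float = 0.0
    am_depth_percent: float = 0.0
    am_mod_rate_hz: float = 20.0
    noise_seed: int | None = None


@dataclass(frozen=True)
class Trial:
    """One mI-nAFC trial: interval parameters, the target position, and —
    when rendered — the interval waveforms."""

    interval_params: tuple[StimulusParams, ...]
    target_index: int
    delta: float
    isi_ms: float
    interval_waveforms: tuple[Waveform, ...] | None = None

    @property
    def n_afc(self) -> int:
        return len(self.interval_params)


_BUILTIN_DEFAULTS = {
    ExperimentName.FREQ_DISC_TONE: dict(
        standard=ToneSpec(frequency=1000.0, duration_ms=250.0, level_dbfs=-20.0, ramp_ms=10.0),
        delta_units=DeltaUnits.HZ,
        delta_bounds=(1e-6, 10_000.0),
    ),
    ExperimentName.INTENSITY_DISC_TONE: dict(
        standard=ToneSpec(frequency=1000.0, duration_ms=250.0, level_dbfs=-40.0, ramp_ms=10.0),
        delta_units=DeltaUnits.DB,
        delta_bounds=(1e-6, 40.0),
    ),
    ExperimentName.DURATION_DISC_TONE: dict(
        standard=ToneSpec(frequency=1000.0, duration_ms=250.0, level_dbfs=-20.0, ramp_ms=10.0),
        delta_units=DeltaUnits.MS,
        delta_bounds=(1e-6, 2000.0),
    ),
    ExperimentName.DURATION_DISC_NOISE: dict(
        standard=NoiseSpec(duration_ms=250.0, level_dbfs=-20.0, ramp_ms=10.0),
        delta_units=DeltaUnits.MS,
        delta_bounds=(1e-6, 2000.0),
    ),
    ExperimentName.GAP_DETECTION_NOISE: dict(
        standard=NoiseSpec(duration_ms=500.0, level_dbfs=-20.0, ramp_ms=10.0),
        delta_units=DeltaUnits.MS,
        delta_bounds=(1e-6, 450.0),
    ),
    ExperimentName.AM_DETECTION_NOISE: dict(
        standard=NoiseSpec(duration_ms=500.0, level_dbfs=-20.0, ramp_ms=10.0),
        delta_units=DeltaUnits.PERCENT,
        delta_bounds=(1e-6, 100.0),
    ),
}

BUILTIN_EXPERIMENTS = tuple(name.value for name in ExperimentName)


def builtin_experiment(name: str | ExperimentName, **overrides) -> ExperimentSpec:
    """One of the six built-in experiments, with optional field overrides.

    Defaults follow common psychoacoustic practice: a 250-ms 1-kHz standard
    tone at -20 dB FS with 10-ms raised-cosine ramps, 3I-3AFC presentation,
    500-ms ISI/ITI, one block.
    """
    name = ExperimentName(name)
    kwargs = dict(_BUILTIN_DEFAULTS[name])
    kwargs.update(overrides)
    return ExperimentSpec(name=name, **kwargs)


def standard_params(spec: ExperimentSpec) -> StimulusParams:
    """The unmanipulated standard stimulus of the experiment."""
    return StimulusParams(base=spec.standard, am_mod_rate_hz=spec.am_mod_rate_hz)


def variable_from_delta(spec: ExperimentSpec, delta: float) -> StimulusParams:
    """Resolve the variable stimulus for the current delta.

    All parameters are copied from the standard except the one the
    experiment manipulates.  Intensity increments are clamped so the level
    never exceeds 0 dB FS (with a warning).
    """
    lo, hi = spec.delta_bounds
    if not (lo <= delta <= hi):
        raise ValueError(f"delta {delta} outside bounds [{lo}, {hi}]")
    name = spec.name
    std = spec.standard
    if name is ExperimentName.FREQ_DISC_TONE:
        return StimulusParams(base=replace(std, frequency=std.frequency + delta))
    if name is ExperimentName.INTENSITY_DISC_TONE:
        level = std.level_dbfs + delta
        if level > 0.0:
            warnings.warn(
                f"variable level {level:.2f} dB FS clamped to 0 dB FS (full scale)",
                UserWarning,
                stacklevel=2,
            )
            level = 0.0
        return StimulusParams(base=replace(std, level_dbfs=level))
    if name in (ExperimentName.DURATION_DISC_TONE, ExperimentName.DURATION_DISC_NOISE):
        # Lengthening extends the plateau; ramp durations are preserved.
        return StimulusParams(base=replace(std, duration_ms=std.duration_ms + delta))
    if name is ExperimentName.GAP_DETECTION_NOISE:
        return StimulusParams(base=std, gap_ms=delta)
    if name is ExperimentName.AM_DETECTION_NOISE:
        return StimulusParams(
            base=std, am_depth_percent=delta, am_mod_rate_hz=spec.am_mod_rate_hz
        )
    raise AssertionError(f"unhandled experiment {name}")


def render_stimulus(params: StimulusParams, sample_rate: int = DEFAULT_SAMPLE_RATE) -> Waveform:
    """Synthesize one interval's audio from its resolved parameters."""
    if isinstance(params.base, NoiseSpec):
        base = params.base
        if params.noise_seed is not None:
            base = replace(base, seed=params.noise_seed)
        wave = white_noise(base, sample_rate)
    else:
        wave = pure_tone(params.base, sample_rate)
    if params.gap_ms:
        wave = insert_gap(wave, params.gap_ms)
    if params.am_depth_percent:
        wave = amplitude_modulate(wave, params.am_depth_percent, params.am_mod_rate_hz)
    return wave


def make_trial(
    spec: ExperimentSpec,
    delta: float,
    rng: np.random.Generator,
    render_audio: bool = False,
) -> Trial:
    """Assemble one forced-choice trial at the given delta.

    The variable occupies a uniformly random interval; the other
    ``n_afc - 1`` intervals hold standards.  Noise-based experiments draw an
    independent noise seed per interval from ``rng``, so every interval is a
    fresh noise token.  Waveforms are synthesized only when ``render_audio``
    is set; simulations run on parameters alone.
    """
    target = int(rng.integers(spec.n_afc))
    variable = variable_from_delta(spec, delta)
    standard = standard_params(spec)
    intervals = []
    for i in range(spec.n_afc):
        params = variable if i == target else standard
        if spec.needs_noise:
            params = replace(params, noise_seed=int(rng.integers(2**31)))
        intervals.append(params)
    waveforms = None
    if render_audio:
        waveforms = tuple(render_stimulus(p, spec.sample_rate) for p in intervals)
    return Trial(
        interval_params=tuple(intervals),
        target_index=target,
        delta=delta,
        isi_ms=spec.isi_ms,
        interval_waveforms=waveforms,
    )


def score_response(trial: Trial, response_index: int, feedback: bool = False) -> bool:
    """True iff the response names the variable's interval.

    An out-of-range index raises without consuming the trial.
    """
    if not 0 <= response_index < trial.n_afc:
        raise ValueError(
            f"response_index {response_index} outside [0, {trial.n_afc})"
        )
    correct = response_index == trial.target_index
    if feedback:
        print("correct!" if correct else "wrong")
    return correct
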