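"""YAML/JSON configuration loading.

One file may hold ``experiment``, ``staircase`` and ``observer`` sections
(YAML is the native format; JSON is valid YAML and therefore accepted):

.. code-block:: yaml

    experiment:
      name: freq_disc_tone
      standard: {frequencyHz: 1000, durationMs: 250, levelDbfs: -20, rampMs: 10}
      nAfc: 3
      isiMs: 500
      itiMs: 500
      nBlocks: 3
      feedback: false
    staircase:
      rule: 2d1u            # or 3d1u, or an integer n
      phases: [[4, 2.0], [8, 1.4142135623730951]]
      startDelta: 100
      reversalThreshold: 8
      meanType: arithmetic
      deltaMin: 1.0e-6
      deltaMax: 10000
      maxTrials: 1000
    observer:
      model: logistic
      alphaDelta: 10
      beta: 4
      gammaAuto: true       # derive gamma = 1 / nAfc
      lambda: 0
      seed: 0
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .experiments import ExperimentSpec, NoiseSpec, ToneSpec, builtin_experiment
from .observer import PsychometricObserver
from .staircase import MeanType, StaircaseConfig

__all__ = ["ConfigError", "load_config", "parse_experiment", "parse_staircase", "parse_observer"]


class ConfigError(ValueError):
    """A malformed configuration; the message names the offending field."""


def _require(section: dict, field_name: str, section_name: str):
    if field_name not in section:
        raise ConfigError(f"missing required field '{section_name}.{field_name}'")
    return section[field_name]


def _rule_to_n_down(rule) -> int:
    if isinstance(rule, int):
        n = rule
    elif isinstance(rule, str) and rule.endswith("d1u") and rule[:-3].isdigit():
        n = int(rule[:-3])
    else:
        raise ConfigError(f"staircase.rule must be '2d1u', '3d1u' or an integer, got {rule!r}")
    if n < 1:
        raise ConfigError(f"staircase.rule must be >= 1, got {n}")
    return n


def parse_staircase(section: dict) -> StaircaseConfig:
    try:
        return StaircaseConfig(
            n_down=_rule_to_n_down(section.get("rule", "2d1u")),
            phases=tuple(
                (int(count), float(factor)) for count, factor in section.get("phases", [[4, 2.0], [8, 2**0.5]])
            ),
            start_delta=float(_require(section, "startDelta", "staircase")),
            reversal_threshold_k=int(section.get("reversalThreshold", 8)),
            mean_type=MeanType(section.get("meanType", "arithmetic")),
            delta_min=float(section.get("deltaMin", 1e-6)),
            delta_max=float(section.get("deltaMax", 1e6)),
            max_trials=int(section.get("maxTrials", 1000)),
        )
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid staircase section: {exc}") from exc


def _parse_standard(section: dict, needs_noise: bool):
    kwargs = {}
    mapping = {
        "frequencyHz": "frequency",
        "durationMs": "duration_ms",
        "levelDbfs": "level_dbfs",
        "rampMs": "ramp_ms",
        "seed": "seed",
    }
    for key, value in section.items():
        if key not in mapping:
            raise ConfigError(f"unknown field 'experiment.standard.{key}'")
        kwargs[mapping[key]] = value
    if needs_noise:
        kwargs.pop("frequency", None)
        return NoiseSpec(**kwargs)
    kwargs.pop("seed", None)
    return ToneSpec(**kwargs)


def parse_experiment(section: dict) -> ExperimentSpec:
    name = _require(section, "name", "experiment")
    overrides = {}
    try:
        base = builtin_experiment(name)
        if "standard" in section:
            overrides["standard"] = _parse_standard(
                section["standard"], base.needs_noise
            )
        for cfg_key, attr in [
            ("nAfc", "n_afc"),
            ("isiMs", "isi_ms"),
            ("itiMs", "iti_ms"),
            ("nBlocks", "n_blocks"),
            ("feedback", "feedback"),
            ("amModRateHz", "am_mod_rate_hz"),
            ("sampleRate", "sample_rate"),
        ]:
            if cfg_key in section:
                overrides[attr] = section[cfg_key]
        if "deltaBounds" in section:
            lo, hi = section["deltaBounds"]
            overrides["delta_bounds"] = (float(lo), float(hi))
        return builtin_experiment(name, **overrides)
    except ConfigError:
        raise
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid experiment section: {exc}") from exc


def parse_observer(section: dict, n_afc: int = 3) -> PsychometricObserver:
    try:
        gamma = 1.0 / n_afc if section.get("gammaAuto", True) else float(
            _require(section, "gamma", "observer")
        )
        return PsychometricObserver(
            alpha=float(_require(section, "alphaDelta", "observer")),
            beta=float(section.get("beta", 4.0)),
            gamma=gamma,
            lapse=float(section.get("lambda", 0.0)),
            seed=int(section.get("seed", 0)),
            model=section.get("model", "logistic"),
        )
    except ConfigError:
        raise
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid observer section: {exc}") from exc


def load_config(path) -> dict:
    """Load a session config file.

    Returns a dict with whichever of ``experiment`` (ExperimentSpec),
    ``staircase`` (StaircaseConfig) and ``observer`` (PsychometricObserver)
    sections the file defines.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    out: dict = {}
    if "experiment" in raw:
        out["experiment"] = parse_experiment(raw["experiment"])
    if "staircase" in raw:
        out["staircase"] = parse_staircase(raw["staircase"])
    if "observer" in raw:
        n_afc = out["experiment"].n_afc if "experiment" in out else 3
        out["observer"] = parse_observer(raw["observer"], n_afc=n_afc)
    if not out:
        raise ConfigError(
            "config defines none of the sections 'experiment', 'staircase', 'observer'"
        )
    return out
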