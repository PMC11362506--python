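"""Synthesize the default stimuli of each built-in experiment as WAV files.

For each experiment the standard and a clearly supra-threshold variable are
written side by side, so the manipulated parameter is audible by ear.
"""

from pathlib import Path

from audithresh import (
    BUILTIN_EXPERIMENTS,
    builtin_experiment,
    render_stimulus,
    standard_params,
    variable_from_delta,
    write_wav,
)

EASY_DELTAS = {
    "freq_disc_tone": 200.0,       # Hz
    "intensity_disc_tone": 10.0,   # dB
    "duration_disc_tone": 150.0,   # ms
    "duration_disc_noise": 150.0,  # ms
    "gap_detection_noise": 50.0,   # ms
    "am_detection_noise": 90.0,    # percent depth
}

out = Path("example_output/stimuli")
out.mkdir(parents=True, exist_ok=True)
for name in BUILTIN_EXPERIMENTS:
    spec = builtin_experiment(name)
    from dataclasses import replace

    std = replace(standard_params(spec), noise_seed=0)
    var = replace(variable_from_delta(spec, EASY_DELTAS[name]), noise_seed=1)
    write_wav(render_stimulus(std, spec.sample_rate), out / f"{name}_standard.wav")
    write_wav(render_stimulus(var, spec.sample_rate), out / f"{name}_variable.wav")
    print(f"{name}: standard + variable (delta {EASY_DELTAS[name]} {spec.delta_units.value})")
print(f"WAV files in {out}/ — levels are dB FS (relative), 48 kHz, 16-bit mono.")
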