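# audithresh

Adaptive estimation of auditory sensory thresholds with transformed up-down
(Levitt) staircases.

Psychoacousticians measure how small a stimulus difference a listener can
detect — a frequency difference between two tones, a level or duration
difference, a silent gap in noise, or sinusoidal amplitude modulation — by
presenting forced-choice trials whose difficulty adapts to the listener's
responses. This package implements the computational core of that workflow
for six classic experiments, for people who want to run, simulate or analyse
such experiments from Python (or a shell) without any audio-hardware or GUI
layer:

* **staircase engine** — n-down/one-up rules with multiplicative step
  factors, reversal bookkeeping, and reversal-based threshold estimates;
* **stimulus synthesis** — pure tones and Gaussian noise at dB FS levels,
  raised-cosine gating, temporal gaps, amplitude modulation, WAV export;
* **experiments** — the six built-in tasks, delta-to-parameter mapping and
  mI-nAFC trial assembly;
* **simulated observers** — parametric psychometric functions for
  closed-loop validation without human listeners;
* **session I/O** — familiarisation, blocks, sessions, and the reduced /
  extended CSV datafiles, with exact replay from the extended log.

## The model

On each trial of an mI-nAFC task, `n` intervals are presented: `n − 1`
standards and one variable differing by Δ in a single physical parameter.
Under the *n-down/one-up* rule, `n_down` consecutive correct responses
divide Δ by the step factor in force (typically 2 early, √2 late), and one
error multiplies it. A change of step direction is a *reversal*; the
threshold is the mean of the last *k* reversal deltas. The rule converges
where a down step is as likely as an up step,

    P(down) = p^n_down = 1/2    ⇒    p = 2^(−1/n_down),

i.e. the stimulus level answered correctly 70.7% of the time for the
two-down/one-up rule and 79.4% for the three-down/one-up rule — above the
guessing floor 1/n of the forced-choice task, so the estimate does not mix
sensitivity with task chance.

Simulated listeners follow Ψ(Δ) = γ + (1 − γ − λ)·F(Δ) with F logistic in
ln Δ (location α, slope β), guess floor γ = 1/n and lapse rate λ.

## Worked example

```python
from audithresh import (PsychometricObserver, builtin_experiment,
                        lab_staircase, run_session)

spec = builtin_experiment("freq_disc_tone", n_blocks=3)   # 3I-3AFC, 1-kHz standard
observer = PsychometricObserver(alpha=10.0, beta=4.0, gamma=1/3, seed=0)
session = run_session(spec, lab_staircase(), observer, seed=0)
for b in session.blocks:
    print(f"block {b.block_index}: threshold {b.threshold.value:.2f} Hz "
          f"({b.n_trials} trials, {len(b.reversal_deltas)} reversals)")
print(f"session threshold: {session.threshold:.2f} Hz")
```

prints

```
block 1: threshold 12.14 Hz (27 trials, 8 reversals)
block 2: threshold 10.67 Hz (24 trials, 8 reversals)
block 3: threshold 13.62 Hz (28 trials, 8 reversals)
session threshold: 12.14 Hz
```

(the `examples/simulate_session.py` output). Each block threshold is the
frequency difference this simulated listener tracks at 70.7% correct — for
an observer with α = 10 Hz and β = 4 that point lies at ≈ 10.6 Hz, and the
block estimates scatter around it; the session threshold averages the
blocks. `examples/` contains one short script per capability (staircase
walkthrough, convergence check, stimulus synthesis, session simulation, log
replay).

The same session can be run from a shell:

```bash
audithresh simulate --config config.yaml --replicates 10 --seed 1
audithresh convergence --rule 2d1u
audithresh run --config config.yaml --mode interactive
audithresh make-stimuli --out stimuli/
```

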