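# Methods

## The adaptive procedure

The engine implements the transformed up-down family in its common
multiplicative form. Responses are grouped: `n_down` consecutive correct
responses complete a *down* group and divide the delta by the step factor in
force; a single error completes an *up* group and multiplies it. The rule's
equilibrium is where `P(down) = p**n_down = 1/2`, so an n-down/one-up track
converges on the stimulus level answered correctly with probability
`2**(-1/n_down)`: 70.7% (n=2), 79.4% (n=3), 84.1% (n=4).
`equilibrium_probability` computes this closed form; the
convergence simulations below verify the closed loop lands there.

Step factors are organised in phases keyed to the reversal count — by
default 4 reversals at factor 2 (fast approach) then 8 at √2 (fine
tracking). The phase advances the moment its boundary reversal is recorded:
the step following the 4th reversal already uses the small factor. This
reading treats the phase counts as step-size eras delimited by reversals,
which keeps the factor a pure function of the reversal ledger.

Semantics fixed where common practice varies:

* **First step** — the initial direction is "none": the first descent (or
  ascent) from the deliberately easy start delta records no reversal.
* **Reversal value** — the delta *presented on the trial that triggers the
  direction change* (the pre-step delta), i.e. the extreme of the excursion.
* **Termination** — the track finishes the instant the final configured
  reversal is recorded; the terminal step is not applied. A `max_trials`
  safety cap (default 1000) finishes a pathological track; its threshold is
  then computed on the reversals available and flagged `complete=False`
  rather than discarded.
* **Bounds** — delta is clamped (never rejected) at `delta_min`/`delta_max`;
  a clamped step still counts for direction/grouping (so a zero-sensitivity
  responder parks at `delta_max`, and a direction change at the bound is
  still a reversal). Clamping events are logged on the track state. Whether
  a deployed tool should count clamped steps as direction changes is
  genuinely open; counting them is the self-consistent choice given that the
  step logic is otherwise independent of the clamp.

## Threshold estimation

Two reversal-based estimators are provided: the mean of the last *k*
reversal deltas (default; *k* configurable, even values recommended — odd
*k* warns but is allowed) and the mean of midpoints of runs (consecutive
reversal pairs). Both offer arithmetic and geometric averaging.

The *reporting* default is the arithmetic mean of raw deltas, matching
everyday lab practice. The *convergence harness* (the `convergence` CLI
command, `scripts/acceptance.py`, and the convergence tests) averages
geometrically. The distinction is deliberate: multiplicative steps make the
reversal deltas log-symmetric about the equilibrium, so the geometric mean
(the log-domain average, which is also how log-thresholds are analysed
downstream) is the estimator that is unbiased for the tracked point, while
the arithmetic mean is biased upward by roughly half the log-scale variance
of the reversals. Under the harness conditions below the difference is about
3.5 percentage points of tracked performance (74.1% vs 70.2% for the
two-down/one-up rule); a harness asking "what level does the rule track?"
must therefore measure on the log axis.

## Experiments and trial assembly

Six built-in tasks: frequency, intensity and duration discrimination of
pure tones; duration discrimination of noise; gap detection in noise; AM
detection with a noise carrier. Defaults are a 250-ms, 1-kHz, −20 dB FS
standard tone with 10-ms raised-cosine ramps (noise: 500 ms for gap/AM,
−20 dB FS), 3I-3AFC presentation, 500-ms ISI and ITI, one block. The
variable is always the "greater" stimulus (higher frequency/level/longer;
gap or modulation present); there is no roving of the standard. Intensity
increments clamp at 0 dB FS with a warning, since digital full scale cannot
be exceeded. Duration increments lengthen the plateau and preserve the
ramps.

Trials place the variable at a uniformly random interval; forced-choice
scoring is `response == target`. Noise-based experiments draw an
independent noise seed per interval from the trial RNG — each interval is a
fresh token, so listeners (simulated or real) cannot exploit a repeated
sample pattern; "same noise" in the task definitions is read as same
*parameters*.

## Stimuli

dB FS is peak-referenced for tones (0 dB FS = peak 1.0) and RMS-referenced
to a full-scale sine for noise (RMS = 10^(dBFS/20)/√2), so equal nominal
levels carry equal power. Levels are purely relative; absolute SPL
calibration is explicitly out of scope. Default sample rate 48 kHz; 44.1 kHz
supported; synthesis at or above Nyquist raises. Gaps are abrupt (no edge
ramps) and centred — gap placement and gating are not standardised across
tools, and the abrupt centred gap is the simplest defensible choice, kept
configurable in structure (`position` argument). The AM modulator is a
20-Hz zero-phase sinusoid by default (a common modulation rate for broadband
AM detection; the rate is a required-with-default config field), and the
modulated waveform is divided by (1+m) so full-depth modulation cannot clip;
an option disables the compensation. Noise is Gaussian white. WAV export is
16-bit PCM mono and refuses out-of-range samples instead of clipping them.

## Simulated observers

`PsychometricObserver` uses Ψ(Δ) = γ + (1−γ−λ)·F(Δ) with F logistic in
ln Δ by default — the log axis matches the staircase's multiplicative
geometry — with a Weibull alternative. γ defaults to 1/n_afc; λ defaults to
0 (the validation harness assumes attentive listeners; a small λ is
available for robustness studies). Incorrect responses choose uniformly
among the non-target intervals; interval bias is out of scope. A
zero-sensitivity observer (α = ∞, Ψ ≡ γ) models pure guessing and is used
to verify the 2AFC/3AFC floors.

`tracked_performance` runs replicate closed-loop tracks, maps each
replicate's threshold back through the observer's noise-free Ψ, and averages
— the empirical tracked level to compare with the analytic equilibrium.

## Sessions and datafiles

A session runs familiarisation (optional) and `n_blocks` blocks;
the session threshold is the arithmetic mean of the complete block
thresholds (incomplete blocks are flagged and excluded, with a warning).
Familiarisation presents easy fixed deltas (default: the start delta and
half of it, generalising the frequency-task convention of 100 and 50 Hz)
until 6 consecutive correct responses, failing at a 30-trial cap.

The reduced CSV holds demographics plus one threshold row per block. The
extended CSV holds one row per trial with the classic columns (nAFC, ISI,
ITI, Reversal threshold, Algorithm, Delta, Correct, Reversals) plus the
standard-stimulus parameters, staircase settings, per-trial
factor/target/response, a nominal timestamp, and the block seeds. Exact
column order is fixed by `EXTENDED_COLUMNS`. Demographics may be empty
(anonymous deployments); decimals use "." with no thousands separators.
Because the seeds and settings are stored, `replay_extended_csv` rebuilds
the session and reproduces the file byte-for-byte — the extended log is a
sufficient statistic for the block. ITI is recorded but not slept in
simulation; timestamps are a deterministic nominal clock accumulated from
stimulus durations, ISI and ITI.

Replay reconstructs the experiment from the file's metadata columns and the
built-in experiment's delta bounds; custom physical bounds narrower than the
staircase bounds are the one setting not carried in the file.

## Validation harness and problem sizes

Convergence runs use the frequency-discrimination task (3I-3AFC), a
logistic observer with α = 10 Hz, β = 4, γ = 1/3, λ = 0, start delta
100 Hz, 4+8 reversals with factors 2/√2, threshold from the last 8
reversals averaged geometrically, and 500 replicate tracks (≈ 40–55 trials
each) — enough for a Monte-Carlo standard error of the tracked level of
about 0.2 percentage points. The guessing-floor checks use 10,000 seeded
trials (binomial 99% CI half-width ≈ 1.3 points at p = 1/3). The
short-staircase check (6 reversals: 2 at factor 2, 4 at √2, threshold on the
last 4) uses 2,000 replicates per observer α ∈ {5, 10, 20}. All seeds derive
from a single master seed via `numpy.random.SeedSequence`.

## What the synthetic validation does and does not show

The simulated observer is stationary, unbiased across intervals, and (by
default) lapse-free; real listeners drift, favour intervals, lapse, and
learn. Passing convergence and recovery tests therefore shows the
*procedure* is implemented correctly and is unbiased under its own
assumptions — not that any particular human threshold is accurate.
Human-facing concerns (audio hardware, absolute calibration, headphone
screening, response timing) are explicitly outside this package.

## Known limitations

* Only multiplicative steps; additive (fixed linear step) staircases and
  parametric procedures (PEST, QUEST, maximum likelihood) are not
  implemented.
* No psychometric-function fitting on logs — the extended CSV is designed
  so external fitting tools can consume it.
* The staircase assumes the variable is detectable at the start delta;
  pathological configurations end via `max_trials` with `complete=False`.
* Interval-bias and roving-standard designs are not modelled.
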