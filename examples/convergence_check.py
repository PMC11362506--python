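"""Verify by simulation which performance level each staircase rule tracks.

An n-down/one-up rule is in equilibrium where p**n = 1/2; simulation with a
known observer should land on that level (70.7% for n=2, 79.4% for n=3).
"""

from audithresh import (
    MeanType,
    PsychometricObserver,
    builtin_experiment,
    equilibrium_probability,
    standard_staircase,
    tracked_performance,
)

spec = builtin_experiment("freq_disc_tone")
observer = PsychometricObserver(alpha=10.0, beta=4.0, gamma=1 / spec.n_afc)

for n_down in (2, 3):
    config = standard_staircase(n_down=n_down, mean_type=MeanType.GEOMETRIC)
    summary = tracked_performance(config, spec, observer, n_replicates=500, seed=1)
    print(
        f"{config.rule_name}: analytic {100 * equilibrium_probability(n_down):.1f}%  "
        f"simulated {100 * summary.mean_tracked_p:.1f}%  "
        f"(mean {summary.n_trials.mean():.0f} trials/track)"
    )
# The simulated column is the observer's true probability of answering
# correctly at the staircase's threshold estimate, averaged over 500 tracks;
# it should match the analytic equilibrium to within Monte-Carlo error.
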