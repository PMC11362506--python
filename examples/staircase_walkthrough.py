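"""Walk a hand-written response string through a two-down/one-up staircase.

Two consecutive correct answers ('+') divide the delta by the factor in
force; one error ('-') multiplies it.  A change of step direction is a
reversal, and the threshold is the mean of the last reversal deltas.
"""

from audithresh import StaircaseConfig, new_track, threshold_last_k, update_track

config = StaircaseConfig(
    n_down=2, phases=((2, 2.0), (4, 2**0.5)), start_delta=100.0,
    reversal_threshold_k=4,
)
responses = "++++-++-++-++-+++-"

track = new_track(config)
print(f"trial  response  delta (Hz)  reversals")
for symbol in responses:
    if track.finished:
        break
    delta_before = track.delta
    update_track(track, config, symbol == "+")
    print(f"{track.trial_count:>5}  {symbol:>8}  {delta_before:>10.2f}  {len(track.reversals):>9}")

estimate = threshold_last_k(track.reversal_deltas, config.reversal_threshold_k)
print(f"\nreversal deltas: {[round(d, 2) for d in track.reversal_deltas]}")
print(f"threshold (mean of last {estimate.n_reversals_used} reversals): {estimate.value:.2f} Hz")
# The printed threshold is the frequency difference this simulated listener
# could just discriminate — the delta tracked at ~70.7% correct.
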