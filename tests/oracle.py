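"""Independent brute-force enumerator of the n-down/one-up state machine.

Re-derives, from a raw response string, the step sequence, reversal ledger
and final delta by direct enumeration — no shared code with the staircase
engine.  Used as the oracle the engine is checked against.
"""

from __future__ import annotations


def enumerate_track(
    responses: str,
    n_down: int,
    phases: tuple[tuple[int, float], ...],
    start_delta: float,
    delta_min: float = 1e-12,
    delta_max: float = 1e12,
):
    """Walk a '+'/'-' response string through the n-down/one-up rules.

    Returns (reversals, final_delta, trials_consumed) where reversals is a
    list of (1-based trial index, delta presented on that trial).  Stops —
    without applying the terminal step — once the configured total number of
    reversals has been recorded.
    """
    total = sum(c for c, _ in phases)

    def factor_for(reversal_number: int) -> float:
        cum = 0
        for count, factor in phases:
            cum += count
            if reversal_number <= cum:
                return factor
        return phases[-1][1]

    delta = start_delta
    streak = 0
    last_dir = None  # 'up' | 'down' | None
    reversals: list[tuple[int, float]] = []
    for trial, symbol in enumerate(responses, start=1):
        direction = None
        if symbol == "+":
            streak += 1
            if streak == n_down:
                direction = "down"
                streak = 0
        elif symbol == "-":
            direction = "up"
            streak = 0
        else:
            raise ValueError(f"bad symbol {symbol!r}")
        if direction is None:
            continue
        if last_dir is not None and direction != last_dir:
            reversals.append((trial, delta))
            if len(reversals) == total:
                return reversals, delta, trial
        factor = factor_for(len(reversals) + 1)
        delta = delta / factor if direction == "down" else delta * factor
        delta = min(max(delta, delta_min), delta_max)
        last_dir = direction
    return reversals, delta, len(responses)
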