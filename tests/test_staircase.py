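"""Unit and property tests for the transformed up-down engine."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from audithresh.staircase import (
    Direction,
    InsufficientDataError,
    MeanType,
    StaircaseConfig,
    StaircaseUsageError,
    compute_threshold,
    current_factor,
    equilibrium_probability,
    new_track,
    threshold_last_k,
    threshold_midpoint_runs,
    update_track,
)

from oracle import enumerate_track

SQRT2 = math.sqrt(2.0)


def drive(config, responses):
    """Feed a '+'/'-' string through the engine; returns the track."""
    track = new_track(config)
    for symbol in responses:
        if track.finished:
            break
        update_track(track, config, symbol == "+")
    return track


def single_phase(factor=2.0, n=6, **kw):
    defaults = dict(
        n_down=2, phases=((n, factor),), start_delta=100.0, reversal_threshold_k=4
    )
    defaults.update(kw)
    return StaircaseConfig(**defaults)


class TestUpdateTrack:
    def test_two_consecutive_correct_divide_delta(self):
        track = drive(single_phase(), "++")
        assert track.delta == 50.0
        assert track.reversals == []  # first step: no prior direction

    def test_hand_traced_reversal_ledger(self):
        # ++ ++ - ++  ->  100 -> 50 -> 25 -> (rev) 50 -> (rev) 25
        track = drive(single_phase(), "++++-++")
        assert track.delta == 25.0
        assert track.reversals == [(5, 25.0), (7, 50.0)]

    def test_alternating_responses_are_up_steps_not_reversals(self):
        # "+-+-+-": each '-' closes an up group; no down step ever completes
        track = drive(single_phase(), "+-+-+-")
        assert track.reversals == []
        assert track.delta == 800.0  # 100 * 2**3
        assert track.last_direction is Direction.UP

    def test_finished_track_rejects_updates(self):
        config = single_phase(n=2, reversal_threshold_k=2)
        track = drive(config, "++++-++" + "-" * 10)
        assert track.finished
        with pytest.raises(StaircaseUsageError):
            update_track(track, config, True)

    def test_terminal_reversal_applies_no_step(self):
        config = single_phase(n=2, reversal_threshold_k=2)
        track = drive(config, "++++-++")
        # second reversal at trial 7 (delta 50) finishes the track; the down
        # step that triggered it is not applied
        assert track.finished
        assert track.reversals == [(5, 25.0), (7, 50.0)]
        assert track.delta == 50.0

    def test_max_trials_cap_finishes_track(self):
        config = single_phase(max_trials=5)
        track = drive(config, "+" * 50)
        assert track.finished and track.trial_count == 5

    def test_clamping_at_delta_max(self):
        config = single_phase(delta_max=200.0)
        track = drive(config, "---")
        assert track.delta == 200.0
        assert track.clamp_events  # the clamped steps were logged

    def test_three_down_one_up_grouping(self):
        config = single_phase(n_down=3)
        track = drive(config, "++")
        assert track.delta == 100.0  # two correct: no group completed yet
        track = drive(config, "+++")
        assert track.delta == 50.0


class TestCurrentFactor:
    @pytest.mark.parametrize(
        "n_reversals, expected",
        [(0, 2.0), (3, 2.0), (4, SQRT2), (11, SQRT2)],
    )
    def test_two_phase_schedule(self, n_reversals, expected):
        config = StaircaseConfig(phases=((4, 2.0), (8, SQRT2)))
        track = new_track(config)
        track.reversals.extend((i + 1, 10.0) for i in range(n_reversals))
        assert current_factor(track, config) == pytest.approx(expected)

    def test_single_phase_always_same(self):
        config = single_phase(n=6)
        track = new_track(config)
        track.reversals.extend((i + 1, 10.0) for i in range(5))
        assert current_factor(track, config) == 2.0

    def test_phase_advances_on_boundary_reversal(self):
        # "-++-++-": reversals at trials 3, 4, 6 and 7; the step recording
        # the 4th (phase-boundary) reversal already multiplies by sqrt(2)
        config = StaircaseConfig(
            phases=((4, 2.0), (4, SQRT2)), start_delta=100.0, reversal_threshold_k=4
        )
        track = drive(config, "-++-++-")
        assert len(track.reversals) == 4
        assert track.delta == pytest.approx(100.0 * SQRT2)


class TestThresholds:
    def test_last_k_arithmetic_symmetric_alternation(self):
        est = threshold_last_k([40, 20, 40, 20, 40, 20, 40, 20], k=8)
        assert est.value == pytest.approx(30.0)
        assert est.method == "last_k_mean" and est.n_reversals_used == 8

    def test_last_k_geometric(self):
        est = threshold_last_k([10, 40, 10, 40], k=4, mean_type=MeanType.GEOMETRIC)
        assert est.value == pytest.approx(20.0)

    def test_last_k_takes_the_tail(self):
        revs = [100, 50, 25, 40, 20, 40, 20, 40, 20, 40, 20, 40]
        est = threshold_last_k(revs, k=6)
        assert est.value == pytest.approx(sum(revs[-6:]) / 6) == pytest.approx(30.0)

    def test_last_k_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            threshold_last_k([10, 20], k=4)

    def test_last_k_odd_warns(self):
        with pytest.warns(UserWarning, match="even number"):
            threshold_last_k([10, 20, 30], k=3)

    @pytest.mark.parametrize(
        "revs, n_used, expected",
        [
            ([20, 40, 20, 40], 4, 30.0),
            ([10, 30], 2, 20.0),
            ([16, 32, 8, 24], 4, 20.0),  # midpoints [24, 20, 16]
        ],
    )
    def test_midpoint_of_runs(self, revs, n_used, expected):
        est = threshold_midpoint_runs(revs, n_used)
        assert est.value == pytest.approx(expected)
        assert est.method == "midpoint_of_runs"

    def test_midpoint_rejects_odd_n(self):
        with pytest.raises(ValueError, match="even"):
            threshold_midpoint_runs([10, 20, 30], 3)

    def test_value_within_range_of_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            revs = list(rng.uniform(1, 100, size=8))
            for est in (
                threshold_last_k(revs, 6),
                threshold_last_k(revs, 6, MeanType.GEOMETRIC),
                threshold_midpoint_runs(revs, 6),
            ):
                assert min(revs) <= est.value <= max(revs)

    def test_truncated_track_threshold_incomplete(self):
        config = single_phase(n=6, reversal_threshold_k=4, max_trials=8)
        track = drive(config, "++++-++-")
        assert track.finished and len(track.reversals) < 6
        with pytest.warns(UserWarning, match="truncated"):
            est = compute_threshold(track, config)
        assert not est.complete
        assert est.n_reversals_used == len(track.reversals)


class TestEquilibrium:
    @pytest.mark.parametrize(
        "n_down, expected",
        [(1, 0.5), (2, 0.7071), (3, 0.7937), (4, 0.8409)],
    )
    def test_printed_values(self, n_down, expected):
        assert equilibrium_probability(n_down) == pytest.approx(expected, abs=5e-5)

    def test_solves_equilibrium_condition(self):
        for n in range(1, 7):
            p = equilibrium_probability(n)
            assert abs(p**n - 0.5) < 1e-12

    def test_invalid_rule(self):
        with pytest.raises(ValueError):
            equilibrium_probability(0)


class TestConfigValidation:
    def test_factor_must_exceed_one(self):
        with pytest.raises(ValueError, match="factor"):
            StaircaseConfig(phases=((4, 1.0),), reversal_threshold_k=2)

    def test_threshold_k_cannot_exceed_total_reversals(self):
        with pytest.raises(ValueError, match="reversal_threshold_k"):
            StaircaseConfig(phases=((4, 2.0),), reversal_threshold_k=6)

    def test_start_delta_within_bounds(self):
        with pytest.raises(ValueError, match="start_delta"):
            StaircaseConfig(start_delta=0.5, delta_min=1.0, delta_max=10.0)

    def test_odd_k_warns_but_is_allowed(self):
        with pytest.warns(UserWarning, match="even"):
            config = StaircaseConfig(phases=((6, 2.0),), reversal_threshold_k=5)
        assert config.reversal_threshold_k == 5


# --- properties ------------------------------------------------------------


@st.composite
def response_strings(draw):
    return draw(st.text(alphabet="+-", min_size=1, max_size=60))


@given(responses=response_strings(), n_down=st.integers(1, 3))
@settings(max_examples=300, derandomize=True, deadline=None)
def test_engine_matches_brute_force_oracle(responses, n_down):
    """Reversal ledger and final delta agree with an independent enumerator."""
    phases = ((2, 2.0), (4, SQRT2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        config = StaircaseConfig(
            n_down=n_down,
            phases=phases,
            start_delta=100.0,
            reversal_threshold_k=4,
            delta_min=1e-12,
            delta_max=1e12,
            max_trials=10_000,
        )
    track = drive(config, responses)
    expected_revs, expected_delta, _ = enumerate_track(
        responses, n_down, phases, 100.0, 1e-12, 1e12
    )
    assert track.reversals == expected_revs
    assert track.delta == pytest.approx(expected_delta, rel=1e-12)


@given(responses=response_strings())
@settings(max_examples=200, derandomize=True, deadline=None)
def test_consecutive_deltas_differ_by_factor_in_force(responses):
    """Every unclamped step changes delta by exactly the phase factor."""
    config = StaircaseConfig(
        phases=((2, 2.0), (4, SQRT2)),
        start_delta=100.0,
        reversal_threshold_k=4,
        delta_min=1e-12,
        delta_max=1e12,
    )
    track = new_track(config)
    deltas = [track.delta]
    for symbol in responses:
        if track.finished:
            break
        update_track(track, config, symbol == "+")
        deltas.append(track.delta)
    for before, after in zip(deltas, deltas[1:]):
        if before == after:
            continue  # no step on this trial
        ratio = max(before, after) / min(before, after)
        assert ratio == pytest.approx(2.0, rel=1e-9) or ratio == pytest.approx(
            SQRT2, rel=1e-9
        )


@given(
    revs=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=16),
    k=st.integers(2, 16),
)
@settings(max_examples=200, derandomize=True, deadline=None)
def test_geometric_mean_never_exceeds_arithmetic(revs, k):
    if k > len(revs) or k % 2:
        k = 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        am = threshold_last_k(revs, k, MeanType.ARITHMETIC).value
        gm = threshold_last_k(revs, k, MeanType.GEOMETRIC).value
    assert gm <= am * (1 + 1e-12)


def test_zero_sensitivity_pins_delta_at_ceiling():
    """All-wrong responding drives delta to delta_max and keeps it there."""
    config = single_phase(delta_max=400.0, max_trials=30)
    track = new_track(config)
    for _ in range(30):
        if track.finished:
            break
        update_track(track, config, False)
        assert track.delta <= 400.0
    assert track.delta == 400.0
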