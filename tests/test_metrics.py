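"""Reward mapping and behavioural variability measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rewardtap.metrics import (
    Block,
    InsufficientDataError,
    Trial,
    block_variability,
    exploration_after_outcome,
    exploration_series,
    iki_difference_norm,
    reward_score,
    within_trial_cv,
)

PRINTED_PATTERN = [0.2, 1, 0.2, 1, 0.2, 1, 0.2]

positive_ikis = st.lists(
    st.floats(min_value=0.01, max_value=5.0, allow_nan=False),
    min_size=2, max_size=12,
)


class TestDifferenceNorm:
    @pytest.mark.parametrize(
        "iki, expected",
        [
            (PRINTED_PATTERN, 0.8 * math.sqrt(6)),   # the task's target pattern
            ([0.5] * 7, 0.0),                        # isochronous
            ([0.1, 0.4, 0.3], math.sqrt(0.10)),
        ],
    )
    def test_known_values(self, iki, expected):
        assert iki_difference_norm(iki) == pytest.approx(expected, abs=1e-12)

    def test_matches_printed_target(self):
        """The task's winning pattern has the printed difference norm."""
        assert round(iki_difference_norm(PRINTED_PATTERN), 4) == 1.9596

    @settings(deadline=None, derandomize=True)
    @given(positive_ikis)
    def test_reversal_invariant_and_nonnegative(self, iki):
        norm = iki_difference_norm(iki)
        assert norm >= 0
        assert iki_difference_norm(iki[::-1]) == pytest.approx(norm, rel=1e-12)

    @pytest.mark.parametrize("bad", [[0.5], [0.2, -0.1, 0.3], [0.2, 0.0, 0.3]])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            iki_difference_norm(bad)


class TestRewardScore:
    def test_perfect_match_scores_100(self):
        assert reward_score(1.9596, 1.9596) == 100.0
        assert reward_score(0.0, 0.0) == 100.0

    def test_unit_mismatch(self):
        assert reward_score(2.9596, 1.9596) == pytest.approx(
            100 * math.exp(-1), abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0, 10), st.floats(0, 10))
    def test_bounded_and_positive(self, a, b):
        s = reward_score(a, b)
        assert 0 < s <= 100

    def test_monotone_decay(self):
        mismatches = np.linspace(0, 8, 30)
        scores = [reward_score(1.9596 + d, 1.9596) for d in mismatches]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_many_to_one_mapping(self):
        """Distinct timing patterns with equal difference norm score equally."""
        a = [0.2, 1, 0.2, 1, 0.2, 1, 0.2]
        b = [1, 0.2, 1, 0.2, 1, 0.2, 1]       # different pattern, same |Δz|
        assert iki_difference_norm(a) == pytest.approx(iki_difference_norm(b))
        assert reward_score(iki_difference_norm(a)) == pytest.approx(
            reward_score(iki_difference_norm(b)))

    def test_negative_norm_rejected(self):
        with pytest.raises(ValueError):
            reward_score(-0.1, 1.9596)


class TestWithinTrialCV:
    def test_isochronous_zero(self):
        assert within_trial_cv([0.5] * 7) == 0.0

    def test_hand_value(self):
        # population sd 0.15 over mean 0.45
        assert within_trial_cv([0.3, 0.6]) == pytest.approx(0.15 / 0.45, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(positive_ikis, st.floats(min_value=0.1, max_value=10))
    def test_tempo_scale_invariance(self, iki, scale):
        base = within_trial_cv(iki)
        scaled = within_trial_cv([scale * z for z in iki])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)

    def test_too_short(self):
        with pytest.raises(ValueError):
            within_trial_cv([0.5])


class TestBlockVariability:
    def _block(self, mat, errors=None):
        errors = errors or [False] * len(mat)
        trials = [Trial(iki=row, is_error=e) for row, e in zip(mat, errors)]
        return Block(phase="baseline", trials=trials)

    def test_identical_trials_zero(self):
        assert block_variability(self._block([[0.5, 0.5]] * 4)) == 0.0

    def test_hand_value(self):
        # per-position population cv = 0.1/0.5 = 0.2 at both positions
        blk = self._block([[0.4, 0.4], [0.6, 0.6]])
        assert block_variability(blk) == pytest.approx(0.2, abs=1e-12)

    def test_tempo_scale_invariance(self):
        mat = [[0.4, 0.5], [0.6, 0.45], [0.55, 0.62]]
        doubled = [[2 * v for v in row] for row in mat]
        assert block_variability(self._block(doubled)) == pytest.approx(
            block_variability(self._block(mat)))

    def test_error_trials_excluded_but_counted(self):
        blk = self._block(
            [[0.4, 0.4], [0.6, 0.6], [9.0, 9.0]], errors=[False, False, True])
        assert block_variability(blk) == pytest.approx(0.2, abs=1e-12)
        assert blk.error_rate() == pytest.approx(1 / 3)

    def test_insufficient_trials(self):
        blk = self._block([[0.4, 0.4], [0.6, 0.6]], errors=[False, True])
        with pytest.raises(InsufficientDataError):
            block_variability(blk)

    def test_velocity_dimension(self):
        trials = [Trial(iki=[0.5, 0.5], velocity=[60, 60]),
                  Trial(iki=[0.5, 0.5], velocity=[80, 80])]
        blk = Block(phase="baseline", trials=trials)
        assert block_variability(blk, "velocity") == pytest.approx(10 / 70)


class TestExplorationSeries:
    def test_constant_series_floored(self):
        y = exploration_series(np.full(5, 0.2), eps=1e-6)
        assert np.allclose(y, math.log(1e-6))
        assert y.size == 4

    def test_hand_value(self):
        y = exploration_series(np.array([0.10, 0.30]))
        assert y[0] == pytest.approx(math.log(0.20), abs=1e-12)

    def test_reversal_symmetry(self):
        cv = np.array([0.1, 0.25, 0.17, 0.4])
        fwd = exploration_series(cv)
        rev = exploration_series(cv[::-1])
        assert np.allclose(fwd, rev[::-1])

    def test_accepts_trials(self):
        trials = [Trial(iki=[0.3, 0.6]), Trial(iki=[0.5, 0.5])]
        y = exploration_series(trials)
        assert y.size == 1
        assert y[0] == pytest.approx(math.log(0.15 / 0.45), abs=1e-9)


class TestExplorationAfterOutcome:
    def test_constant_exploration(self):
        drop, rise = exploration_after_outcome([10, 90, 10, 90], [2.0, 2.0, 2.0])
        assert drop == rise == 2.0

    def test_hand_partition(self):
        # changes preceding Y^3..Y^5: +40 (rise), -30 (drop), +40 (rise)
        u = [10, 50, 20, 60, 30]
        y = [99.0, -3.0, -1.0, -3.0]   # first entry has no preceding change
        assert exploration_after_outcome(u, y) == (-1.0, -3.0)

    def test_requires_both_outcomes(self):
        with pytest.raises(InsufficientDataError):
            exploration_after_outcome([10, 20, 30, 40], [0.0, 0.0, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            exploration_after_outcome([10, 20, 30], [0.0, 0.0, 0.0])


class TestDomainTypes:
    def test_trial_rejects_nonpositive_iki(self):
        with pytest.raises(ValueError):
            Trial(iki=[0.5, 0.0, 0.5])

    def test_trial_velocity_length_check(self):
        with pytest.raises(ValueError):
            Trial(iki=[0.5, 0.5], velocity=[60] * 7)

    def test_baseline_block_rejects_scores(self):
        with pytest.raises(ValueError):
            Block(phase="baseline", trials=[Trial(iki=[0.5, 0.5])],
                  scores=np.array([50.0]))

    def test_score_series_bounds(self):
        from rewardtap.metrics import ScoreSeries
        with pytest.raises(ValueError):
            ScoreSeries(np.array([50.0, 101.0]))
        with pytest.raises(ValueError):
            ScoreSeries(np.array([-0.5, 10.0]))
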