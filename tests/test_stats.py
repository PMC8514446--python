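"""Non-parametric group statistics: permutation tests, FDR, effect sizes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rewardtap.stats import (
    adaptive_fdr,
    bootstrap_ci_delta,
    delta_dep,
    paired_perm_test,
    perm_factorial_rm,
    perm_oneway_rm,
)


def fdr_oracle(pvals, q):
    """Independent straight transcription of the two-stage step-up procedure.

    Stage 1: linear step-up at q' = q/(1+q); its rejection count estimates
    the number of true nulls m0 = m - r1.  Stage 2: linear step-up at
    q' * m / m0.  Returns the boolean rejection vector.
    """
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    ps = p[order]

    def step_up(level):
        k = 0
        for i in range(m):
            if ps[i] <= level * (i + 1) / m + 1e-12:
                k = i + 1
        return k

    q1 = q / (1 + q)
    r1 = step_up(q1)
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    r2 = step_up(q1 * m / (m - r1))
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:r2]] = True
    return rejected


class TestOnewayRM:
    def test_degenerate_null(self):
        data = np.tile([[1.0, 1.0, 1.0]], (5, 1))
        res = perm_oneway_rm(data)
        assert res.observed_stat == 0.0
        assert res.p == 1.0
        assert res.exhaustive

    def test_monte_carlo_matches_exhaustive(self, rng):
        data = rng.normal(0, 1, (4, 2))
        data[:, 1] += 0.8
        exact = perm_oneway_rm(data)            # (2!)^4 = 16 arrangements
        assert exact.exhaustive and exact.n_perm == 16
        mc = perm_oneway_rm(data, n_perm=20_000, seed=0, exhaustive_cap=1)
        assert not mc.exhaustive
        assert abs(mc.p - exact.p) < 0.01

    def test_exhaustive_is_seed_free(self, rng):
        data = rng.normal(0, 1, (4, 3))
        a = perm_oneway_rm(data, seed=1)
        b = perm_oneway_rm(data, seed=999)
        assert a.exhaustive and a.p == b.p

    def test_detects_strong_effect(self, rng):
        data = rng.normal(0, 0.1, (10, 3))
        data[:, 0] += 2.0
        res = perm_oneway_rm(data, n_perm=999, seed=0)
        assert res.p <= 0.01

    def test_requires_complete_crossing(self):
        data = np.ones((4, 3))
        data[2, 1] = np.nan
        with pytest.raises(ValueError):
            perm_oneway_rm(data)
        with pytest.raises(ValueError):
            perm_oneway_rm(np.ones((1, 3)))


class TestFactorialRM:
    def test_constant_data_all_p_one(self):
        data = np.ones((5, 3, 3))
        res = perm_factorial_rm(data, n_perm=200, seed=0)
        assert res.factor_a.p == 1.0
        assert res.factor_b.p == 1.0
        assert res.interaction.p == 1.0

    def test_pure_block_effect(self, rng):
        data = rng.normal(0, 0.3, (12, 3, 3))
        data += np.array([0.0, 1.0, 2.0])[None, :, None]   # factor-A shift
        res = perm_factorial_rm(data, n_perm=999, seed=0)
        assert res.factor_a.p <= 0.01
        assert res.factor_b.p > 0.05

    def test_interaction_detected(self, rng):
        data = rng.normal(0, 0.2, (12, 2, 2))
        data[:, 0, 0] += 1.0
        data[:, 1, 1] += 1.0                               # crossover pattern
        res = perm_factorial_rm(data, n_perm=999, seed=0)
        assert res.interaction.p <= 0.01

    def test_interaction_stat_invariant_to_relabeling(self, rng):
        data = rng.normal(0, 1, (8, 3, 3))
        a = perm_factorial_rm(data, n_perm=50, seed=0)
        b = perm_factorial_rm(data[:, :, [2, 0, 1]], n_perm=50, seed=0)
        assert a.interaction.observed_stat == pytest.approx(
            b.interaction.observed_stat)

    def test_rejects_non_crossed(self):
        with pytest.raises(ValueError):
            perm_factorial_rm(np.ones((4, 3)))
        bad = np.ones((4, 2, 2))
        bad[0, 1, 1] = np.nan
        with pytest.raises(ValueError):
            perm_factorial_rm(bad)


class TestPairedPerm:
    def test_identical_pairs(self):
        x = np.arange(6.0)
        res = paired_perm_test(x, x)
        assert res.p == 1.0

    def test_monte_carlo_matches_exhaustive(self, rng):
        x = rng.normal(0.6, 1, 10)
        y = rng.normal(0.0, 1, 10)
        exact = paired_perm_test(x, y)           # 2^10 sign patterns
        assert exact.exhaustive and exact.n_perm == 1024
        mc = paired_perm_test(x, y, n_perm=20_000, seed=1, exhaustive_cap=1)
        assert abs(mc.p - exact.p) < 0.01

    def test_translation_invariance(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0, 1, 8)
        a = paired_perm_test(x, y, seed=3)
        b = paired_perm_test(x + 5.0, y + 5.0, seed=3)
        assert a.p == b.p
        assert a.observed_stat == pytest.approx(b.observed_stat)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_perm_test([1, 2, 3], [1, 2])


class TestAdaptiveFDR:
    HAND_SETS = [
        [0.001, 0.008, 0.039, 0.041, 0.042, 0.06],
        [0.2, 0.5, 0.9, 0.04, 0.03, 0.6],
        [0.001, 0.002, 0.003, 0.004, 0.005, 0.006],
        [0.06, 0.07, 0.2, 0.8, 0.9, 0.95],
        [0.01],
        [0.049, 0.051],
    ]

    @pytest.mark.parametrize("pvals", HAND_SETS)
    def test_matches_independent_transcription(self, pvals):
        res = adaptive_fdr(pvals, q=0.05)
        assert np.array_equal(res.rejected, fdr_oracle(pvals, 0.05))

    @pytest.mark.parametrize("pvals", HAND_SETS[:4])
    def test_duplication_consistent_with_oracle(self, pvals):
        doubled = list(pvals) * 2
        res = adaptive_fdr(doubled, q=0.05)
        assert np.array_equal(res.rejected, fdr_oracle(doubled, 0.05))

    def test_matches_statsmodels_two_stage(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = np.concatenate([rng.uniform(0, 1, 8),
                                rng.uniform(0, 0.01, 4)])
            res = adaptive_fdr(p, q=0.05)
            sm_rej = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            assert np.array_equal(res.rejected, sm_rej)

    def test_no_rejections_above_q(self):
        res = adaptive_fdr([0.2, 0.4, 0.9], q=0.05)
        assert not res.rejected.any()
        assert res.p_fdr == 0.0

    def test_threshold_defines_rejections(self):
        res = adaptive_fdr(self.HAND_SETS[0], q=0.05)
        assert np.array_equal(
            res.rejected, np.asarray(self.HAND_SETS[0]) <= res.p_fdr + 1e-12)

    def test_monotone_in_q(self):
        p = self.HAND_SETS[0]
        low = adaptive_fdr(p, q=0.01).rejected
        high = adaptive_fdr(p, q=0.05).rejected
        assert np.all(high | ~low)   # lowering q never adds rejections

    def test_errors(self):
        with pytest.raises(ValueError):
            adaptive_fdr([])
        with pytest.raises(ValueError):
            adaptive_fdr([0.5, 1.2])


class TestDeltaDep:
    def test_all_wins(self):
        assert delta_dep([2, 3, 4], [1, 1, 1]).delta_dep == 1.0

    def test_all_ties(self):
        x = [1.0, 2.0, 3.0]
        assert delta_dep(x, x).delta_dep == 0.5

    def test_hand_enumeration(self):
        # x=(3,1,5,2) vs y=(2,2,2,2): wins at pairs 1 and 3, loss at 2,
        # tie at 4 -> (2 + 0.5) / 4 = 0.625 under the half-tie convention
        res = delta_dep([3, 1, 5, 2], [2, 2, 2, 2])
        assert res.delta_dep == pytest.approx(0.625)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=20))
    def test_complement_identity(self, x):
        y = [v + 0.3 * ((-1) ** i) for i, v in enumerate(x)]
        a = delta_dep(x, y).delta_dep
        b = delta_dep(y, x).delta_dep
        assert a + b == pytest.approx(1.0)


class TestBootstrapCI:
    def test_degenerate_collapses(self):
        x = np.full(10, 2.0)
        res = bootstrap_ci_delta(x, x, n_boot=1000, seed=0)
        assert res.ci_low == res.delta_dep == res.ci_high == 0.5

    def test_mirror_symmetry(self, rng):
        x = rng.normal(0.5, 1, 25)
        y = rng.normal(0.0, 1, 25)
        a = bootstrap_ci_delta(x, y, n_boot=2000, seed=4)
        b = bootstrap_ci_delta(y, x, n_boot=2000, seed=4)
        assert a.delta_dep == pytest.approx(1 - b.delta_dep)
        assert a.ci_low == pytest.approx(1 - b.ci_high, abs=1e-9)
        assert a.ci_high == pytest.approx(1 - b.ci_low, abs=1e-9)

    def test_ordering_invariant(self, rng):
        x = rng.normal(0.3, 1, 30)
        y = rng.normal(0, 1, 30)
        res = bootstrap_ci_delta(x, y, n_boot=1500, seed=2)
        assert 0 <= res.ci_low <= res.delta_dep <= res.ci_high <= 1

    def test_coverage_of_known_superiority(self):
        """Percentile-bootstrap CI covers the true superiority probability.

        Pairs (x, y) with x - y ~ N(mu, 1) give a known P(x > y); nominal
        95% intervals should cover it at close to nominal rate.
        """
        mu = 0.5244  # Phi(0.5244) ~ 0.70
        truth = 0.70
        rng = np.random.default_rng(2024)
        covered = 0
        n_rep = 1000
        for _ in range(n_rep):
            d = rng.normal(mu, 1.0, 50)
            y = rng.normal(0, 1, 50)
            res = bootstrap_ci_delta(y + d, y, n_boot=999, seed=int(
                rng.integers(2 ** 31)))
            covered += res.ci_low <= truth <= res.ci_high
        assert 0.92 <= covered / n_rep <= 0.975
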