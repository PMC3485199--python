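"""Cosinor scoring, period estimation, permutation p-values, call logic."""

import itertools

import numpy as np
import pytest

from hubcycle import (
    PeriodicityScore,
    SmoothedMatrix,
    call_gene,
    combine_calls,
    cosinor_fit,
    estimate_period,
    score_gene,
)


def bruteforce_p_perm(times, values, period, n_perm, seed):
    """Independent permutation oracle: per-permutation least-squares refit."""
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    w = 2 * np.pi * t / period
    X = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])

    def r2(yy):
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        ss_res = np.sum((yy - X @ beta) ** 2)
        ss_tot = np.sum((yy - yy.mean()) ** 2)
        return 1 - ss_res / ss_tot

    obs = r2(y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r2(y[rng.permutation(t.size)]) >= obs:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def smoothed(values, times=None, experiment_id="e"):
    values = np.atleast_2d(np.asarray(values, float))
    times = np.arange(values.shape[1], dtype=float) * 7 if times is None else times
    return SmoothedMatrix(
        experiment_id=experiment_id,
        genes=[f"G{i}" for i in range(values.shape[0])],
        times=times,
        values=values,
        missing=np.zeros_like(values, dtype=bool),
    )


class TestCosinorFit:
    def test_recovers_known_parameters(self):
        t = np.linspace(0, 119, 18)
        m, amp, phase, r2 = cosinor_fit(t, 0.3 + 0.8 * np.cos(2 * np.pi * (t - 25) / 60), 60)
        assert m == pytest.approx(0.3, abs=1e-9)
        assert amp == pytest.approx(0.8, abs=1e-9)
        assert phase == pytest.approx(25.0, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_series(self):
        t = np.linspace(0, 119, 18)
        _, amp, _, r2 = cosinor_fit(t, np.full(18, 0.2), 60)
        assert amp == 0.0 and r2 == 0.0


class TestEstimatePeriod:
    GRID = list(range(40, 125, 5))

    def test_noiseless_cosines(self, rng):
        t = np.linspace(0, 119, 18)
        rows = [
            rng.uniform(0.4, 1) * np.cos(2 * np.pi * (t - rng.uniform(0, 60)) / 60)
            for _ in range(20)
        ]
        assert estimate_period(smoothed(np.array(rows), t), self.GRID) == 60.0

    def test_all_constant_matrix_errors(self):
        with pytest.raises(ValueError, match="no usable genes"):
            estimate_period(smoothed(np.zeros((5, 18))), self.GRID)

    def test_noisy_recovery_rate(self):
        # T=75, A=1, sigma=0.2: recovered within +/-5 in >=95/100 replicates
        t = np.linspace(0, 160, 17)
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            rows = [
                np.cos(2 * np.pi * (t - rng.uniform(0, 75)) / 75)
                + rng.normal(0, 0.2, t.size)
                for _ in range(20)
            ]
            if abs(estimate_period(smoothed(np.array(rows), t), self.GRID) - 75) <= 5:
                hits += 1
        assert hits >= 95


class TestScoreGene:
    def test_perfect_cosine(self):
        t = np.linspace(0, 119, 18)
        y = np.cos(2 * np.pi * t / 60)
        sc = score_gene(t, y, 60, n_perm=200, seed=0)
        assert sc.usable
        assert sc.amplitude_A == pytest.approx(1.0, abs=1e-9)
        assert sc.r_squared == pytest.approx(1.0, abs=1e-9)
        assert sc.p_perm == pytest.approx(1 / 201)

    def test_constant_series_amplitude_zero(self):
        t = np.linspace(0, 119, 18)
        sc = score_gene(t, np.full(18, 0.4), 60, n_perm=50, seed=0)
        assert sc.usable and sc.amplitude_A == 0.0
        assert call_gene(sc) == "aperiodic"

    def test_too_few_points_unusable(self):
        t = np.linspace(0, 119, 18)
        missing = np.ones(18, bool)
        missing[:5] = False
        sc = score_gene(t, np.zeros(18), 60, missing=missing)
        assert not sc.usable
        assert call_gene(sc) == "unusable"

    def test_window_shorter_than_period_unusable(self):
        t = np.linspace(0, 50, 10)
        sc = score_gene(t, np.cos(2 * np.pi * t / 80), 80)
        assert not sc.usable

    def test_matches_bruteforce_permutation_oracle(self, rng):
        t = np.linspace(0, 119, 18)
        for k in range(20):
            y = rng.normal(0, 1, 18)
            sc = score_gene(t, y, 66, n_perm=200, seed=500 + k)
            assert sc.p_perm == bruteforce_p_perm(t, y, 66, 200, 500 + k)

    def test_p_invariant_to_shift_and_positive_scale(self, rng):
        t = np.linspace(0, 119, 18)
        y = rng.normal(0, 1, 18)
        p0 = score_gene(t, y, 66, n_perm=300, seed=9).p_perm
        assert score_gene(t, y + 5.0, 66, n_perm=300, seed=9).p_perm == p0
        assert score_gene(t, 3.7 * y, 66, n_perm=300, seed=9).p_perm == p0


class TestCallGene:
    def _score(self, amp, p):
        return PeriodicityScore(
            gene="G", experiment_id="e", period_T=66.0, amplitude_A=amp,
            phase_phi=0.0, r_squared=0.9, p_perm=p, n_usable=18, usable=True,
        )

    def test_low_amplitude_fails_floor(self):
        # significant but tiny oscillation is still aperiodic
        assert call_gene(self._score(0.15, 0.001)) == "aperiodic"

    def test_both_criteria_met(self):
        assert call_gene(self._score(0.8, 0.001)) == "periodic"

    def test_insignificant_fails(self):
        assert call_gene(self._score(0.8, 0.2)) == "aperiodic"


class TestCombineCalls:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            (["periodic", "periodic", "aperiodic"], "periodic"),
            (["aperiodic", "aperiodic", "periodic"], "aperiodic"),
            (["periodic", "aperiodic"], "unclassifiable"),
            (["unusable", "unusable", "periodic"], "unclassifiable"),
            (["unusable", "periodic", "periodic"], "periodic"),
        ],
    )
    def test_majority_rule(self, calls, expected):
        assert combine_calls(calls) == expected

    def test_symmetric_in_experiment_order(self):
        calls = ["periodic", "aperiodic", "unusable", "periodic"]
        results = {combine_calls(list(p)) for p in itertools.permutations(calls)}
        assert len(results) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_calls([])
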