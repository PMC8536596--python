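"""True-survival MSE, time-dependent concordance, IPCW Brier scores."""

import numpy as np
import pytest

from nnsurv import (
    StepEstimate,
    ValidationError,
    brier_score,
    censoring_kaplan_meier,
    concordance_td,
    integrated_brier_score,
    mse_true_survival,
)


def brute_force_concordance(durations, events, S):
    """Literal double loop over ordered pairs (independent oracle)."""
    n = len(durations)
    num, den = 0.0, 0
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            comparable = durations[i] < durations[j] or (
                durations[i] == durations[j] and events[j] == 0
            )
            if not comparable:
                continue
            den += 1
            if S[i, i] < S[i, j]:
                num += 1.0
            elif S[i, i] == S[i, j]:
                num += 0.5
    if den == 0:
        raise ValidationError("no comparable pairs")
    return num / den


class TestMSE:
    def test_identity_and_offset(self):
        truth = np.random.default_rng(0).uniform(0.2, 0.8, (5, 7))
        assert mse_true_survival(truth, truth) == 0.0
        assert mse_true_survival(truth + 0.1, truth) == pytest.approx(0.01)

    def test_hand_value(self):
        assert mse_true_survival([[1.0, 0.0]], [[0.5, 0.5]]) == pytest.approx(0.25)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            mse_true_survival(np.ones((2, 3)), np.ones((2, 4)))


class TestConcordance:
    def test_perfect_ranking(self):
        durations = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 1, 1])
        # lower survival for earlier events at every evaluation time
        S = np.array([[0.1, 0.5, 0.9]] * 3, dtype=float)
        assert concordance_td(durations, events, S) == 1.0

    def test_identical_predictions_give_half(self):
        durations = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 1, 1])
        S = np.full((3, 3), 0.5)
        assert concordance_td(durations, events, S) == 0.5

    def test_hand_counted_third(self):
        durations = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 1, 1])
        # pairs (1,2): 0, (1,3): 0, (2,3): 1  ->  1/3
        S = np.array(
            [
                [0.5, 0.4, 0.3],  # S(T_1 | x_j): x_1 highest -> discordant twice
                [0.0, 0.5, 0.9],
                [0.0, 0.0, 0.5],
            ]
        )
        assert concordance_td(durations, events, S) == pytest.approx(1 / 3)

    def test_no_comparable_pairs(self):
        with pytest.raises(ValidationError):
            concordance_td([1.0, 1.0], [0, 0], np.full((2, 2), 0.5))

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 31))
            durations = np.round(rng.exponential(3, n), 1) + 0.1
            events = (rng.random(n) < 0.7).astype(int)
            if not events.any():
                events[0] = 1
            S = rng.uniform(0, 1, (n, n))
            S[rng.random((n, n)) < 0.1] = 0.5  # force some prediction ties
            try:
                expected = brute_force_concordance(durations, events, S)
            except ValidationError:
                continue
            assert concordance_td(durations, events, S) == expected

    def test_invariant_to_monotone_transform(self, rng):
        n = 20
        durations = rng.exponential(3, n) + 0.1
        events = np.ones(n, dtype=int)
        S = rng.uniform(0, 1, (n, n))
        before = concordance_td(durations, events, S)
        after = concordance_td(durations, events, np.sqrt(S))
        assert before == after


class TestBrierScore:
    def test_oracle_predictions_score_zero(self, rng):
        durations = rng.uniform(1, 10, 30)
        events = np.ones(30, dtype=int)
        G = censoring_kaplan_meier(durations, events)  # identically 1
        for t in (2.0, 5.0):
            surv = (durations > t).astype(float)
            assert brier_score(t, durations, events, surv, G) == 0.0

    def test_constant_half_scores_quarter(self, rng):
        durations = rng.uniform(1, 10, 50)
        events = np.ones(50, dtype=int)
        G = censoring_kaplan_meier(durations, events)
        assert brier_score(5.0, durations, events, np.full(50, 0.5), G) == pytest.approx(0.25)

    def test_hand_value(self):
        durations = np.array([1.0, 3.0])
        events = np.array([1, 1])
        G = censoring_kaplan_meier(durations, events)
        s = np.array([0.2, 0.9])
        assert brier_score(2.0, durations, events, s, G) == pytest.approx(0.025)

    def test_uncensored_equals_plain_squared_error(self, rng):
        durations = rng.uniform(1, 10, 40)
        events = np.ones(40, dtype=int)
        G = StepEstimate([], [])  # G == 1
        s = rng.uniform(0, 1, 40)
        t = 4.0
        expected = np.mean(((durations > t).astype(float) - s) ** 2)
        assert brier_score(t, durations, events, s, G) == pytest.approx(expected, abs=1e-12)

    def test_censored_before_t_contribute_zero(self):
        durations = np.array([1.0, 5.0])
        events = np.array([0, 1])
        G = StepEstimate([], [])
        s = np.array([0.9, 0.8])
        # only the second individual contributes (still alive at t=2)
        assert brier_score(2.0, durations, events, s, G) == pytest.approx(
            (1 - 0.8) ** 2 / 2
        )


class TestIntegratedBrierScore:
    def test_constant_half_integrates_to_quarter(self, rng):
        durations = rng.uniform(1, 10, 50)
        events = np.ones(50, dtype=int)
        G = censoring_kaplan_meier(durations, events)
        times = np.linspace(0.5, 0.9, 10)  # everyone still alive
        surv = np.full((50, 10), 0.5)
        assert integrated_brier_score(times, durations, events, surv, G) == pytest.approx(0.25)

    def test_trapezoid_of_linear_integrand(self):
        durations = np.array([10.0, 10.0])
        events = np.array([1, 1])
        G = StepEstimate([], [])
        # hand-set Brier values 0.1 and 0.3 at the two times -> trapezoid 0.2
        s = np.array([[1 - np.sqrt(0.1), 1 - np.sqrt(0.3)]] * 2)
        times = np.array([1.0, 2.0])
        assert integrated_brier_score(times, durations, events, s, G) == pytest.approx(0.2)

    def test_refinement_invariance_piecewise_linear(self):
        durations = np.array([100.0] * 3)
        events = np.array([1, 1, 1])
        G = StepEstimate([], [])

        def s_of_t(t):
            return 1 - np.sqrt(0.05 + 0.02 * t)  # integrand linear in t

        coarse = np.array([1.0, 5.0, 9.0])
        fine = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        sc = np.tile(s_of_t(coarse), (3, 1))
        sf = np.tile(s_of_t(fine), (3, 1))
        a = integrated_brier_score(coarse, durations, events, sc, G)
        b = integrated_brier_score(fine, durations, events, sf, G)
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            integrated_brier_score([], [1.0], [1], np.ones((1, 0)), StepEstimate([], []))
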