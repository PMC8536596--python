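"""Link functions, loss values, loss gradients and survival constructors."""

import numpy as np
import pytest

from nnsurv import ConfigurationError, TimeGrid, ValidationError
from nnsurv.discretization import DiscreteLabels
from nnsurv.heads import (
    hazard_from_logits,
    logistic_hazard_loss,
    logistic_hazard_loss_grad,
    pc_hazard_loss,
    pc_hazard_loss_grad,
    pmf_from_logits,
    pmf_loss,
    pmf_loss_grad,
    softplus_rates,
    surv_from_hazard,
    surv_from_pmf,
    surv_pc_hazard,
)


def random_labels(rng, n, m, interval=False):
    idx = rng.integers(0, m + 1, n)
    events = (rng.random(n) < 0.5).astype(int)
    events[idx == 0] = 0
    frac = np.where(idx >= 1, rng.uniform(0.01, 1.0, n), 1.0)
    return DiscreteLabels(idx, events, frac, m)


class TestLinks:
    def test_hazard_link(self):
        h = hazard_from_logits(np.array([[0.0, np.log(3.0), -50.0]]))
        np.testing.assert_allclose(h[0, :2], [0.5, 0.75], atol=1e-12)
        assert h[0, 2] < 1e-20

    def test_surv_from_hazard(self):
        s = surv_from_hazard(np.array([[0.5, 0.5]]))
        np.testing.assert_allclose(s, [[1, 0.5, 0.25]], atol=1e-12)
        np.testing.assert_allclose(surv_from_hazard(np.zeros((1, 3))), np.ones((1, 4)))
        np.testing.assert_allclose(
            surv_from_hazard(np.array([[1.0, 0.3]])), [[1, 0, 0]], atol=1e-300
        )

    def test_pmf_link(self):
        f, tail = pmf_from_logits(np.array([[0.0, 0.0]]))
        np.testing.assert_allclose(f, [[1 / 3, 1 / 3]], atol=1e-12)
        np.testing.assert_allclose(tail, [1 / 3], atol=1e-12)
        f, tail = pmf_from_logits(np.array([[np.log(2.0), 0.0]]))
        np.testing.assert_allclose(f, [[0.5, 0.25]], atol=1e-12)
        np.testing.assert_allclose(tail, [0.25], atol=1e-12)

    def test_surv_from_pmf(self):
        s = surv_from_pmf(np.array([[1 / 3, 1 / 3]]), np.array([1 / 3]))
        np.testing.assert_allclose(s, [[1, 2 / 3, 1 / 3]], atol=1e-12)
        s = surv_from_pmf(np.array([[0.0, 0.0]]), np.array([1.0]))
        np.testing.assert_allclose(s, np.ones((1, 3)))
        s = surv_from_pmf(np.array([[1.0, 0.0]]), np.array([0.0]))
        np.testing.assert_allclose(s, [[1, 0, 0]], atol=1e-12)

    def test_softplus(self):
        np.testing.assert_allclose(softplus_rates(np.array(0.0)), np.log(2), atol=1e-12)
        np.testing.assert_allclose(softplus_rates(np.array(50.0)), 50.0, atol=1e-12)
        np.testing.assert_allclose(
            softplus_rates(np.array(np.log(np.e - 1))), 1.0, atol=1e-12
        )


class TestLossValues:
    def test_logistic_hazard_hand_values(self):
        # single event in the first interval at phi=0: -log 0.5
        L = DiscreteLabels([1], [1], [1.0], 3)
        assert logistic_hazard_loss(np.zeros((1, 3)), L) == pytest.approx(
            np.log(2), abs=1e-12
        )
        # censored at kappa=2: two survival factors of 0.5
        L = DiscreteLabels([2], [0], [1.0], 2)
        assert logistic_hazard_loss(np.zeros((1, 2)), L) == pytest.approx(
            2 * np.log(2), abs=1e-12
        )
        # censored at kappa=0: empty sum
        L = DiscreteLabels([0], [0], [1.0], 2)
        assert logistic_hazard_loss(np.ones((1, 2)), L) == 0.0

    def test_pmf_hand_values(self):
        L = DiscreteLabels([1], [1], [1.0], 1)
        assert pmf_loss(np.zeros((1, 1)), L) == pytest.approx(np.log(2), abs=1e-12)
        L = DiscreteLabels([1], [0], [1.0], 2)
        assert pmf_loss(np.zeros((1, 2)), L) == pytest.approx(
            -np.log(2 / 3), abs=1e-12
        )
        L = DiscreteLabels([0], [0], [1.0], 2)
        assert pmf_loss(np.ones((1, 2)), L) == 0.0

    def test_pc_hazard_hand_values(self):
        phi1 = np.full((1, 1), np.log(np.e - 1))  # eta = 1
        L = DiscreteLabels([1], [1], [0.5], 1)
        assert pc_hazard_loss(phi1, L) == pytest.approx(0.5, abs=1e-12)
        phi2 = np.full((1, 2), np.log(np.e - 1))
        L = DiscreteLabels([2], [0], [1.0], 2)
        assert pc_hazard_loss(phi2, L) == pytest.approx(2.0, abs=1e-12)
        L = DiscreteLabels([0], [0], [1.0], 2)
        assert pc_hazard_loss(phi2, L) == 0.0

    def test_shape_mismatch_is_configuration_error(self):
        L = DiscreteLabels([1], [1], [1.0], 3)
        with pytest.raises(ConfigurationError):
            logistic_hazard_loss(np.zeros((1, 2)), L)

    @pytest.mark.parametrize("loss", [pmf_loss, pc_hazard_loss])
    def test_event_at_zero_rejected(self, loss):
        bad = DiscreteLabels([1], [1], [1.0], 2)
        bad.idx[0] = 0  # bypass the container's own check
        with pytest.raises(ValidationError):
            loss(np.zeros((1, 2)), bad)


class TestGradients:
    @pytest.mark.parametrize(
        "loss, grad",
        [
            (logistic_hazard_loss, logistic_hazard_loss_grad),
            (pmf_loss, pmf_loss_grad),
            (pc_hazard_loss, pc_hazard_loss_grad),
        ],
    )
    def test_matches_finite_differences(self, rng, loss, grad):
        n, m = 6, 4
        phi = rng.normal(0, 2, (n, m))
        lab = random_labels(rng, n, m)
        g = grad(phi, lab)
        eps = 1e-6
        for i in range(n):
            for j in range(m):
                p = phi.copy()
                p[i, j] += eps
                up = loss(p, lab)
                p[i, j] -= 2 * eps
                dn = loss(p, lab)
                assert g[i, j] == pytest.approx((up - dn) / (2 * eps), abs=1e-7)


class TestLikelihoodEquivalence:
    def test_hazard_form_equals_pmf_form(self, rng):
        """The binary cross-entropy reformulation equals the f/S form of the
        censored likelihood computed from identical hazards."""
        for _ in range(50):
            n = int(rng.integers(1, 21))
            m = int(rng.integers(1, 11))
            phi = rng.normal(0, 3, (n, m))
            lab = random_labels(rng, n, m)
            h = hazard_from_logits(phi)
            S = surv_from_hazard(h)
            f = h * S[:, :-1]
            total = 0.0
            for i in range(n):
                k = lab.idx[i]
                if k == 0:
                    continue
                total -= np.log(f[i, k - 1]) if lab.events[i] else np.log(S[i, k])
            assert logistic_hazard_loss(phi, lab) == pytest.approx(
                total / n, abs=1e-10
            )


class TestNormalizationAndMonotonicity:
    def test_pmf_rows_sum_to_one_extremes(self, rng):
        phi = rng.uniform(-30, 30, (200, 8))
        f, tail = pmf_from_logits(phi)
        np.testing.assert_allclose(f.sum(axis=1) + tail, 1.0, atol=1e-12)

    def test_all_constructors_monotone_from_one(self, rng):
        grid = TimeGrid(np.arange(7.0))
        for _ in range(20):
            phi = rng.normal(0, 4, (10, 6))
            for surv in (
                surv_from_hazard(hazard_from_logits(phi)),
                surv_from_pmf(*pmf_from_logits(phi)),
                np.hstack(
                    [np.ones((10, 1)), np.exp(-np.cumsum(softplus_rates(phi), axis=1))]
                ),
            ):
                np.testing.assert_allclose(surv[:, 0], 1.0)
                assert (np.diff(surv, axis=1) <= 1e-12).all()
                assert ((surv >= 0) & (surv <= 1 + 1e-12)).all()


class TestPCHazardSurvival:
    grid = TimeGrid([0, 1, 2])

    def test_hand_values(self):
        eta = np.log(2) * np.ones((1, 2))
        np.testing.assert_allclose(
            surv_pc_hazard(eta, self.grid, [1.0]), [[0.5]], atol=1e-12
        )
        np.testing.assert_allclose(
            surv_pc_hazard(eta, self.grid, [1.5]),
            [[0.5 * np.exp(-0.5 * np.log(2))]],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            surv_pc_hazard(np.zeros((1, 2)), self.grid, [0.5, 1.7]), [[1.0, 1.0]]
        )

    def test_grid_points_equal_cumulative_product(self, rng):
        eta = rng.uniform(0, 2, (5, 2))
        s = surv_pc_hazard(eta, self.grid, self.grid.cuts[1:])
        expected = np.exp(-np.cumsum(eta, axis=1))
        np.testing.assert_allclose(s, expected, atol=1e-12)

    def test_continuity_at_cuts(self, rng):
        eta = rng.uniform(0, 2, (4, 2))
        eps = 1e-10
        for cut in [1.0]:
            lo = surv_pc_hazard(eta, self.grid, [cut - eps])
            hi = surv_pc_hazard(eta, self.grid, [cut + eps])
            np.testing.assert_allclose(lo, hi, atol=1e-9)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValidationError):
            surv_pc_hazard(np.ones((1, 2)), self.grid, [0.0])
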