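import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gastroseg.losses import (
    DegeneratePartitionError,
    LossConfig,
    curve_length,
    ls_loss,
    lsr_gradient,
    lsr_loss,
    region_area,
    region_means,
    smoothed_step,
    smoothed_step_literal,
)

from _oracles import ls_loss_oracle, lsr_loss_oracle, curve_length_oracle


class TestSmoothedStep:
    def test_half_at_origin_for_any_epsilon(self):
        for eps in (0.1, 1.0, 100.0, 1e6):
            assert smoothed_step(0.0, eps) == 0.5

    def test_three_quarters_at_inverse_epsilon(self):
        for eps in (0.5, 2.0, 50.0):
            assert smoothed_step(1.0 / eps, eps) == pytest.approx(0.75, abs=1e-12)

    @given(st.floats(-50, 50), st.floats(0.01, 1000))
    @settings(deadline=None, max_examples=50)
    def test_odd_symmetry_and_monotone_range(self, x, eps):
        h = smoothed_step(x, eps)
        assert 0.0 < h < 1.0
        assert smoothed_step(x, eps) + smoothed_step(-x, eps) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            smoothed_step(0.0, 0.0)

    def test_literal_variant_exposes_quoted_constants(self):
        # arctan(0)/180 + 60 = 60: the printed form is not a unit step
        assert smoothed_step_literal(0.0, 5.0) == 60.0


class TestRegularizers:
    def test_constant_field_has_zero_length(self):
        assert curve_length(np.ones((8, 8)), 100.0) == 0.0

    def test_all_ones_area_tends_to_pixel_count(self):
        assert region_area(np.ones((8, 8)), 1e8) == pytest.approx(64.0, rel=1e-6)

    def test_block_length_counts_boundary_edges(self):
        phi = np.zeros((8, 8))
        phi[2:6, 2:6] = 1.0
        # 4x4 block away from the border: 16 sign-change edges under forward diffs
        assert curve_length(phi, 1e8) == pytest.approx(16.0, rel=1e-6)

    def test_matches_scalar_loop(self, rng):
        phi = rng.uniform(0, 1, (9, 7))
        assert curve_length(phi, 13.0) == pytest.approx(
            curve_length_oracle(phi.tolist(), 13.0), rel=1e-12
        )


class TestRegionMeans:
    def test_binary_perfect_partition_limits(self):
        G = np.zeros((6, 6))
        G[1:4, 1:4] = 1.0
        c1, c2 = region_means(G, G, epsilon=1e7)
        assert c1 == pytest.approx(1.0, abs=1e-5)
        assert c2 == pytest.approx(0.0, abs=1e-5)

    def test_constant_reference_gives_equal_means(self, rng):
        phi = rng.uniform(0.1, 0.9, (5, 5))
        c1, c2 = region_means(np.full((5, 5), 3.7), phi, 10.0)
        assert c1 == pytest.approx(3.7)
        assert c2 == pytest.approx(3.7)

    def test_two_by_two_hand_evaluated_case(self):
        G = np.array([[1.0, 0.0], [0.0, 0.0]])
        phi = np.array([[0.8, 0.2], [0.1, 0.1]])
        c1, c2 = region_means(G, phi, 10.0)
        assert c1 == pytest.approx(0.776484452877, abs=1e-10)
        assert c2 == pytest.approx(0.036010857695, abs=1e-10)

    def test_degenerate_partition_raises(self):
        with pytest.raises(DegeneratePartitionError):
            region_means(np.ones((4, 4)), np.ones((4, 4)), epsilon=1e12)


class TestLossOracleEquivalence:
    def test_ls_loss_matches_scalar_loop_on_random_instances(self, rng):
        for _ in range(25):
            h, w = rng.integers(3, 17, size=2)
            img = rng.normal(0, 50, (h, w))
            phi = rng.uniform(0.02, 0.98, (h, w))
            cfg = LossConfig(
                mu=rng.uniform(0.1, 2), chi=rng.uniform(0.1, 2),
                delta1=rng.uniform(0.1, 3), delta2=rng.uniform(0.1, 3),
                epsilon=rng.uniform(1, 50),
            )
            expected = ls_loss_oracle(
                img.tolist(), phi.tolist(), cfg.mu, cfg.chi,
                cfg.delta1, cfg.delta2, cfg.epsilon,
            )
            assert ls_loss(img, phi, cfg) == pytest.approx(expected, rel=1e-10)

    def test_lsr_loss_matches_scalar_loop_on_random_instances(self, rng):
        for _ in range(25):
            h, w = rng.integers(3, 17, size=2)
            G = rng.integers(0, 2, (h, w)).astype(float)
            phi = rng.uniform(0.02, 0.98, (h, w))
            cfg = LossConfig(
                delta1=rng.uniform(0.1, 3), delta2=rng.uniform(0.1, 3),
                delta3=rng.uniform(0.1, 3), epsilon=rng.uniform(1, 50),
            )
            expected = lsr_loss_oracle(
                G.tolist(), phi.tolist(), cfg.delta1, cfg.delta2,
                cfg.delta3, cfg.epsilon,
            )
            assert lsr_loss(G, phi, cfg) == pytest.approx(expected, rel=1e-10)

    def test_three_by_three_cross_worked_case(self):
        G = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=float)
        phi = 0.7 * G + 0.1
        cfg = LossConfig(epsilon=5.0)
        expected = lsr_loss_oracle(G.tolist(), phi.tolist(), 1.0, 1.0, 1.0, 5.0)
        assert lsr_loss(G, phi, cfg) == pytest.approx(expected, rel=1e-10)


class TestLossProperties:
    def test_non_negativity(self, rng):
        for _ in range(10):
            img = rng.normal(0, 10, (6, 6))
            G = rng.integers(0, 2, (6, 6)).astype(float)
            phi = rng.uniform(0.05, 0.95, (6, 6))
            assert ls_loss(img, phi) >= 0.0
            assert lsr_loss(G, phi) >= 0.0

    def test_delta3_scale_covariance(self, rng):
        # the pixel-fidelity term enters as (1/delta3) * sum (G-phi)^2 exactly
        G = rng.integers(0, 2, (6, 6)).astype(float)
        phi = rng.uniform(0.05, 0.95, (6, 6))
        f3 = float(((G - phi) ** 2).sum())
        l1 = lsr_loss(G, phi, LossConfig(delta3=1.0))
        l4 = lsr_loss(G, phi, LossConfig(delta3=4.0))
        assert l1 - l4 == pytest.approx(0.75 * f3, rel=1e-10)

    def test_perfect_prediction_limit(self, rng):
        for _ in range(5):
            G = rng.integers(0, 2, (12, 12)).astype(float)
            if G.min() == G.max():
                continue
            loss = lsr_loss(G, G, LossConfig(epsilon=1e6))
            assert loss < 1e-6 * G.size

    def test_misclassification_penalized(self, rng):
        G = np.zeros((8, 8))
        G[2:6, 2:6] = 1.0
        cfg = LossConfig(epsilon=50.0)
        assert lsr_loss(G, 1.0 - G, cfg) > lsr_loss(G, G, cfg)

    def test_two_region_image_fidelity_vanishes_at_true_partition(self):
        img = np.full((8, 8), 0.1)
        img[:, 4:] = 0.9
        phi = (img > 0.5).astype(float)
        tiny = 1e-9
        cfg = LossConfig(mu=tiny, chi=tiny, epsilon=1e6)
        assert ls_loss(img, phi, cfg) < 1e-3


class TestLsrGradient:
    def test_matches_central_finite_differences(self, rng):
        for _ in range(5):
            G = rng.integers(0, 2, (8, 8)).astype(float)
            phi = rng.uniform(0.05, 0.95, (8, 8))
            cfg = LossConfig(
                delta1=rng.uniform(0.5, 2), delta2=rng.uniform(0.5, 2),
                delta3=rng.uniform(0.5, 2), epsilon=rng.uniform(2, 20),
            )
            g = lsr_gradient(G, phi, cfg)
            h = 1e-5
            fd = np.zeros_like(phi)
            for i in range(8):
                for j in range(8):
                    up, dn = phi.copy(), phi.copy()
                    up[i, j] += h
                    dn[i, j] -= h
                    fd[i, j] = (lsr_loss(G, up, cfg) - lsr_loss(G, dn, cfg)) / (2 * h)
            denom = np.maximum(np.abs(fd), 1e-6)
            assert (np.abs(g - fd) / denom).max() < 1e-3

    def test_zero_gradient_at_sharp_perfect_prediction(self, rng):
        G = rng.integers(0, 2, (8, 8)).astype(float)
        G[0, 0], G[0, 1] = 0, 1  # both classes present
        g = lsr_gradient(G, G, LossConfig(epsilon=1e8))
        assert np.abs(g).max() < 1e-6

    def test_gradient_shape_matches_phi(self, rng):
        G = rng.integers(0, 2, (5, 9)).astype(float)
        phi = rng.uniform(0.1, 0.9, (5, 9))
        assert lsr_gradient(G, phi).shape == (5, 9)
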