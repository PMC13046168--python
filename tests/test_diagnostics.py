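"""Tests of thinning, super-thinning and the K/L machinery."""

import dataclasses

import numpy as np
import pytest

import hawkesmix as hm
from hawkesmix.diagnostics import _COS_TAB, _SIN_TAB, _pair_weights
from tests.conftest import window_for


def brute_force_K(cat, region, distances, n_circle=8192):
    """Independent double-loop Ripley K with a fine circumference grid."""
    n = cat.n
    angles = 2 * np.pi * np.arange(n_circle) / n_circle
    ca, sa = np.cos(angles), np.sin(angles)
    out = np.zeros_like(np.asarray(distances, dtype=float))
    for m, d in enumerate(distances):
        acc = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dij = np.hypot(cat.x[i] - cat.x[j], cat.y[i] - cat.y[j])
                if dij < d:
                    px = cat.x[i] + dij * ca
                    py = cat.y[i] + dij * sa
                    w = np.mean(
                        (px >= region.x_lo)
                        & (px <= region.x_hi)
                        & (py >= region.y_lo)
                        & (py <= region.y_hi)
                    )
                    acc += 1.0 / w
        out[m] = region.area / n**2 * acc
    return out


class TestThin:
    def test_constant_intensity_keeps_everything(self, toy_catalog):
        lam = np.full(toy_catalog.n, 0.7)
        out = hm.thin(toy_catalog, lam, 0.7, seed=0)
        assert out.n == toy_catalog.n

    def test_zero_rate_empties(self, toy_catalog):
        lam = np.full(toy_catalog.n, 0.7)
        assert hm.thin(toy_catalog, lam, 0.0, seed=0).n == 0

    def test_half_retention_frequency(self, region):
        cat = hm.simulate_homogeneous(0.05, region, hm.TimeWindow(0, 10), seed=8)
        lam = np.full(cat.n, 2.0)
        kept = sum(hm.thin(cat, lam, 1.0, seed=s).n for s in range(50))
        total = 50 * cat.n
        se = np.sqrt(total * 0.25)
        assert abs(kept - 0.5 * total) < 3 * se


class TestSuperthinRate:
    def test_pure_background_reduction(self):
        bg = hm.BackgroundParams(a=[2.0], c=[0], d=[0], alpha=[1.0], beta=[1.0])
        tr = hm.TriggerParams(b=[1e-300], alpha=[1], beta=[1], gamma=[1])
        model = hm.ModelSpec(background=bg, trigger=tr, n_star=0)
        region = hm.SpatialRegion(-50, 50, -50, 50)
        window = hm.TimeWindow(0, 4)
        cat = hm.EventCatalog([0.0], [0.0], [1.0])
        k = hm.superthin_rate(model, cat, region, window)
        assert k == pytest.approx(bg.total_mass_per_time() / region.area, rel=1e-9)

    def test_linearity_in_amplitudes(self, toy_model, toy_catalog):
        region = hm.SpatialRegion(0, 4, 0, 4)
        window = hm.TimeWindow(0, 5)
        k1 = hm.superthin_rate(toy_model, toy_catalog, region, window)
        doubled = hm.ModelSpec(
            background=hm.BackgroundParams(
                a=2 * toy_model.background.a,
                c=toy_model.background.c,
                d=toy_model.background.d,
                alpha=toy_model.background.alpha,
                beta=toy_model.background.beta,
            ),
            trigger=hm.TriggerParams(
                b=2 * toy_model.trigger.b,
                alpha=toy_model.trigger.alpha,
                beta=toy_model.trigger.beta,
                gamma=toy_model.trigger.gamma,
            ),
            n_star=toy_model.n_star,
        )
        k2 = hm.superthin_rate(doubled, toy_catalog, region, window)
        assert k2 == pytest.approx(2 * k1, rel=1e-12)

    def test_equals_mean_intensity_by_quadrature(self, toy_model, toy_catalog):
        from tests.test_likelihood import numeric_compensator

        cat = hm.EventCatalog(toy_catalog.x[:5], toy_catalog.y[:5], toy_catalog.t[:5])
        region = hm.SpatialRegion(0, 4, 0, 4)
        window = hm.TimeWindow(0, 5)
        k = hm.superthin_rate(toy_model, cat, region, window)
        expected = numeric_compensator(toy_model, cat, region, window) / (
            region.area * window.length
        )
        assert k == pytest.approx(expected, rel=1e-5)


class TestSuperThin:
    def test_homogenization_count(self, region):
        # kernel well contained in the region so clipping and burn-in leave
        # the observed pattern's intensity essentially equal to the model's
        kern = hm.SimKernel(
            mu_bar=5.71,
            sigma_mu=2.2,
            c=10.0,
            d=10.0,
            components=(hm.TriggerComponent(theta=0.2, omega=0.5, sigma_x=0.05, sigma_y=0.05),),
        )
        model = hm.simkernel_to_model(kern)  # full history
        cfg = hm.SimConfig(kernel=kern, region=region, target_n=900, trim=300, seed=14)
        cat = hm.simulate_catalog(cfg)
        window = window_for(cat)
        k = hm.superthin_rate(model, cat, region, window)
        counts = [
            hm.super_thin(model, cat, region, window, seed=s).combined.n for s in range(12)
        ]
        expected = k * region.area * window.length
        se = np.sqrt(expected / 12)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_tiny_rate_thins_without_superposing(self, region):
        kern = hm.burglary_single_kernel()
        model = dataclasses.replace(hm.simkernel_to_model(kern), n_star=200)
        cfg = hm.SimConfig(kernel=kern, region=region, target_n=900, trim=300, seed=15)
        cat = hm.simulate_catalog(cfg)
        window = window_for(cat)
        lam = hm.intensity_at_events(model, cat)
        k = 0.5 * float(lam.min())
        res = hm.super_thin(model, cat, region, window, k=k, seed=2)
        assert res.superposed.n == 0 or res.superposed.n < 0.01 * cat.n
        expected_retained = float(np.sum(np.minimum(k / lam, 1.0)))
        assert abs(res.retained.n - expected_retained) < 4 * np.sqrt(expected_retained)
        assert res.combined.n == res.retained.n + res.superposed.n


class TestRipleyK:
    def test_zero_below_smallest_distance(self, region):
        cat = hm.EventCatalog([2.0, 18.0], [2.0, 18.0], [0.0, 1.0])
        K = hm.ripley_K(cat, region, np.array([0.5, 1.0]))
        np.testing.assert_array_equal(K, 0.0)

    def test_two_point_closed_form(self):
        region = hm.SpatialRegion(0, 1, 0, 1)
        cat = hm.EventCatalog([0.45, 0.55], [0.5, 0.5], [0.0, 1.0])
        K = hm.ripley_K(cat, region, np.array([0.2]))
        # both weights are 1; K = |S| n^-2 * 2 = 1 * (1/4) * 2
        assert K[0] == pytest.approx(0.5)

    def test_matches_brute_force_interior(self):
        rng = np.random.default_rng(6)
        region = hm.SpatialRegion(0, 10, 0, 10)
        cat = hm.EventCatalog.from_unsorted(
            rng.uniform(4, 6, 12), rng.uniform(4, 6, 12), rng.uniform(0, 1, 12)
        )
        d = np.array([0.3, 0.8, 1.5])  # circles stay interior: weights exactly 1
        np.testing.assert_allclose(
            hm.ripley_K(cat, region, d), brute_force_K(cat, region, d), rtol=1e-9
        )

    def test_matches_brute_force_with_edge_correction(self):
        rng = np.random.default_rng(16)
        region = hm.SpatialRegion(0, 4, 0, 4)
        cat = hm.EventCatalog.from_unsorted(
            rng.uniform(0, 4, 20), rng.uniform(0, 4, 20), rng.uniform(0, 1, 20)
        )
        d = np.array([0.5, 1.0])
        got = hm.ripley_K(cat, region, d)
        expected = brute_force_K(cat, region, d)
        np.testing.assert_allclose(got, expected, rtol=5e-3)

    def test_nondecreasing_in_distance(self, region, single_catalog):
        cat = hm.EventCatalog(
            single_catalog.x[:300], single_catalog.y[:300], single_catalog.t[:300]
        )
        K = hm.ripley_K(cat, region, hm.default_distance_grid(region))
        assert np.all(np.diff(K) >= 0)

    def test_requires_two_points(self, region):
        with pytest.raises(ValueError):
            hm.ripley_K(hm.EventCatalog([1.0], [1.0], [0.0]), region, np.array([1.0]))


class TestPairWeights:
    def test_interior_circle_weight_one(self):
        w = _pair_weights(
            np.array([10.0]), np.array([10.0]), np.array([2.0]),
            0.0, 20.0, 0.0, 20.0, _COS_TAB, _SIN_TAB,
        )
        assert w[0] == 1.0

    def test_weights_bounded(self):
        rng = np.random.default_rng(12)
        px = rng.uniform(0, 20, 200)
        py = rng.uniform(0, 20, 200)
        r = rng.uniform(0.1, 5, 200)
        w = _pair_weights(px, py, r, 0.0, 20.0, 0.0, 20.0, _COS_TAB, _SIN_TAB)
        assert np.all(w > 0) and np.all(w <= 1)

    def test_corner_circle_quarter_weight(self):
        w = _pair_weights(
            np.array([0.0]), np.array([0.0]), np.array([1.0]),
            0.0, 20.0, 0.0, 20.0, _COS_TAB, _SIN_TAB,
        )
        assert w[0] == pytest.approx(0.25, abs=0.01)


class TestCenteredL:
    def test_poisson_expectation_zero(self):
        d = np.linspace(0.1, 2, 10)
        np.testing.assert_allclose(hm.centered_L(np.pi * d**2, d), 0.0, atol=1e-12)

    def test_zero_K_gives_minus_d(self):
        d = np.array([0.5, 1.0])
        np.testing.assert_allclose(hm.centered_L(np.zeros(2), d), -d)

    def test_negative_K_rejected(self):
        with pytest.raises(ValueError):
            hm.centered_L(np.array([-0.1]), np.array([1.0]))


class TestEnvelope:
    def test_envelope_brackets_zero_and_mean_small(self, region):
        window = hm.TimeWindow(0, 30)
        d = hm.default_distance_grid(region, 25)[1:]
        lo, hi, mean = hm.mc_envelope(0.08, region, window, M=60, distances=d, seed=3)
        assert np.all(lo <= 0) and np.all(hi >= 0)
        assert np.all(lo <= hi)
        assert np.max(np.abs(mean)) < 0.5 * np.max(hi - lo)

    def test_clustered_catalog_exceeds_envelope(self, region):
        kern = hm.SimKernel(
            mu_bar=2.0,
            sigma_mu=4.5,
            c=10.0,
            d=10.0,
            components=(hm.TriggerComponent(theta=0.5, omega=0.5, sigma_x=0.05, sigma_y=0.05),),
        )
        cfg = hm.SimConfig(kernel=kern, region=region, target_n=700, trim=200, seed=19)
        cat = hm.simulate_catalog(cfg)
        window = window_for(cat)
        rate = cat.n / (region.area * window.length)
        d = hm.default_distance_grid(region, 25)[1:]
        lo, hi, _ = hm.mc_envelope(rate, region, window, M=40, distances=d, seed=5)
        cl = hm.centered_L(hm.ripley_K(cat, region, d), d)
        assert np.any(cl > hi)


def test_temporal_uniformity_pvalue(region):
    cat = hm.simulate_homogeneous(0.05, region, hm.TimeWindow(0, 20), seed=30)
    p = hm.temporal_uniformity(cat, hm.TimeWindow(0, 20))
    assert 0.0 <= p <= 1.0
    assert p > 0.001
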