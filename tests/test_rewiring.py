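import numpy as np
import pytest

from wirenet.geometry import SpatialLayout
from wirenet.rewiring import (
    RewireConfig,
    SaturationError,
    deepr_update,
    dsr_prune_and_grow,
    sample_regrowth_sites,
    set_rewire,
)
from wirenet.wiring_cost import SparseNet
from conftest import random_net


def net_from_weights(weights, coords=None):
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    coords = np.asarray(coords, float) if coords is not None else np.column_stack(
        [np.arange(n, dtype=float), np.zeros(n)]
    )
    mask = (weights != 0).astype(float)
    return SparseNet(mask, weights, SpatialLayout(coords))


class TestSet:
    def test_prunes_smallest_of_each_sign(self, rng):
        # active weights +0.9, +0.1, -0.5, -0.05 ; zeta=0.5 drops +0.1 and -0.05
        w = np.zeros((3, 3))
        w[0, 1], w[0, 2], w[1, 0], w[1, 2] = 0.9, 0.1, -0.5, -0.05
        net = net_from_weights(w)
        out = set_rewire(net, 0.5, rng)
        # survivors keep their weights; pruned slots are 0 (regrown sites
        # may coincide with pruned ones but always restart at weight 0)
        assert out.weights[0, 1] == 0.9 and out.mask[0, 1] == 1
        assert out.weights[1, 0] == -0.5 and out.mask[1, 0] == 1
        assert sorted(out.weights[out.mask > 0]) == [-0.5, 0.0, 0.0, 0.9]
        assert out.n_active == net.n_active

    def test_tiny_zeta_is_identity(self, rng, small_net):
        out = set_rewire(small_net, 1e-6, rng)
        np.testing.assert_array_equal(out.mask, small_net.mask)

    def test_count_conservation(self, rng, circle_net):
        net = circle_net
        for _ in range(5):
            net = set_rewire(net, 0.3, rng, distance_bias=True)
            assert net.n_active == circle_net.n_active

    def test_regrown_weights_start_at_zero(self, rng, small_net):
        out = set_rewire(small_net, 0.5, rng)
        new = (out.mask == 1) & (small_net.mask == 0)
        np.testing.assert_array_equal(out.weights[new], 0.0)


class TestDeepr:
    def cfg(self, **kw):
        defaults = dict(strategy="deepr", alpha=0.1, xi=1.0, temperature=0.0,
                        distance_bias=False)
        defaults.update(kw)
        return RewireConfig(**defaults)

    def test_plain_update(self, rng):
        net = net_from_weights([[0.0, 0.5], [0.0, 0.0]])
        signs = np.sign(net.weights)
        out, _ = deepr_update(net, signs, np.zeros((2, 2)), self.cfg(), rng)
        assert out.weights[0, 1] == pytest.approx(0.4)
        assert out.mask[0, 1] == 1

    def test_sign_flip_deactivates_and_regrows(self, rng):
        net = net_from_weights([[0.0, 0.05], [0.0, 0.0]])
        signs = np.sign(net.weights)
        out, new_signs = deepr_update(net, signs, np.zeros((2, 2)), self.cfg(), rng)
        assert out.mask[0, 1] == 0 and out.weights[0, 1] == 0
        assert out.n_active == 1
        grown = (out.mask == 1) & (net.mask == 0)
        assert grown.sum() == 1
        assert np.abs(out.weights[grown][0]) == pytest.approx(1e-12)
        assert new_signs[grown][0] in (-1.0, 1.0)

    def test_count_conserved_and_signs_stable_under_noise(self, rng, circle_net):
        net = circle_net.copy()
        signs = np.sign(net.weights)
        cfg = self.cfg(alpha=0.01, xi=0.1, temperature=1e-3, distance_bias=True)
        m0 = net.n_active
        for _ in range(200):
            grads = rng.standard_normal(net.weights.shape)
            net, signs = deepr_update(net, signs, grads, cfg, rng)
            assert net.n_active == m0
            active_nonzero = (net.mask > 0) & (net.weights != 0)
            np.testing.assert_array_equal(
                np.sign(net.weights[active_nonzero]), signs[active_nonzero]
            )

    def test_sign_bookkeeping_error(self, rng):
        net = net_from_weights([[0.0, 0.5], [0.0, 0.0]])
        bad_signs = -np.sign(net.weights)
        with pytest.raises(RuntimeError):
            deepr_update(net, bad_signs, np.zeros((2, 2)), self.cfg(), rng)


class TestDsr:
    def cfg(self, **kw):
        defaults = dict(strategy="dsr", H=0.1, delta=0.1, K=8, distance_bias=False)
        defaults.update(kw)
        return RewireConfig(**defaults)

    def test_single_layer_growth_equals_pruned(self, rng, small_net):
        net = small_net.copy()
        # push 8 active weights below threshold
        ii, jj = np.nonzero(net.mask)
        net.weights[ii[:8], jj[:8]] = 0.01
        (out,), _ = dsr_prune_and_grow([net], self.cfg(), rng)
        assert out.n_active == net.n_active

    def test_two_layer_proportional_allocation(self, rng):
        rng2 = np.random.default_rng(0)
        a = random_net(12, 0.5, rng2)
        b = random_net(12, 0.5, rng2)
        # layer a: 30 survivors + 6 pruned; layer b: 10 survivors + 2 pruned
        def shape_layer(net, keep, prune):
            ii, jj = np.nonzero(net.mask)
            net.mask[:] = 0
            net.weights[:] = 0
            sel = list(zip(ii, jj))[: keep + prune]
            for k, (i, j) in enumerate(sel):
                net.mask[i, j] = 1
                net.weights[i, j] = 0.01 if k < prune else 1.0
        shape_layer(a, 30, 6)
        shape_layer(b, 10, 2)
        cfg = self.cfg(K=8)
        (oa, ob), _ = dsr_prune_and_grow([a, b], cfg, rng)
        # 8 pruned in total; growth split 8 * 30/40 = 6 and 8 * 10/40 = 2
        assert oa.n_active == 36 and ob.n_active == 12

    def test_threshold_doubles_when_underpruning(self, rng, small_net):
        net = small_net.copy()
        net.weights[net.mask > 0] = 5.0  # nothing below H
        _, H_new = dsr_prune_and_grow([net], self.cfg(H=0.001, K=100), rng)
        assert H_new == pytest.approx(0.002)

    def test_threshold_halves_when_overpruning(self, rng, small_net):
        net = small_net.copy()
        net.weights[net.mask > 0] = 1e-6  # everything below H
        _, H_new = dsr_prune_and_grow([net], self.cfg(H=0.001, K=2), rng)
        assert H_new == pytest.approx(0.0005)


class TestRegrowthSampler:
    def test_equal_distances_sample_uniformly(self, rng):
        # 4 units on a square, one inactive candidate pair per side at equal D
        layout = SpatialLayout(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))
        mask = np.ones((4, 4))
        np.fill_diagonal(mask, 0)
        # free exactly the 4 side pairs (distance 1 each)
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            mask[i, j] = 0
        net = SparseNet(mask, np.zeros((4, 4)), layout)
        counts = {}
        for _ in range(10_000):
            (site,) = sample_regrowth_sites(net, 1, True, rng)
            counts[site] = counts.get(site, 0) + 1
        from scipy.stats import chisquare

        stat, p = chisquare(list(counts.values()))
        assert p > 0.01

    def test_inverse_distance_bias_two_candidates(self, rng):
        # candidates at distances 1 and 3 -> probabilities 0.75 / 0.25
        layout = SpatialLayout(np.array([[0, 0], [1, 0], [3, 0]], dtype=float))
        mask = np.ones((3, 3))
        np.fill_diagonal(mask, 0)
        mask[0, 1] = 0  # distance 1
        mask[0, 2] = 0  # distance 3
        net = SparseNet(mask, np.zeros((3, 3)) * mask, layout)
        n_near = 0
        draws = 10_000
        for _ in range(draws):
            (site,) = sample_regrowth_sites(net, 1, True, rng)
            n_near += site == (0, 1)
        from scipy.stats import binom

        lo, hi = binom.ppf([0.005, 0.995], draws, 0.75)
        assert lo <= n_near <= hi

    def test_exhaustion_returns_all_candidates(self, rng, small_net):
        off_diag = ~np.eye(small_net.n_units, dtype=bool)
        k = int(((small_net.mask == 0) & off_diag).sum())  # biased sampling skips D=0
        sites = sample_regrowth_sites(small_net, k, True, rng)
        assert len(set(sites)) == k

    def test_saturation_error(self, rng, small_net):
        with pytest.raises(SaturationError):
            sample_regrowth_sites(small_net, 10_000, False, rng)


class TestRewireConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"zeta": 0.0},
            {"zeta": 1.0},
            {"H": 0.0},
            {"delta": 1.5},
            {"K": 0},
            {"strategy": "magic"},
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            RewireConfig(**kw)
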