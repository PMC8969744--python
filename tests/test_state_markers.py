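"""Spectral power, wSMI connectivity and cluster-mass permutation tests."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_epochs
from oddball.montage import disc_montage
from oddball.state_markers import (
    BANDS,
    cluster_permutation_contrast,
    normalized_band_power,
    sensor_bayes_map,
    symbolic_transform,
    wsmi,
    wsmi_weights,
)


@pytest.fixture(scope="module")
def montage():
    return disc_montage(8)


def _rest_epochs(montage, n_trials=10, seed=0, fill=None):
    """Epochs spanning -0.8..0.8 s at 250 Hz (400 samples)."""
    epochs = make_epochs(montage, n_trials=n_trials, n_times=400, seed=seed,
                         tmin=-0.8)
    if fill is not None:
        epochs.data[:] = fill
    return epochs


class TestNormalizedBandPower:
    def test_pure_alpha_tone_concentrates_in_alpha(self, montage):
        epochs = _rest_epochs(montage, n_trials=4, seed=1)
        t = np.arange(400) / 250.0
        epochs.data[:] = 5.0 * np.sin(2 * np.pi * 10.0 * t)
        epochs.data += 0.01 * np.random.default_rng(2).normal(
            size=epochs.data.shape)
        power = normalized_band_power(epochs)
        assert power["alpha"].values.min() > 0.9
        assert power["gamma"].values.max() < 0.05

    def test_white_noise_fractions_track_bandwidth(self, montage):
        epochs = _rest_epochs(montage, n_trials=60, seed=3)
        power = normalized_band_power(epochs)
        total_bw = 44.0
        for name, (lo, hi) in BANDS.items():
            expected = (hi - lo) / total_bw
            got = power[name].values.mean()
            assert got == pytest.approx(expected, abs=0.05), name

    def test_band_fractions_tile_to_one(self, montage):
        epochs = _rest_epochs(montage, n_trials=6, seed=4)
        power = normalized_band_power(epochs)
        total = sum(power[name].values for name in BANDS)
        assert np.allclose(total, 1.0, atol=1e-9)


class TestSymbolicTransform:
    def test_monotone_series_single_symbol(self):
        sym = symbolic_transform(np.arange(30.0), k=3, tau=2)
        assert len(np.unique(sym)) == 1

    def test_negation_maps_to_opposite_symbols(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        s_pos = symbolic_transform(x, k=3, tau=1)
        s_neg = symbolic_transform(-x, k=3, tau=1)
        # the pair (s_pos, s_neg) must always be an opposite pair: the
        # weight matrix zeroes exactly those cells
        w = wsmi_weights(3)
        assert np.all(w[s_pos, s_neg] == 0.0)
        assert not np.any(s_pos == s_neg)  # strict negation flips every pattern

    def test_counts_match_exhaustive_enumeration_on_toy(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0, 6.0, 5.5, 3.5, 5.8, 7.0])
        tau, k = 2, 3
        sym = symbolic_transform(x, k=k, tau=tau)
        perms = list(itertools.permutations(range(k)))
        expected = []
        for t in range(len(x) - (k - 1) * tau):
            triple = (x[t], x[t + tau], x[t + 2 * tau])
            order = sorted(range(k), key=lambda i: triple[i])
            ranks = [0] * k
            for r, i in enumerate(order):
                ranks[i] = r
            expected.append(perms.index(tuple(ranks)))
        assert list(sym) == expected

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            symbolic_transform(np.arange(4.0), k=3, tau=2)


def brute_force_wsmi(xa, xb, k=3, tau=1):
    """Joint-symbol-histogram weighted MI, straight from the definition."""
    sa = symbolic_transform(xa, k=k, tau=tau)
    sb = symbolic_transform(xb, k=k, tau=tau)
    n_sym = math.factorial(k)
    w = wsmi_weights(k)
    m = len(sa)
    total = 0.0
    for s in range(n_sym):
        for s2 in range(n_sym):
            pj = np.sum((sa == s) & (sb == s2)) / m
            if pj == 0 or w[s, s2] == 0:
                continue
            ps = np.sum(sa == s) / m
            ps2 = np.sum(sb == s2) / m
            total += pj * np.log(pj / (ps * ps2))
    return total / np.log(n_sym)


class TestWsmi:
    def test_matches_brute_force_histogram_oracle(self, montage):
        epochs = _rest_epochs(montage, n_trials=3, seed=6)
        res = wsmi(epochs, tau=2, window=(-0.8, 0.0))
        mask = epochs.time_mask((-0.8, 0.0 - 1e-9))
        for e in range(3):
            for i, j in [(0, 1), (2, 5), (6, 7)]:
                ref = brute_force_wsmi(epochs.data[e, i, mask],
                                       epochs.data[e, j, mask], tau=2)
                assert res.matrices[e, i, j] == pytest.approx(ref, abs=1e-12)

    def test_symmetric_and_bounded(self, montage):
        epochs = _rest_epochs(montage, n_trials=4, seed=7)
        res = wsmi(epochs, tau=1)
        assert np.array_equal(res.matrices, np.swapaxes(res.matrices, 1, 2))
        assert np.all(res.matrices <= 1.0 + 1e-12)

    def test_identical_channels_score_zero(self, montage):
        epochs = _rest_epochs(montage, n_trials=3, seed=8)
        epochs.data[:, 1, :] = epochs.data[:, 0, :]
        res = wsmi(epochs, tau=1)
        assert np.allclose(res.matrices[:, 0, 1], 0.0, atol=1e-12)

    def test_independent_channels_near_zero(self, montage):
        epochs = _rest_epochs(montage, n_trials=20, seed=9)
        res = wsmi(epochs, tau=1)
        vals = res.matrices[:, 0, 1]
        # the plug-in MI estimate of independent finite samples carries a
        # positive bias of roughly (#weighted cells - 1) / (2 m log k!),
        # ~0.03 for the ~200-sample window; stay within a factor of two
        assert vals.mean() < 0.06

    def test_coupled_pair_dominates_uncoupled(self, montage):
        """A lag-coupled channel pair exceeds every uncoupled pair's wSMI in
        nearly all seeds."""
        from oddball.synth import couple_sensors

        hits = 0
        n_seeds = 12
        kern = np.ones(4) / 4.0
        for seed in range(n_seeds):
            epochs = _rest_epochs(montage, n_trials=12, seed=100 + seed)
            # autocorrelated background (as EEG is), decorrelating on the
            # lag timescale: a plain white-noise copy shares no rank
            # patterns with its source, while a long-smoothed copy becomes
            # a near-duplicate whose identical symbol pairs the weights
            # deliberately discount
            epochs.data = np.apply_along_axis(
                lambda v: np.convolve(v, kern, mode="same"), -1, epochs.data)
            coupled = couple_sensors(epochs, [(0, 1)], lag=2, strength=0.8)
            res = wsmi(coupled, tau=2)
            med = np.median(res.matrices, axis=0)
            pair_val = med[0, 1]
            others = [med[i, j] for i in range(8) for j in range(i + 1, 8)
                      if (i, j) != (0, 1)]
            hits += pair_val > max(others)
        assert hits >= n_seeds - 1

    def test_added_noise_never_helps_coupling(self, montage):
        """Data-processing-flavoured check: degrading one channel of a
        coupled pair with independent noise lowers its median wSMI."""
        from oddball.synth import couple_sensors

        lower = 0
        n_seeds = 10
        for seed in range(n_seeds):
            epochs = _rest_epochs(montage, n_trials=10, seed=200 + seed)
            coupled = couple_sensors(epochs, [(0, 1)], lag=2, strength=1.0)
            noisy = coupled.copy()
            noisy.data[:, 1, :] += 2.0 * np.random.default_rng(seed).normal(
                size=noisy.data[:, 1, :].shape)
            v_clean = np.median(wsmi(coupled, tau=2).matrices[:, 0, 1])
            v_noisy = np.median(wsmi(noisy, tau=2).matrices[:, 0, 1])
            lower += v_noisy < v_clean
        assert lower >= n_seeds - 1


class TestClusterPermutation:
    def test_planted_cluster_detected(self):
        montage = disc_montage(24)
        rng = np.random.default_rng(10)
        n = 150
        a = rng.normal(size=(n, 24))
        b = rng.normal(size=(n, 24))
        seed_sensor = 5
        cluster = np.flatnonzero(montage.adjacency[seed_sensor])[:5]
        cluster = np.append(cluster, seed_sensor)
        a[:, cluster] += 1.0
        res = cluster_permutation_contrast(a, b, montage.adjacency,
                                           n_perm=500, rng_seed=11)
        assert res.any_significant
        top = res.clusters[0]
        assert top.p <= 0.05
        assert set(cluster) <= set(top.sensors)

    def test_null_false_positive_rate(self):
        montage = disc_montage(8)
        rng = np.random.default_rng(12)
        fp = 0
        n_runs = 60
        for _ in range(n_runs):
            a = rng.normal(size=(25, 8))
            b = rng.normal(size=(25, 8))
            res = cluster_permutation_contrast(a, b, montage.adjacency,
                                               n_perm=150, rng_seed=13)
            fp += res.any_significant
        assert fp / n_runs < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_runs)

    def test_matches_exhaustive_enumeration_on_tiny_problem(self):
        """Sampled permutation p agrees with full enumeration of all
        condition reassignments on 4 sensors x 6+6 epochs."""
        from itertools import combinations

        from oddball.montage import Montage
        from oddball.state_markers import _clusters_and_masses, _welch_t_map
        from scipy import stats

        adj = np.zeros((4, 4), dtype=bool)
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = True
        montage = Montage(names=("a", "b", "c", "d"),
                          positions=np.column_stack([np.arange(4), np.zeros(4)]),
                          adjacency=adj)
        rng = np.random.default_rng(14)
        a = rng.normal(size=(6, 4))
        b = rng.normal(size=(6, 4))
        a[:, :2] += 1.8
        res = cluster_permutation_contrast(a, b, adj, n_perm=4000, rng_seed=15)
        assert res.clusters, "expected at least one suprathreshold cluster"
        obs_mass = res.clusters[0].mass

        both = np.vstack([a, b])
        masses = []
        for pick in combinations(range(12), 6):
            pa = both[list(pick)]
            pb = both[[i for i in range(12) if i not in pick]]
            t, df = _welch_t_map(pa, pb)
            th = stats.t.ppf(0.975, df)
            cl = _clusters_and_masses(t, th, adj)
            masses.append(max((m for _, m, _ in cl), default=0.0))
        exact_p = np.mean(np.asarray(masses) >= obs_mass)
        assert res.clusters[0].p == pytest.approx(exact_p, abs=0.02)

    def test_exchangeable_under_epoch_reordering(self):
        montage = disc_montage(8)
        rng = np.random.default_rng(16)
        a = rng.normal(size=(20, 8))
        b = rng.normal(size=(20, 8))
        r1 = cluster_permutation_contrast(a, b, montage.adjacency, n_perm=300,
                                          rng_seed=17)
        perm = rng.permutation(20)
        r2 = cluster_permutation_contrast(a[perm], b, montage.adjacency,
                                          n_perm=300, rng_seed=17)
        assert np.allclose(r1.t_map, r2.t_map, atol=1e-12)


class TestSensorBayesMap:
    def test_null_vs_planted_effects(self):
        rng = np.random.default_rng(18)
        n = 150
        a = rng.normal(size=(n, 8))
        b = rng.normal(size=(n, 8))
        a[:, [2, 3]] += 1.0
        bf = sensor_bayes_map(a, b)
        assert np.median(np.delete(bf, [2, 3])) < 1.0
        assert bf[2] > 30 and bf[3] > 30

    def test_invariant_to_sensor_reordering(self):
        rng = np.random.default_rng(19)
        a = rng.normal(size=(30, 8))
        b = rng.normal(size=(30, 8))
        bf = sensor_bayes_map(a, b)
        order = rng.permutation(8)
        bf_perm = sensor_bayes_map(a[:, order], b[:, order])
        assert np.allclose(bf[order], bf_perm, rtol=1e-12)
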