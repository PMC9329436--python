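"""Quadratic-form distance: oracle agreement, metric axioms, binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellhealth.errors import IncompatibleHistogramError
from cellhealth.flow import DEFAULT_PANEL, EventMatrix
from cellhealth.qf import (Histogram, control_noise_floor, gaussian_kernel,
                           qf_distance, transform_and_bin)


def brute_force_qf(h, g, kernel):
    """Independent O(b²) double-sum oracle: sqrt(Σᵢⱼ dᵢ Aᵢⱼ dⱼ)."""
    d = h.mass - g.mass
    total = 0.0
    for i in range(len(d)):
        for j in range(len(d)):
            total += d[i] * kernel.matrix[i, j] * d[j]
    return np.sqrt(max(total, 0.0))


def random_histogram(rng, edges):
    mass = rng.dirichlet(np.ones(len(edges) - 1))
    return Histogram(bin_edges=edges, mass=mass, n_source_events=1000)


@pytest.fixture(scope="module")
def edges16():
    return np.linspace(0.0, 1.0, 17)


class TestQFDistance:
    def test_identical_histograms_give_zero(self, edges16):
        h = Histogram(edges16, np.full(16, 1 / 16), 100)
        assert qf_distance(h, h, gaussian_kernel(16)) == 0.0

    def test_hand_expanded_three_bin_case(self):
        edges = np.array([0.0, 1.0, 2.0, 3.0])
        h = Histogram(edges, np.array([1.0, 0.0, 0.0]), 1)
        g = Histogram(edges, np.array([0.0, 0.0, 1.0]), 1)
        identity = gaussian_kernel(3, bandwidth=1e-6)
        # d = (1,0,-1); dᵀId = 2 → sqrt(2)
        assert qf_distance(h, g, identity) == pytest.approx(np.sqrt(2))
        assert brute_force_qf(h, g, identity) == pytest.approx(np.sqrt(2))

    def test_matches_double_sum_oracle_on_random_pairs(self, edges16):
        rng = np.random.default_rng(7)
        kernel = gaussian_kernel(16)
        for _ in range(200):
            h, g = (random_histogram(rng, edges16) for _ in range(2))
            assert qf_distance(h, g, kernel) == pytest.approx(
                brute_force_qf(h, g, kernel), abs=1e-10)

    def test_metric_axioms_on_random_triples(self, edges16):
        """Non-negativity, symmetry, identity, triangle inequality with a
        strictly PD Gaussian kernel."""
        rng = np.random.default_rng(11)
        kernel = gaussian_kernel(16)
        for _ in range(1000):
            h, g, f = (random_histogram(rng, edges16) for _ in range(3))
            dhg = qf_distance(h, g, kernel)
            assert dhg >= 0
            assert dhg == pytest.approx(qf_distance(g, h, kernel), abs=1e-12)
            assert qf_distance(h, h, kernel) == pytest.approx(0.0, abs=1e-12)
            assert dhg <= (qf_distance(h, f, kernel)
                           + qf_distance(f, g, kernel) + 1e-10)

    def test_vanishing_bandwidth_recovers_euclidean(self, edges16):
        rng = np.random.default_rng(13)
        h, g = (random_histogram(rng, edges16) for _ in range(2))
        tiny = gaussian_kernel(16, bandwidth=1e-6)
        euclid = np.linalg.norm(h.mass - g.mass)
        assert qf_distance(h, g, tiny) == pytest.approx(euclid, rel=1e-9)

    def test_near_bin_shift_smaller_than_far_shift(self, edges16):
        """The similarity kernel tolerates near-bin shifts, unlike Euclidean."""
        kernel = gaussian_kernel(16, bandwidth=3.0)
        base = np.zeros(16); base[4] = 1.0
        near = np.zeros(16); near[5] = 1.0
        far = np.zeros(16); far[14] = 1.0
        h = Histogram(edges16, base, 1)
        assert qf_distance(h, Histogram(edges16, near, 1), kernel) < \
            qf_distance(h, Histogram(edges16, far, 1), kernel)

    def test_mismatched_binning_rejected(self, edges16):
        h = Histogram(edges16, np.full(16, 1 / 16), 1)
        g = Histogram(edges16 + 0.5, np.full(16, 1 / 16), 1)
        with pytest.raises(IncompatibleHistogramError):
            qf_distance(h, g, gaussian_kernel(16))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_distance_is_nonnegative_and_bounded(self, seed, edges16):
        rng = np.random.default_rng(seed)
        kernel = gaussian_kernel(16)
        h, g = (random_histogram(rng, edges16) for _ in range(2))
        d = qf_distance(h, g, kernel)
        assert 0 <= d <= np.sqrt(2) + 1e-9  # mass vectors live on the simplex


class TestTransformAndBin:
    def _matrix(self, col, rng):
        vals = rng.lognormal(5, 0.4, size=(len(col), 12))
        vals[:, 4] = col  # MitoSOXRed column
        return EventMatrix(well="w", channels=list(DEFAULT_PANEL.names),
                           values=vals)

    def test_point_mass_occupies_single_bin(self, rng):
        em = self._matrix(np.full(100, 250.0), rng)
        h = transform_and_bin(em, "MitoSOXRed", 16)
        assert np.max(h.mass) == pytest.approx(1.0)
        assert np.count_nonzero(h.mass) == 1

    def test_duplicating_events_leaves_histogram_unchanged(self, rng):
        col = rng.lognormal(5, 0.5, 400)
        em1 = self._matrix(col, rng)
        em2 = self._matrix(np.concatenate([col, col]), rng)
        edges = np.concatenate(([-np.inf], np.linspace(0, 4, 15), [np.inf]))
        h1 = transform_and_bin(em1, "MitoSOXRed", 16, edges)
        h2 = transform_and_bin(em2, "MitoSOXRed", 16, edges)
        np.testing.assert_allclose(h1.mass, h2.mass, atol=1e-12)

    def test_mass_matches_direct_counting_oracle(self, rng):
        col = rng.lognormal(0, 1, 1000)
        em = self._matrix(col, rng)
        edges = np.concatenate(([-np.inf], np.linspace(-3, 3, 63), [np.inf]))
        h = transform_and_bin(em, "MitoSOXRed", 64, edges)
        t = np.arcsinh(col / 150.0)
        counts = np.zeros(64)
        for v in t:  # independent per-event counting
            for b in range(64):
                if edges[b] <= v < edges[b + 1]:
                    counts[b] += 1
                    break
        np.testing.assert_allclose(h.mass, counts / counts.sum(), atol=1e-12)

    def test_scatter_channels_binned_linearly(self, rng):
        col = rng.lognormal(10.8, 0.3, 500)
        vals = rng.lognormal(5, 0.4, size=(500, 12))
        vals[:, 0] = col
        em = EventMatrix(well="w", channels=list(DEFAULT_PANEL.names),
                         values=vals)
        h = transform_and_bin(em, "FSC", 16)
        # linear edges should sit on the raw intensity scale
        finite = h.bin_edges[np.isfinite(h.bin_edges)]
        assert finite.max() > 1000


class TestSubsamplingStability:
    def test_half_splits_of_one_well_fall_below_noise_floor(self, small_config):
        """QF distance between two 50% subsamples of the same well stays
        below the control-resampling detection threshold almost always."""
        from cellhealth.simulate import null_profile, simulate_well_events

        kernel = gaussian_kernel(64)
        rng = np.random.default_rng(5)
        negs = [simulate_well_events(null_profile(), 0.0, small_config,
                                     well="n0",
                                     rng=np.random.default_rng(100))]
        floor = control_noise_floor(negs, "MitoSOXRed", kernel,
                                    n_resamples=100, quantile=0.99, rng=rng)
        well = simulate_well_events(null_profile(), 0.0, small_config,
                                    rng=np.random.default_rng(999))
        below = 0
        n_resamples = 100
        from cellhealth.qf import compute_shared_edges
        edges = compute_shared_edges(negs, "MitoSOXRed", 64)
        for _ in range(n_resamples):
            perm = rng.permutation(well.n_events)
            half = well.n_events // 2
            a = EventMatrix("a", well.channels, well.values[perm[:half]])
            b = EventMatrix("b", well.channels, well.values[perm[half:]])
            ha = transform_and_bin(a, "MitoSOXRed", 64, edges)
            hb = transform_and_bin(b, "MitoSOXRed", 64, edges)
            below += qf_distance(ha, hb, kernel) <= floor
        assert below / n_resamples >= 0.95
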