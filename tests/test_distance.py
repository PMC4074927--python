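import math

import numpy as np
import pytest
from scipy.stats import entropy as scipy_entropy

from entroclust import (
    distance_matrix,
    entropy_profile,
    histogram_entropies,
    js_divergence,
    js_metric,
    kl_divergence,
    make_binning,
)
from entroclust.distance import DistanceError, DistanceMatrix, read_phylip
from tests.test_distribution import profile_from_entropies


def js_mixture_entropy_form(p, q):
    """Independent oracle: D_JS = H((p+q)/2) - H(p)/2 - H(q)/2 (scipy entropies)."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    m = (p + q) / 2
    return scipy_entropy(m, base=2) - scipy_entropy(p, base=2) / 2 - scipy_entropy(q, base=2) / 2


def random_prob_vectors(rng, n_pairs, n_bins=64, sparse_fraction=0.3):
    """Random pairs, a fraction with disjointly zeroed bins to exercise 0-handling."""
    for k in range(n_pairs):
        p = rng.dirichlet(np.ones(n_bins))
        q = rng.dirichlet(np.ones(n_bins))
        if k % int(1 / sparse_fraction) == 0:
            p[rng.choice(n_bins, 10, replace=False)] = 0
            q[rng.choice(n_bins, 10, replace=False)] = 0
            p, q = p / p.sum(), q / q.sum()
        yield p, q


class TestKL:
    def test_identity(self):
        assert kl_divergence([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_hand_cases(self):
        assert kl_divergence([1, 0], [0.75, 0.25]) == pytest.approx(
            math.log2(4 / 3), abs=1e-12
        )
        assert kl_divergence([0.5, 0.5], [0.75, 0.25]) == pytest.approx(0.2075187496, abs=1e-9)

    def test_support_violation_and_length_mismatch(self):
        with pytest.raises(DistanceError):
            kl_divergence([0.5, 0.5], [1.0, 0.0])
        with pytest.raises(DistanceError):
            kl_divergence([0.5, 0.5], [0.5, 0.25, 0.25])

    def test_non_negative_on_random_pairs(self, rng):
        for p, q in random_prob_vectors(rng, 200):
            m = (p + q) / 2
            assert kl_divergence(p, m) >= 0


class TestJS:
    def test_hand_cases(self):
        assert js_divergence([1, 0], [1, 0]) == 0.0
        assert js_divergence([1, 0], [0, 1]) == pytest.approx(1.0, abs=1e-12)
        assert js_divergence([1, 0], [0.5, 0.5]) == pytest.approx(0.311278, abs=1e-6)
        assert js_metric([1, 0], [0.5, 0.5]) == pytest.approx(0.557923, abs=1e-6)

    def test_oracle_equivalence_symmetry_bounds(self, rng):
        for p, q in random_prob_vectors(rng, 1000):
            d = js_divergence(p, q)
            assert d == pytest.approx(js_mixture_entropy_form(p, q), abs=1e-12)
            assert d == pytest.approx(js_divergence(q, p), abs=1e-12)
            assert 0 <= d <= 1.0 + 1e-12

    def test_triangle_inequality_of_sqrt_js(self, rng):
        for _ in range(1000):
            p, q, r = (rng.dirichlet(np.ones(64)) for _ in range(3))
            assert js_metric(p, r) <= js_metric(p, q) + js_metric(q, r) + 1e-9

    def test_zero_iff_equal(self, rng):
        p = rng.dirichlet(np.ones(64))
        assert js_divergence(p, p.copy()) == pytest.approx(0.0, abs=1e-12)
        q = rng.dirichlet(np.ones(64))
        assert js_divergence(p, q) > 1e-6

    def test_mismatched_binning_refused(self, random_genome):
        prof = entropy_profile(random_genome, 100)
        d64 = histogram_entropies(prof, make_binning(64))
        d32 = histogram_entropies(prof, make_binning(32))
        with pytest.raises(DistanceError):
            js_divergence(d64, d32)


class TestDistanceMatrix:
    def _dists(self, vectors, labels):
        scheme = make_binning(len(vectors[0]), 0, 2)
        out = []
        for v, lab in zip(vectors, labels):
            n = 100
            counts = (np.asarray(v) * n).round().astype(int)
            prof = profile_from_entropies(
                np.repeat((scheme.edges[:-1] + scheme.bin_width / 2), counts), label=lab
            )
            out.append(histogram_entropies(prof, scheme))
        return out

    def test_identical_distributions_zero_matrix(self):
        dists = self._dists([[1, 0], [1, 0]], ["a", "b"])
        dm = distance_matrix(dists)
        np.testing.assert_allclose(dm.values, 0.0, atol=1e-12)

    def test_three_way_hand_case(self):
        dists = self._dists([[1, 0], [0, 1], [0.5, 0.5]], ["a", "b", "c"])
        dm = distance_matrix(dists)
        assert dm[("a", "b")] == pytest.approx(1.0, abs=1e-9)
        assert dm[("a", "c")] == pytest.approx(0.557923, abs=1e-6)
        assert dm[("b", "c")] == pytest.approx(0.557923, abs=1e-6)
        # invariants
        np.testing.assert_allclose(dm.values, dm.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(dm.values), 0, atol=1e-12)
        assert (dm.values <= 1.0 + 1e-12).all()

    def test_single_distribution_and_duplicate_labels_rejected(self):
        dists = self._dists([[1, 0]], ["a"])
        with pytest.raises(DistanceError):
            distance_matrix(dists)
        dup = self._dists([[1, 0], [0, 1]], ["a", "a"])
        with pytest.raises(DistanceError):
            distance_matrix(dup)

    def test_raw_js_mode_is_square_of_metric(self):
        dists = self._dists([[1, 0], [0.5, 0.5]], ["a", "b"])
        raw = distance_matrix(dists, metric="raw_js")
        sqrt = distance_matrix(dists, metric="sqrt_js")
        np.testing.assert_allclose(sqrt.values**2, raw.values, atol=1e-12)

    def test_phylip_round_trip(self):
        dm = DistanceMatrix(
            labels=("a", "b", "c"),
            values=np.array([[0, 0.5, 0.25], [0.5, 0, 0.125], [0.25, 0.125, 0]]),
        )
        back = read_phylip(dm.to_phylip())
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.values, dm.values, atol=1e-6)
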