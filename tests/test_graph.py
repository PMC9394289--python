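"""Adjacency construction, Laplacian, and Chebyshev filtering."""

import numpy as np
import pytest
from numpy.polynomial import chebyshev as npcheb

from crgcn import (
    ChannelGraph,
    calibrate_delta,
    chebyshev_matrices,
    chebyshev_terms,
    connectivity_adjacency,
    distance_adjacency,
    fuse,
    laplacian,
    spectral_decomposition,
)
from crgcn.montage import Montage


class TestDistanceAdjacency:
    def test_inverse_square_values(self, line_montage):
        # with delta = 1: d^2 = 1 -> capped at 1; d^2 = 4 -> 0.25
        g = distance_adjacency(line_montage, delta=1.0)
        assert g.adjacency[0, 1] == 1.0
        assert g.adjacency[0, 2] == 0.25
        assert g.adjacency[0, 3] == pytest.approx(1 / 9)
        assert np.allclose(g.adjacency, g.adjacency.T)
        assert np.all(np.diag(g.adjacency) == 1.0)

    def test_entries_bounded_by_cap(self, montage32):
        g = distance_adjacency(montage32, delta=0.05)
        assert np.all(g.adjacency >= 0) and np.all(g.adjacency <= 1)

    def test_coincident_electrodes_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            Montage(("a", "b"), np.zeros((2, 3)))

    def test_bad_delta(self, line_montage):
        with pytest.raises(ValueError):
            distance_adjacency(line_montage, delta=0.0)


class TestCalibrateDelta:
    def test_bundled_montage_hits_20_percent_retention(self, montage32):
        delta = calibrate_delta(montage32, target_fraction=0.2, cutoff=0.1)
        g = distance_adjacency(montage32, delta)
        off = g.adjacency[~np.eye(32, dtype=bool)]
        frac = (off > 0.1).mean()
        # one edge-count step = one unordered pair = 2 of the 992 entries
        assert 0.2 <= frac <= 0.2 + 2 / 992 + 1e-12

    def test_target_one_saturates_all(self, line_montage):
        delta = calibrate_delta(line_montage, target_fraction=1.0)
        g = distance_adjacency(line_montage, delta)
        off = g.adjacency[~np.eye(4, dtype=bool)]
        assert np.all(off > 0.1)

    def test_small_target_keeps_single_edge_step(self, montage32):
        delta = calibrate_delta(montage32, target_fraction=1e-9)
        g = distance_adjacency(montage32, delta)
        off = g.adjacency[~np.eye(32, dtype=bool)]
        assert (off > 0.1).sum() == 2  # one symmetric pair

    def test_matches_sorted_quantile_oracle(self, montage32):
        # oracle: sort all off-diagonal squared distances, delta must retain
        # exactly ceil(0.2 * n_pairs) pairs
        d = montage32.pairwise_distances()
        d2 = np.sort(d[np.triu_indices(32, 1)] ** 2)
        m = int(np.ceil(0.2 * d2.size))
        delta = calibrate_delta(montage32, 0.2, 0.1)
        retained = (d2 < delta / 0.1).sum()
        assert retained == m

    @pytest.mark.parametrize("t_lo,t_hi", [(0.1, 0.3), (0.3, 0.7), (0.5, 0.9)])
    def test_retention_monotone_in_delta(self, montage32, t_lo, t_hi):
        d_lo = calibrate_delta(montage32, t_lo)
        d_hi = calibrate_delta(montage32, t_hi)
        assert d_hi > d_lo
        off = ~np.eye(32, dtype=bool)
        f_lo = (distance_adjacency(montage32, d_lo).adjacency[off] > 0.1).mean()
        f_hi = (distance_adjacency(montage32, d_hi).adjacency[off] > 0.1).mean()
        assert f_hi >= f_lo


class TestConnectivityAdjacency:
    def test_identical_and_anticorrelated_channels(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        z = rng.standard_normal(200)
        g = connectivity_adjacency(np.stack([x, x, -x, z]), lam=0.98)
        assert g.adjacency[0, 1] == pytest.approx(1.0)
        assert g.adjacency[0, 2] == pytest.approx(-1.0)  # sign retained
        assert g.adjacency[0, 3] == 0.0  # independent noise below threshold

    def test_independent_noise_all_zero_offdiag(self):
        rng = np.random.default_rng(7)
        g = connectivity_adjacency(rng.standard_normal((6, 1000)), lam=0.98)
        off = g.adjacency[~np.eye(6, dtype=bool)]
        assert np.all(off == 0.0)

    def test_lambda_monotonicity(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((1, 300))
        sig = base + 0.15 * rng.standard_normal((8, 300))
        counts = [
            np.count_nonzero(
                connectivity_adjacency(sig, lam).adjacency[~np.eye(8, dtype=bool)]
            )
            for lam in (0.5, 0.9, 0.98, 0.999)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_gate(self):
        rng = np.random.default_rng(1)
        sig = rng.standard_normal((5, 400))
        g = connectivity_adjacency(sig, lam=0.3)
        off = g.adjacency[~np.eye(5, dtype=bool)]
        nz = off[off != 0]
        assert np.all(np.abs(nz) > 0.3)

    def test_zero_variance_channel_rejected(self):
        sig = np.vstack([np.ones(50), np.arange(50.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            connectivity_adjacency(sig)


class TestFusion:
    def test_additive_identity_and_commutativity(self, line_montage):
        a = distance_adjacency(line_montage, delta=1.0)
        zero = ChannelGraph(np.zeros((4, 4)), "connectivity")
        assert np.array_equal(fuse(a, zero).adjacency, a.adjacency)
        rng = np.random.default_rng(5)
        sig = rng.standard_normal((4, 100))
        b = connectivity_adjacency(sig, lam=0.0)
        assert np.array_equal(
            fuse(a, b).adjacency, fuse(b, a).adjacency
        )

    def test_entrywise_sum_and_edge_preservation(self, line_montage):
        a = distance_adjacency(line_montage, delta=1.0)
        b = ChannelGraph(np.full((4, 4), 0.99) - 0.99 * np.eye(4) + np.eye(4),
                         "connectivity")
        c = fuse(a, b)
        assert c.adjacency[0, 2] == pytest.approx(0.25 + 0.99)
        assert c.provenance == "fused"
        # no retained edge from either parent is lost
        parents_nz = (a.adjacency != 0) | (b.adjacency != 0)
        assert np.all(c.adjacency[parents_nz] != 0)
        assert np.allclose(c.adjacency, c.adjacency.T)

    def test_dimension_mismatch(self, line_montage, montage32):
        a = distance_adjacency(line_montage, 1.0)
        b = distance_adjacency(montage32, 1.0)
        with pytest.raises(ValueError, match="mismatch"):
            fuse(a, b)


class TestLaplacian:
    def test_two_node_single_edge(self):
        # normalization cancels the edge weight
        for w in (0.5, 1.0, 3.0):
            C = np.array([[0.0, w], [w, 0.0]])
            L, _, lmax = laplacian(C)
            assert np.allclose(L, [[1, -1], [-1, 1]])
            assert lmax == pytest.approx(2.0)

    def test_self_loops_only_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            laplacian(np.eye(3))

    def test_eigenvalues_within_standard_bound(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = rng.integers(3, 9)
            C = rng.random((n, n))
            C = 0.5 * (C + C.T)
            w = np.linalg.eigvalsh(laplacian(C)[0])
            assert w.min() >= -1e-10 and w.max() <= 2 + 1e-10

    def test_scaled_spectrum_ranges(self):
        rng = np.random.default_rng(2)
        C = rng.random((6, 6))
        C = 0.5 * (C + C.T)
        _, lt_printed, _ = laplacian(C, scaling="as_printed")
        _, lt_cheb, _ = laplacian(C, scaling="chebnet")
        wp = np.linalg.eigvalsh(lt_printed)
        wc = np.linalg.eigvalsh(lt_cheb)
        assert wp.min() >= -1 - 1e-10 and wp.max() <= 1e-10
        assert wc.min() >= -1 - 1e-10 and wc.max() <= 1 + 1e-10

    def test_degree_rule_handles_signed_entries(self):
        C = np.array([[1.0, -0.99, 0.3],
                      [-0.99, 1.0, 0.0],
                      [0.3, 0.0, 1.0]])
        L, _, _ = laplacian(C)
        assert np.all(np.isfinite(L))

    def test_nonpositive_degree_named(self):
        C = np.zeros((3, 3))
        with pytest.raises(ValueError, match="channel index 0"):
            laplacian(C)

    def test_decomposition_reconstructs(self):
        rng = np.random.default_rng(4)
        C = rng.random((7, 7))
        C = 0.5 * (C + C.T)
        L, _, _ = laplacian(C)
        dec = spectral_decomposition(L)
        U, lam = dec.eigenvectors, dec.eigenvalues
        assert np.allclose(U @ np.diag(lam) @ U.T, L, atol=1e-8)
        assert np.allclose(U.T @ U, np.eye(7), atol=1e-8)


class TestChebyshev:
    def test_k1_returns_input_only(self):
        x = np.arange(6.0).reshape(3, 2)
        terms = chebyshev_terms(np.eye(3), x, K=1)
        assert len(terms) == 1
        assert np.array_equal(terms[0], x)

    def test_scalar_graph_recursion(self):
        # T_0 = 1, T_1 = 0.5, T_2(0.5) = 2*0.25 - 1 = -0.5
        terms = chebyshev_terms(np.array([[0.5]]), np.array([1.0]), K=3)
        assert [t.item() for t in terms] == pytest.approx([1.0, 0.5, -0.5])

    def test_scalar_consistency_with_cosine_form(self):
        xs = np.linspace(-1, 1, 101)
        for k in range(11):
            got = np.array([
                chebyshev_terms(np.array([[x]]), np.array([1.0]), K=k + 1)[-1][0]
                for x in xs
            ])
            assert np.allclose(got, np.cos(k * np.arccos(xs)), atol=1e-10)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            chebyshev_terms(np.eye(2), np.ones(2), K=0)

    @pytest.mark.parametrize("scaling", ["as_printed", "chebnet"])
    def test_filter_matches_eigendecomposition(self, scaling):
        """The polynomial-in-L~ filter equals explicit spectral filtering
        U g(Lambda) U^T x, with g evaluated by numpy's Chebyshev series."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(2, 11))
            K = int(rng.integers(1, 7))
            C = rng.random((n, n))
            C = 0.5 * (C + C.T)
            L, Lt, lmax = laplacian(C, scaling=scaling)
            x = rng.standard_normal(n)
            theta = rng.standard_normal(K)
            terms = chebyshev_terms(Lt, x, K)
            y_cheb = sum(t * term for t, term in zip(theta, terms))
            dec = spectral_decomposition(L)
            scale = 1.0 if scaling == "as_printed" else 2.0
            lam_scaled = scale * dec.eigenvalues / lmax - 1.0
            g = npcheb.chebval(lam_scaled, theta)
            y_direct = dec.eigenvectors @ (g * (dec.eigenvectors.T @ x))
            assert np.allclose(y_cheb, y_direct, atol=1e-8)

    def test_matrix_stack_matches_terms(self):
        rng = np.random.default_rng(9)
        C = rng.random((5, 5))
        C = 0.5 * (C + C.T)
        _, Lt, _ = laplacian(C)
        x = rng.standard_normal((5, 3))
        mats = chebyshev_matrices(Lt, 4)
        terms = chebyshev_terms(Lt, x, 4)
        for Tk, term in zip(mats, terms):
            assert np.allclose(Tk @ x, term, atol=1e-12)
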