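"""Channel-graph construction and spectral machinery.

Two complementary adjacency matrices over EEG channels are built and fused:

* a *topological* (distance) matrix ``A`` with entries
  ``A_ij = min(1, delta / d_ij**2)`` — an inverse-square law over 3D
  inter-electrode distance, capturing local spatial relationships;
* a *functional-connectivity* matrix ``B`` holding the Pearson correlation
  ``p_ij`` between channel feature vectors wherever ``|p_ij|`` exceeds a
  threshold ``lambda`` (signed value retained), capturing global
  relationships.

The fused adjacency is the entrywise sum ``C = A + B``. From ``C`` the
normalized graph Laplacian ``L = I - D^{-1/2} C D^{-1/2}`` is formed and
rescaled to the Chebyshev domain, enabling K-term polynomial spectral
filtering without eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .montage import Montage

__all__ = [
    "ChannelGraph",
    "SpectralDecomposition",
    "distance_adjacency",
    "calibrate_delta",
    "connectivity_adjacency",
    "fuse",
    "laplacian",
    "spectral_decomposition",
    "chebyshev_terms",
    "chebyshev_matrices",
]

Provenance = Literal["distance", "connectivity", "fused"]
LaplacianScaling = Literal["as_printed", "chebnet"]


@dataclass
class ChannelGraph:
    """A symmetric weighted graph over EEG channels with its Laplacians.

    ``scaled_laplacian`` uses the rescaling ``L/lambda_max - I`` by default,
    which maps the Laplacian spectrum from [0, lambda_max] into [-1, 0] —
    inside the Chebyshev domain [-1, 1]. The conventional ChebNet rescaling
    ``2L/lambda_max - I`` is available via ``scaling="chebnet"``.
    """

    adjacency: np.ndarray
    provenance: Provenance
    channel_names: tuple[str, ...] | None = None
    delta: float | None = None
    lam: float | None = None
    scaling: LaplacianScaling = "as_printed"
    _lap: tuple[np.ndarray, np.ndarray, float] | None = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        C = np.asarray(self.adjacency, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError(f"adjacency must be square, got {C.shape}")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric (tol 1e-12)")
        self.adjacency = C

    # Laplacians are computed lazily: intermediate graphs (e.g. a
    # connectivity matrix about to be fused) may be spectrally degenerate
    # on their own without that being an error.
    def _laplacians(self) -> tuple[np.ndarray, np.ndarray, float]:
        if self._lap is None:
            self._lap = laplacian(self.adjacency, scaling=self.scaling)
        return self._lap

    @property
    def laplacian(self) -> np.ndarray:
        return self._laplacians()[0]

    @property
    def scaled_laplacian(self) -> np.ndarray:
        return self._laplacians()[1]

    @property
    def lambda_max(self) -> float:
        return self._laplacians()[2]

    @property
    def n_channels(self) -> int:
        return self.adjacency.shape[0]


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigendecomposition ``L = U diag(eigenvalues) U^T`` of a Laplacian."""

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray


def distance_adjacency(
    montage: Montage, delta: float, *, diagonal: float = 1.0
) -> ChannelGraph:
    """Distance-based adjacency ``A_ij = min(1, delta / d_ij^2)``.

    ``delta`` is a calibration constant: the entry saturates at 1 for any
    pair closer than ``sqrt(delta)``, and decays with the inverse square of
    distance beyond. The diagonal defaults to 1 (the ``d -> 0`` limit of the
    formula, which saturates the cap).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    d = montage.pairwise_distances()
    n = len(montage)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident electrodes: zero off-diagonal distance")
    with np.errstate(divide="ignore"):
        A = np.minimum(1.0, delta / d**2)
    A[np.diag_indices(n)] = diagonal
    return ChannelGraph(
        A, "distance", channel_names=montage.names, delta=float(delta)
    )


def calibrate_delta(
    montage: Montage, target_fraction: float = 0.2, cutoff: float = 0.1
) -> float:
    """Choose ``delta`` so a target fraction of connections is retained.

    A connection is *retained* (nonignorable) when its adjacency entry
    exceeds ``cutoff``, i.e. when ``d_ij^2 < delta / cutoff``. The retained
    fraction is therefore a step function of ``delta`` over the sorted
    squared distances; this picks the smallest achievable fraction that is
    >= ``target_fraction``, placing the threshold halfway between the two
    bracketing squared distances (deterministic, no search).
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must lie in (0, 1]")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = montage.pairwise_distances()
    n = len(montage)
    iu = np.triu_indices(n, k=1)
    d2 = np.sort(d[iu] ** 2)
    n_pairs = d2.size
    m = int(np.ceil(target_fraction * n_pairs))
    m = min(max(m, 1), n_pairs)
    # tied squared distances cannot be split; take the whole tied block
    while m < n_pairs and d2[m] == d2[m - 1]:
        m += 1
    if m == n_pairs:
        thresh = d2[-1] * (1 + 1e-9)
    else:
        thresh = 0.5 * (d2[m - 1] + d2[m])
    return float(cutoff * thresh)


def connectivity_adjacency(
    node_signals: np.ndarray,
    lam: float = 0.98,
    *,
    channel_names: tuple[str, ...] | None = None,
    diagonal: float = 1.0,
) -> ChannelGraph:
    """Thresholded-correlation functional-connectivity adjacency.

    Parameters
    ----------
    node_signals : ndarray, shape (n_channels, n_observations)
        One feature vector per channel — typically each channel's normalized
        band-PSD values concatenated over the training segments, or a raw
        time series.
    lam : float
        Correlation threshold; the signed Pearson correlation ``p_ij`` is
        kept where ``|p_ij| > lam`` and zeroed elsewhere.
    """
    X = np.asarray(node_signals, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"node_signals must be 2D (channels x obs), got {X.shape}")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 observations per channel")
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0, 1]")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance channel at index {bad}")
    p = np.corrcoef(X)
    B = np.where(np.abs(p) > lam, p, 0.0)
    B = 0.5 * (B + B.T)  # guard against eps-level asymmetry from corrcoef
    B[np.diag_indices(X.shape[0])] = diagonal
    return ChannelGraph(B, "connectivity", channel_names=channel_names, lam=float(lam))


def fuse(a: ChannelGraph, b: ChannelGraph) -> ChannelGraph:
    """Entrywise sum ``C = A + B`` of two channel graphs (matrix fusion)."""
    if a.adjacency.shape != b.adjacency.shape:
        raise ValueError(
            f"dimension mismatch: {a.adjacency.shape} vs {b.adjacency.shape}"
        )
    if (
        a.channel_names is not None
        and b.channel_names is not None
        and a.channel_names != b.channel_names
    ):
        raise ValueError("channel orderings differ between graphs")
    return ChannelGraph(
        a.adjacency + b.adjacency,
        "fused",
        channel_names=a.channel_names or b.channel_names,
        delta=a.delta if a.delta is not None else b.delta,
        lam=a.lam if a.lam is not None else b.lam,
        scaling=a.scaling,
    )


def laplacian(
    C: np.ndarray, *, scaling: LaplacianScaling = "as_printed"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalized graph Laplacian, its Chebyshev rescaling, and lambda_max.

    ``L = I - D^{-1/2} C D^{-1/2}`` with degrees ``D_ii = sum_j |C_ij|``;
    absolute values keep ``D^{-1/2}`` real when signed correlations make
    some entries negative. Returns ``(L, L_scaled, lambda_max)`` where
    ``L_scaled = L/lambda_max - I`` ("as_printed", spectrum in [-1, 0]) or
    ``2L/lambda_max - I`` ("chebnet", spectrum in [-1, 1]).
    """
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    deg = np.abs(C).sum(axis=1)
    if np.any(deg <= 0):
        bad = int(np.flatnonzero(deg <= 0)[0])
        raise ValueError(f"nonpositive degree for channel index {bad}")
    dinv = 1.0 / np.sqrt(deg)
    n = C.shape[0]
    L = np.eye(n) - (dinv[:, None] * C * dinv[None, :])
    L = 0.5 * (L + L.T)
    lmax = float(np.linalg.eigvalsh(L)[-1])
    if lmax <= 1e-12:
        raise ValueError(
            "Laplacian spectrum is degenerate (no off-diagonal structure); "
            "cannot rescale to the Chebyshev domain"
        )
    if scaling == "as_printed":
        Lt = L / lmax - np.eye(n)
    elif scaling == "chebnet":
        Lt = 2.0 * L / lmax - np.eye(n)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown scaling {scaling!r}")
    return L, Lt, lmax


def spectral_decomposition(L: np.ndarray) -> SpectralDecomposition:
    """Eigendecomposition of a symmetric Laplacian (ascending eigenvalues)."""
    w, U = np.linalg.eigh(np.asarray(L, dtype=float))
    return SpectralDecomposition(eigenvectors=U, eigenvalues=w)


def chebyshev_terms(Lt: np.ndarray, x: np.ndarray, K: int) -> list[np.ndarray]:
    """Chebyshev recursion terms ``T_k(Lt) x`` for ``k = 0 .. K-1``.

    ``T_0 = x``, ``T_1 = Lt x``, ``T_k = 2 Lt T_{k-1} - T_{k-2}``. The K
    terms are the inputs to the learnable spectral filter
    ``y = sum_k theta_k T_k(Lt) x``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    Lt = np.asarray(Lt, dtype=float)
    x = np.asarray(x, dtype=float)
    terms = [x]
    if K >= 2:
        terms.append(Lt @ x)
    for _ in range(2, K):
        terms.append(2.0 * (Lt @ terms[-1]) - terms[-2])
    return terms


def chebyshev_matrices(Lt: np.ndarray, K: int) -> np.ndarray:
    """Stack of matrices ``T_k(Lt)`` for ``k = 0 .. K-1``, shape (K, N, N).

    Precomputing these once per graph makes each forward pass a plain
    sequence of matrix products.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    Lt = np.asarray(Lt, dtype=float)
    n = Lt.shape[0]
    return np.stack(chebyshev_terms(Lt, np.eye(n), K))
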