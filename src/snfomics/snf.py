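"""Similarity network fusion (SNF) of per-modality sample-similarity graphs.

Each modality's samples x features matrix is turned into a dense affinity
network with a locally scaled Gaussian kernel on squared Euclidean
distances.  The networks are then merged by an iterative cross-diffusion
process: each network's row-stochastic transition matrix is repeatedly
propagated through its own K-nearest-neighbour sparsified kernel while
borrowing the complementary networks' global structure, until a fused
network emerges that is supported by all modalities.

Kernel dialect
--------------
For a squared-distance matrix ``D`` the local scale is

    eps(i, j) = (mu_i + mu_j + D(i, j)) / 3

where ``mu_i`` is the mean of ``D`` over sample i's K nearest neighbours
(self excluded).  The affinity is the Gaussian density of ``D(i, j)`` at
mean 0 with standard deviation ``alpha * eps(i, j)``, symmetrized by
averaging with its transpose.  With the recommended ``K=40, alpha=0.5,
T=50`` this matches the parameterization popularized by the reference SNF
tooling, so those defaults carry their conventional meaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import OmicsMatrix

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class SNFParams:
    """Fusion hyper-parameters.

    K : number of nearest neighbours for local scales and sparse kernels.
    alpha : multiplier on the local scale in the Gaussian kernel width.
    T : number of cross-diffusion iterations (fixed count, no early stop).
    """

    K: int = 40
    alpha: float = 0.5
    T: int = 50

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class AffinityMatrix:
    """Symmetric non-negative sample x sample similarity network."""

    sample_ids: list[str]
    W: np.ndarray
    params: SNFParams
    #: per-pair kernel scales eps(i, j), retained for audit (None after fusion)
    local_scales: np.ndarray | None = None
    #: Frobenius norm of the per-iteration change of each transition matrix,
    #: recorded during fusion purely as a convergence diagnostic
    convergence: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        n = len(self.sample_ids)
        if W.shape != (n, n):
            raise ValueError(f"W shape {W.shape} does not match {n} sample IDs")
        if not np.all(np.isfinite(W)):
            raise ValueError("W has non-finite entries")
        if np.nanmax(np.abs(W - W.T)) > 1e-10:
            raise ValueError("W is not symmetric")
        if W.min() < 0:
            raise ValueError("W has negative entries")
        self.W = W


def effective_k(K: int, n: int) -> int:
    """Cap the neighbour count for small networks.

    When ``n <= K`` (scaled-down runs, sweep subsamples) the neighbour count
    is capped at ``floor((n - 1) / 2)`` with a logged warning, so the
    pipeline keeps running instead of failing.
    """
    if n > K:
        return K
    capped = max(1, (n - 1) // 2)
    logger.warning("K=%d >= n=%d; capping K at %d", K, n, capped)
    return capped


def squared_distance_matrix(X: OmicsMatrix | np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances D(i,j) = sum_f (x_if - x_jf)^2."""
    values = X.values if isinstance(X, OmicsMatrix) else np.asarray(X, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if np.isnan(values).any():
        raise ValueError("distance computation requires fully imputed data")
    D = squareform(pdist(values, metric="sqeuclidean"))
    return D


def affinity_matrix(
    D: np.ndarray,
    params: SNFParams = SNFParams(),
    sample_ids: list[str] | None = None,
) -> AffinityMatrix:
    """Locally scaled Gaussian kernel affinity from a squared-distance matrix."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if np.nanmax(np.abs(D - D.T)) > 1e-8:
        raise ValueError("D must be symmetric")
    if D.min() < 0:
        raise ValueError("D must be non-negative")
    if n <= params.K:
        raise ValueError(
            f"n={n} <= K={params.K}: cap K (e.g. via effective_k, which uses "
            f"floor((n-1)/2)={max(1, (n - 1) // 2)}) before building affinities"
        )
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]

    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    # mean distance to the K nearest neighbours, self excluded
    sortedD = np.sort(D, axis=1)
    mu = sortedD[:, 1 : params.K + 1].mean(axis=1) + _EPS
    scales = (mu[:, None] + mu[None, :] + D) / 3.0
    scales = np.maximum(scales, _EPS)
    sigma = params.alpha * scales
    dens = np.exp(-(D**2) / (2.0 * sigma**2)) / (sigma * np.sqrt(2.0 * np.pi))
    W = 0.5 * (dens + dens.T)
    return AffinityMatrix(sample_ids=list(sample_ids), W=W, params=params, local_scales=scales)


def _full_kernel_array(W: np.ndarray) -> np.ndarray:
    """Row-stochastic transition matrix: off-diagonal mass halved, diag 1/2."""
    W = np.asarray(W, dtype=float)
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsums = off.sum(axis=1)
    if np.any(rowsums <= 0):
        bad = np.where(rowsums <= 0)[0]
        raise ValueError(f"rows with zero off-diagonal mass: {bad.tolist()}")
    P = off / (2.0 * rowsums[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def full_kernel(W: AffinityMatrix) -> np.ndarray:
    """Global row-stochastic kernel P with P(i,i) = 1/2."""
    return _full_kernel_array(W.W)


def _local_kernel_array(W: np.ndarray, K: int) -> np.ndarray:
    n = W.shape[0]
    if n <= K:
        raise ValueError(f"n={n} <= K={K}")
    masked = W.copy().astype(float)
    np.fill_diagonal(masked, -np.inf)
    S = np.zeros_like(masked)
    for i in range(n):
        # stable sort: ties at the K-th neighbour resolved by sample order
        order = np.argsort(-masked[i], kind="stable")[:K]
        weights = W[i, order]
        total = weights.sum()
        if total <= 0:
            # degenerate all-zero neighbourhood: uniform over the K nearest
            S[i, order] = 1.0 / K
        else:
            S[i, order] = weights / total
    return S


def local_kernel(W: AffinityMatrix, K: int | None = None) -> np.ndarray:
    """K-nearest-neighbour sparsified row-stochastic kernel S."""
    return _local_kernel_array(W.W, W.params.K if K is None else K)


def fuse(W_list: list[AffinityMatrix], params: SNFParams | None = None) -> AffinityMatrix:
    """Cross-diffuse a list of affinity networks into one fused network.

    Starting from each modality's full kernel ``P_v`` and sparse kernel
    ``S_v``, iterate for T rounds

        P_v  <-  S_v @ (mean of the other modalities' P) @ S_v.T

    re-normalizing rows and symmetrizing (with the 1/2-diagonal convention
    of the full kernel) after every round.  The output is the average of
    the final matrices, renormalized and symmetrized the same way.

    A single-modality input passes through the full kernel unchanged.
    """
    if not W_list:
        raise ValueError("no affinity matrices supplied")
    if params is None:
        params = W_list[0].params
    ids = W_list[0].sample_ids
    n = len(ids)
    for W in W_list[1:]:
        if W.sample_ids != ids:
            raise ValueError("affinity matrices must share the identical sample set and order")

    if len(W_list) == 1:
        P = _full_kernel_array(W_list[0].W)
        P = 0.5 * (P + P.T)
        return AffinityMatrix(sample_ids=ids, W=P, params=params)

    K = params.K if n > params.K else effective_k(params.K, n)
    m = len(W_list)
    P = [_full_kernel_array(W.W) for W in W_list]
    P = [0.5 * (Pv + Pv.T) for Pv in P]
    S = [_local_kernel_array(W.W, K) for W in W_list]

    deltas: list[float] = []
    for _ in range(params.T):
        new_P = []
        for v in range(m):
            others = sum(P[k] for k in range(m) if k != v) / (m - 1)
            new_P.append(S[v] @ others @ S[v].T)
        delta = 0.0
        for v in range(m):
            Pv = _full_kernel_array(new_P[v])
            Pv = 0.5 * (Pv + Pv.T)
            delta += float(np.linalg.norm(Pv - P[v]))
            P[v] = Pv
        deltas.append(delta)

    fused = sum(P) / m
    fused = 0.5 * (fused + fused.T)
    fused = _full_kernel_array(fused)
    fused = 0.5 * (fused + fused.T)
    return AffinityMatrix(sample_ids=ids, W=fused, params=params, convergence=deltas)


def affinity_from_matrix(X: OmicsMatrix, params: SNFParams = SNFParams()) -> AffinityMatrix:
    """Convenience: distances -> kernel for one processed modality."""
    D = squared_distance_matrix(X)
    k = effective_k(params.K, X.n_samples)
    p = params if k == params.K else SNFParams(K=k, alpha=params.alpha, T=params.T)
    return affinity_matrix(D, p, sample_ids=X.sample_ids)


def fused_network_heatmap_export(W: AffinityMatrix, labels, path) -> "pd.DataFrame":
    """Write the network with samples ordered by cluster, for external plotting.

    ``labels`` is a Partition (see :mod:`snfomics.clustering`); the exported
    tab-delimited matrix has contiguous cluster blocks, which makes planted
    block structure visible in any heatmap viewer.
    """
    import pandas as pd

    series = labels.to_series().loc[W.sample_ids]
    order = np.lexsort((np.array(W.sample_ids, dtype=object), series.to_numpy()))
    ordered_ids = [W.sample_ids[i] for i in order]
    frame = pd.DataFrame(W.W[np.ix_(order, order)], index=ordered_ids, columns=ordered_ids)
    frame.to_csv(path, sep="\t")
    return frame
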