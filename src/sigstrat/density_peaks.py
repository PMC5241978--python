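"""Prototype discovery by density-peak clustering.

For every point two quantities are computed from the pairwise distance
matrix: ``rho``, the local density (number of neighbours inside a cutoff
radius ``d_c``, or a Gaussian-kernel analogue), and ``delta``, the minimum
distance to any point of higher local density.  Points where ``delta`` is
anomalously large sit far from any denser region and are taken as cluster
*prototypes*; every remaining point is assigned the label of its nearest
prototype.

Density ties are broken by point index (lower index counts as denser) so the
density order is total and the whole pipeline is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import ParameterError, ValidationError

__all__ = [
    "SENTINEL",
    "ClusteringConfig",
    "DensityPeakResult",
    "resolve_dc",
    "compute_rho",
    "compute_delta",
    "select_prototypes",
    "cluster",
]

#: nearest_higher value for the globally densest point, which has no denser peer
SENTINEL = -1

_DC_MODES = ("fraction", "absolute")
_KERNELS = ("hard", "gaussian")
_SELECTIONS = ("gamma_gap", "threshold", "fixed_k")
_ASSIGNMENTS = ("nearest", "chain")


@dataclass(frozen=True)
class ClusteringConfig:
    """Settings for the density-peak pipeline.

    ``dc_mode='fraction'`` resolves the cutoff radius as the ``dc_value``
    quantile of all off-diagonal pairwise distances (default 0.02, i.e. a
    ~2% neighbourhood); ``'absolute'`` uses ``dc_value`` as the radius
    directly.  ``selection`` picks how "anomalously large" delta is decided:
    the largest consecutive gap in the gamma = rho x delta ranking
    (``gamma_gap``, default — needs no tuned threshold), a mean + k*SD
    threshold on gamma (``threshold``), or simply the top ``k`` (``fixed_k``).
    """

    dc_mode: str = "fraction"
    dc_value: float = 0.02
    kernel: str = "hard"
    selection: str = "gamma_gap"
    k: int | None = None
    threshold_multiplier: float = 3.0
    selection_rho_weight: float = 0.25
    assign: str = "nearest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dc_mode not in _DC_MODES:
            raise ParameterError(f"dc_mode must be one of {_DC_MODES}, got {self.dc_mode!r}")
        if self.kernel not in _KERNELS:
            raise ParameterError(f"kernel must be one of {_KERNELS}, got {self.kernel!r}")
        if self.selection not in _SELECTIONS:
            raise ParameterError(f"selection must be one of {_SELECTIONS}, got {self.selection!r}")
        if self.assign not in _ASSIGNMENTS:
            raise ParameterError(f"assign must be one of {_ASSIGNMENTS}, got {self.assign!r}")
        if self.dc_mode == "fraction" and not 0.0 < self.dc_value < 1.0:
            raise ParameterError("fraction-mode dc_value must lie in (0, 1)")
        if self.dc_mode == "absolute" and not self.dc_value > 0.0:
            raise ParameterError("absolute-mode dc_value must be positive")
        if self.selection == "fixed_k":
            if self.k is None or self.k < 1:
                raise ParameterError("selection 'fixed_k' requires a positive k")
        elif self.k is not None:
            raise ParameterError("k is only meaningful with selection 'fixed_k'")
        if not 0.0 <= self.selection_rho_weight <= 1.0:
            raise ParameterError("selection_rho_weight must lie in [0, 1]")


@dataclass(frozen=True)
class DensityPeakResult:
    """Per-point quantities and the final partition of one clustering run."""

    rho: np.ndarray
    delta: np.ndarray
    nearest_higher: np.ndarray
    gamma: np.ndarray
    prototypes: tuple[int, ...]
    labels: np.ndarray
    dc: float
    config: ClusteringConfig = field(repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.prototypes)


def _validated_distances(distances: np.ndarray) -> np.ndarray:
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError(f"distance matrix must be square, got shape {D.shape}")
    if D.shape[0] < 2:
        raise ValidationError("need at least 2 points")
    if np.any(D < 0):
        raise ValidationError("distance matrix has negative entries")
    if np.any(np.diag(D) != 0):
        raise ValidationError("distance matrix diagonal must be zero")
    if not np.allclose(D, D.T, rtol=0.0, atol=1e-10):
        raise ValidationError("distance matrix is not symmetric")
    return D


def resolve_dc(distances: np.ndarray, config: ClusteringConfig) -> float:
    """Cutoff radius: absolute value, or a quantile of off-diagonal distances."""
    if config.dc_mode == "absolute":
        return float(config.dc_value)
    D = np.asarray(distances, dtype=float)
    iu = np.triu_indices(D.shape[0], k=1)
    return float(np.quantile(D[iu], config.dc_value))


def compute_rho(distances: np.ndarray, config: ClusteringConfig) -> np.ndarray:
    """Local density per point.

    Hard kernel: rho_i = #{j != i : d_ij < d_c}.  Gaussian kernel:
    rho_i = sum_{j != i} exp(-(d_ij / d_c)^2), which avoids the heavy tying
    of integer counts at small n.
    """
    D = _validated_distances(distances)
    dc = resolve_dc(D, config)
    if config.kernel == "hard":
        rho = (D < dc).sum(axis=1).astype(float)
        if dc > 0.0:
            rho -= 1.0  # remove the self neighbour (d_ii = 0 < dc)
        return rho
    if dc <= 0.0:
        raise ParameterError("gaussian kernel requires a strictly positive resolved d_c")
    K = np.exp(-((D / dc) ** 2))
    return K.sum(axis=1) - 1.0  # self term is exp(0) = 1


def _density_order(rho: np.ndarray) -> np.ndarray:
    """Total density order: rho descending, index ascending on ties."""
    n = len(rho)
    return np.lexsort((np.arange(n), -np.asarray(rho, dtype=float)))


def compute_delta(
    distances: np.ndarray, rho: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum distance to a denser point, plus that point's index.

    The single point heading the total density order has no denser peer: it
    receives its maximum pairwise distance and the sentinel index.  Ties in
    the minimizing distance go to the lowest index.
    """
    D = _validated_distances(distances)
    rho = np.asarray(rho, dtype=float)
    n = D.shape[0]
    if rho.shape != (n,):
        raise ValidationError(f"rho length {rho.shape} does not match matrix size {n}")
    delta = np.empty(n)
    nearest = np.empty(n, dtype=int)
    order = _density_order(rho)
    top = order[0]
    delta[top] = D[top].max()
    nearest[top] = SENTINEL
    for pos in range(1, n):
        i = order[pos]
        higher = order[:pos]
        d = D[i, higher]
        m = d.min()
        delta[i] = m
        nearest[i] = int(higher[d == m].min())
    return delta, nearest


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones_like(x)
    return (x - lo) / (hi - lo)


def select_prototypes(
    rho: Sequence[float], delta: Sequence[float], config: ClusteringConfig
) -> list[int]:
    """Indices of the prototype points, sorted by descending selection score.

    gamma_i is the product of min-max normalized rho and delta; a large gamma
    marks a locally dense point well separated from any denser region.  The
    ``gamma_gap`` and ``threshold`` rules rank candidates by a density-damped
    score ``rho^w * delta`` (both min-max normalized, ``w`` =
    ``selection_rho_weight``): local-density estimates carry heavy sampling
    noise in high dimensions while delta carries the separation signal, and a
    full-weight rho lets that noise demote genuine peaks.  ``fixed_k`` keeps
    the top k by plain gamma.  At least one prototype (the score maximum) is
    always returned.
    """
    rho = np.asarray(rho, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if rho.shape != delta.shape:
        raise ValidationError("rho and delta must have equal length")
    n = len(rho)
    if n < 2:
        raise ValidationError("need at least 2 points")

    if config.selection == "fixed_k":
        gamma = _minmax(rho) * _minmax(delta)
        order = np.lexsort((np.arange(n), -gamma))
        if config.k > n:
            raise ParameterError(f"k={config.k} exceeds number of points n={n}")
        return [int(i) for i in order[: config.k]]

    score = _minmax(rho) ** config.selection_rho_weight * _minmax(delta)
    order = np.lexsort((np.arange(n), -score))

    if config.selection == "threshold":
        cut = score.mean() + config.threshold_multiplier * score.std()
        chosen = [int(i) for i in order if score[i] > cut]
        return chosen or [int(order[0])]

    # gamma_gap: cut the descending gamma ranking at the most anomalous
    # consecutive ratio gap among the top ceil(sqrt(n)) candidates.  A gap is
    # judged against the typical gap further down the ranking (the noise
    # tail), not in absolute terms: the density maximum's delta is its
    # maximum pairwise distance, which inflates the very first gap and would
    # otherwise dominate.
    k_max = min(n - 1, math.ceil(math.sqrt(n)))
    if k_max < 1:
        return [int(order[0])]
    window = min(n, 2 * k_max + 1)
    g = score[order[:window]]
    if g[0] <= 0.0:
        return [int(order[0])]
    eps = g[0] * 1e-12
    log_gaps = np.log(g[:-1] + eps) - np.log(g[1:] + eps)  # length window - 1
    if np.all(log_gaps <= 1e-12):
        return [int(order[0])]
    best_j, best_score = 0, -np.inf
    for j in range(k_max):
        tail = log_gaps[j + 1:]
        baseline = tail.mean() if tail.size else 0.0
        score = log_gaps[j] / (baseline + 1e-12)
        if score > best_score:
            best_j, best_score = j, score
    return [int(i) for i in order[: best_j + 1]]


def cluster(points: np.ndarray, config: ClusteringConfig | None = None) -> DensityPeakResult:
    """Full pipeline: distances -> rho -> delta -> prototypes -> labels.

    Labels are integers 0..K-1 indexing into ``prototypes`` (which is sorted
    by descending gamma); each point takes the label of its nearest prototype
    by Euclidean distance, distance ties going to the higher-gamma prototype.
    ``assign='chain'`` instead propagates labels down the density order
    through each point's nearest denser neighbour, which can differ on
    elongated clusters.
    """
    config = config or ClusteringConfig()
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"points must be an n x d matrix, got shape {X.shape}")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 points")
    if np.any(~np.isfinite(X)):
        raise ValidationError("points contain non-finite values")

    D = squareform(pdist(X))
    dc = resolve_dc(D, config)
    rho = compute_rho(D, config)
    delta, nearest = compute_delta(D, rho)
    gamma = _minmax(rho) * _minmax(delta)
    prototypes = select_prototypes(rho, delta, config)

    n = X.shape[0]
    if config.assign == "nearest":
        d2p = cdist(X, X[prototypes])
        labels = np.argmin(d2p, axis=1)  # first occurrence = highest-gamma prototype
    else:
        labels = np.full(n, -1, dtype=int)
        proto_rank = {p: r for r, p in enumerate(prototypes)}
        d2p = cdist(X, X[prototypes])
        for i in _density_order(rho):
            if i in proto_rank:
                labels[i] = proto_rank[i]
            elif nearest[i] != SENTINEL and labels[nearest[i]] >= 0:
                labels[i] = labels[nearest[i]]
            else:
                labels[i] = int(np.argmin(d2p[i]))
    labels[list(prototypes)] = np.arange(len(prototypes))  # a prototype owns its cluster

    return DensityPeakResult(
        rho=rho,
        delta=delta,
        nearest_higher=nearest,
        gamma=gamma,
        prototypes=tuple(int(p) for p in prototypes),
        labels=labels.astype(int),
        dc=dc,
        config=config,
    )
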