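"""Seeded synthetic-cohort generators.

Three generators back the demonstrations and the parameter-recovery tests:

* a bimodal treatment-response simulator (two symptom-total axes, two
  timepoints, a planted responder subgroup whose positive-symptom score
  improves multiplicatively while everything else only drifts by noise);
* an isotropic Gaussian-mixture generator with planted labels, for
  clustering-recovery benchmarks;
* a two-timepoint generator that couples a baseline mixture to follow-up
  clusters through a planted row-stochastic transition matrix, for CPT
  recovery.

All generators are deterministic functions of their spec's seed, and clip
generated values to declared bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import ortho_group, truncnorm

from .errors import ParameterError, ValidationError
from .scales import Cohort, ScaleDefinition, Signature

__all__ = [
    "BimodalResponseSpec",
    "MixtureSpec",
    "TwoTimepointSpec",
    "simulate_bimodal_response",
    "simulate_mixture",
    "simulate_two_timepoint",
    "place_centroids",
]


@dataclass(frozen=True)
class BimodalResponseSpec:
    """Settings for the bimodal-response simulation.

    Baseline positive/negative symptom totals are truncated normals.  Each
    patient is independently a responder with probability
    ``responder_fraction``; a responder's time-2 positive total is
    ``(1 - positive_improvement) * baseline + noise`` (the improvement is
    read multiplicatively), every other follow-up value is baseline + noise.

    The default lower bound is 0 rather than the 7-point floor of a 7-item
    ordinal subscale: a large multiplicative improvement would otherwise be
    censored by the floor and the planted effect could not be recovered.
    """

    n_patients: int = 100
    responder_fraction: float = 0.5
    positive_improvement: float = 0.8
    baseline_positive_mean: float = 22.0
    baseline_positive_sd: float = 6.0
    baseline_negative_mean: float = 22.0
    baseline_negative_sd: float = 6.0
    followup_noise_sd: float = 2.0
    bounds: tuple[float, float] = (0.0, 49.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be positive")
        for name in ("responder_fraction", "positive_improvement"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        for name in ("baseline_positive_sd", "baseline_negative_sd", "followup_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not self.bounds[0] < self.bounds[1]:
            raise ParameterError("degenerate bounds: require min < max")


@dataclass(frozen=True)
class MixtureSpec:
    """Isotropic Gaussian mixture with centroids at a guaranteed mutual distance.

    ``separation`` is the centroid spacing in units of the within-cluster SD.
    """

    n_points: int
    n_dims: int
    n_clusters: int
    separation: float = 8.0
    within_sd: float = 1.0
    weights: tuple[float, ...] | None = None
    bounds: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_points, self.n_dims, self.n_clusters) < 1:
            raise ParameterError("n_points, n_dims and n_clusters must be positive")
        if self.within_sd <= 0:
            raise ParameterError("within_sd must be positive")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            object.__setattr__(self, "weights", tuple(float(x) for x in w))
            if len(w) != self.n_clusters:
                raise ParameterError("weights must have one entry per cluster")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ParameterError("weights must be non-negative and sum to 1")


@dataclass(frozen=True)
class TwoTimepointSpec:
    """Baseline mixture plus a planted transition to follow-up clusters."""

    t1_mixture: MixtureSpec
    transition: np.ndarray = field(repr=False)
    t2_centroids: np.ndarray = field(repr=False)
    t2_within_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        T = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "transition", T)
        C2 = np.atleast_2d(np.asarray(self.t2_centroids, dtype=float))
        object.__setattr__(self, "t2_centroids", C2)
        if T.ndim != 2 or T.shape[0] != self.t1_mixture.n_clusters:
            raise ValidationError("transition must have one row per time-1 cluster")
        if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("transition rows must be non-negative and sum to 1")
        if C2.shape[0] != T.shape[1]:
            raise ValidationError("t2_centroids count must equal transition columns")
        if C2.shape[1] != self.t1_mixture.n_dims:
            raise ValidationError("t2_centroids dimension must match the mixture")
        if self.t2_within_sd <= 0:
            raise ValidationError("t2_within_sd must be positive")


_RESPONSE_SCALE = ScaleDefinition(
    name="symptom_totals",
    items=("positive_total", "negative_total"),
    domains={"positive": ("positive_total",), "negative": ("negative_total",)},
)


def _pid(i: int, n: int) -> str:
    return f"p{str(i + 1).zfill(len(str(n)))}"


def _truncated_normal(rng, mean, sd, bounds, size):
    lo, hi = bounds
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise ParameterError("degenerate draw: mean outside bounds with zero SD")
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_bimodal_response(spec: BimodalResponseSpec) -> tuple[Cohort, np.ndarray]:
    """Two-timepoint cohort on (positive_total, negative_total) axes plus
    the true responder flags."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    lo, hi = spec.bounds

    pos1 = _truncated_normal(rng, spec.baseline_positive_mean, spec.baseline_positive_sd,
                             spec.bounds, n)
    neg1 = _truncated_normal(rng, spec.baseline_negative_mean, spec.baseline_negative_sd,
                             spec.bounds, n)
    responders = rng.random(n) < spec.responder_fraction

    noise = rng.normal(0.0, spec.followup_noise_sd, size=(n, 2))
    pos2 = np.where(responders, (1.0 - spec.positive_improvement) * pos1, pos1) + noise[:, 0]
    neg2 = neg1 + noise[:, 1]
    pos2 = np.clip(pos2, lo, hi)
    neg2 = np.clip(neg2, lo, hi)

    scale = ScaleDefinition(
        name=_RESPONSE_SCALE.name,
        items=_RESPONSE_SCALE.items,
        domains=_RESPONSE_SCALE.domains,
        item_range=(float(lo), float(hi)),
    )
    sigs = [Signature(_pid(i, n), "t1", np.array([pos1[i], neg1[i]])) for i in range(n)]
    sigs += [Signature(_pid(i, n), "t2", np.array([pos2[i], neg2[i]])) for i in range(n)]
    return Cohort(scale, tuple(sigs)), responders


def place_centroids(
    n_clusters: int,
    n_dims: int,
    separation: float,
    within_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cluster centroids at mutual distance >= separation * within_sd.

    Centroids are drawn in random (seeded) directions from a standard normal
    and rescaled so the *minimum* pairwise distance equals the requested
    spacing; typical pairs then sit further apart, as in a generic planted
    mixture.  Draws are retried when two directions coincide; the packing is
    declared infeasible after repeated failures.
    """
    if n_clusters == 1:
        return np.zeros((1, n_dims))
    target = separation * within_sd
    for _ in range(100):
        C = rng.standard_normal((n_clusters, n_dims))
        diffs = C[:, None, :] - C[None, :, :]
        dists = np.sqrt((diffs**2).sum(axis=-1))
        min_dist = dists[np.triu_indices(n_clusters, k=1)].min()
        if min_dist > 0.0:
            return C * (target / min_dist)
    raise ParameterError(
        f"cannot place {n_clusters} distinct centroids in {n_dims} dimensions"
    )


def _draw_mixture(spec: MixtureSpec, rng: np.random.Generator):
    centroids = place_centroids(spec.n_clusters, spec.n_dims, spec.separation,
                                spec.within_sd, rng)
    weights = (np.asarray(spec.weights, dtype=float)
               if spec.weights is not None
               else np.full(spec.n_clusters, 1.0 / spec.n_clusters))
    labels = rng.choice(spec.n_clusters, size=spec.n_points, p=weights)
    X = centroids[labels] + rng.normal(0.0, spec.within_sd, size=(spec.n_points, spec.n_dims))
    if spec.bounds is not None:
        X = np.clip(X, spec.bounds[0], spec.bounds[1])
    return X, labels, centroids


def _generic_scale(n_dims: int, bounds) -> ScaleDefinition:
    width = len(str(n_dims))
    items = tuple(f"dim{str(j + 1).zfill(width)}" for j in range(n_dims))
    item_range = (float(bounds[0]), float(bounds[1])) if bounds is not None else None
    return ScaleDefinition(name="simulated", items=items, item_range=item_range)


def simulate_mixture(spec: MixtureSpec) -> tuple[Cohort, np.ndarray]:
    """Single-timepoint cohort drawn from the planted mixture, plus true labels."""
    rng = np.random.default_rng(spec.seed)
    X, labels, _ = _draw_mixture(spec, rng)
    scale = _generic_scale(spec.n_dims, spec.bounds)
    n = spec.n_points
    sigs = tuple(Signature(_pid(i, n), "t1", X[i]) for i in range(n))
    return Cohort(scale, sigs), labels


def simulate_two_timepoint(
    spec: TwoTimepointSpec,
) -> tuple[Cohort, np.ndarray, np.ndarray]:
    """Two-timepoint cohort with planted cluster labels at both times.

    Each patient's time-2 cluster is drawn from the transition row of their
    true time-1 cluster; the time-2 signature is the corresponding follow-up
    centroid plus isotropic noise.
    """
    rng = np.random.default_rng(spec.seed)
    mix = spec.t1_mixture
    X1, labels1, _ = _draw_mixture(mix, rng)
    n = mix.n_points
    n_t2 = spec.transition.shape[1]
    labels2 = np.array(
        [rng.choice(n_t2, p=spec.transition[z]) for z in labels1], dtype=int
    )
    X2 = spec.t2_centroids[labels2] + rng.normal(
        0.0, spec.t2_within_sd, size=(n, mix.n_dims)
    )
    if mix.bounds is not None:
        X2 = np.clip(X2, mix.bounds[0], mix.bounds[1])
    scale = _generic_scale(mix.n_dims, mix.bounds)
    sigs = [Signature(_pid(i, n), "t1", X1[i]) for i in range(n)]
    sigs += [Signature(_pid(i, n), "t2", X2[i]) for i in range(n)]
    return Cohort(scale, tuple(sigs)), labels1, labels2
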