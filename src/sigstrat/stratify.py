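"""Hard and soft assignment of signatures to prototypes, priors, and
two-class linear discriminants.

Hard stratification assigns a signature to the class with the nearest
centroid.  Soft stratification turns centroid distances into a probability
distribution over class labels (a Gaussian-kernel softmax over squared
distances by default, which recovers the hard rule as temperature -> 0 and
the uniform distribution as temperature -> inf).  Priors over classes —
e.g. prototype prevalences — combine with a membership by Bayes' product
rule.  The supervised route is a closed-form Fisher linear discriminant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateEvidenceError,
    DimensionError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "PrototypeSet",
    "Membership",
    "LinearDiscriminant",
    "hard_assign",
    "soft_assign",
    "apply_prior",
    "fit_discriminant",
    "classify_side",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class PrototypeSet:
    """Labelled centroids (one vector per class), with optional priors."""

    labels: tuple[str, ...]
    centroids: np.ndarray
    priors: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValidationError("prototype labels are not unique")
        C = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        object.__setattr__(self, "centroids", C)
        if C.shape[0] != len(labels):
            raise DimensionError(
                f"{len(labels)} labels but {C.shape[0]} centroids"
            )
        if self.priors is not None:
            p = np.asarray(self.priors, dtype=float)
            object.__setattr__(self, "priors", p)
            if p.shape != (len(labels),):
                raise DimensionError("priors must align with labels")
            if np.any(p < 0) or abs(p.sum() - 1.0) > _PROB_TOL:
                raise ValidationError("priors must be non-negative and sum to 1")

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.centroids,
                          columns=[f"dim{j}" for j in range(self.dim)])
        df.insert(0, "label", list(self.labels))
        if self.priors is not None:
            df["prior"] = self.priors
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PrototypeSet":
        if "label" not in df.columns:
            raise ValidationError("prototype table needs a 'label' column")
        priors = df["prior"].to_numpy() if "prior" in df.columns else None
        value_cols = [c for c in df.columns if c not in ("label", "prior")]
        return cls(tuple(df["label"].astype(str)), df[value_cols].to_numpy(float), priors)


@dataclass(frozen=True)
class Membership:
    """A normalized probability distribution of one signature over class labels."""

    labels: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (len(self.labels),):
            raise DimensionError("probabilities must align with labels")
        if np.any(p < 0):
            raise ValidationError("membership probabilities must be non-negative")
        if abs(p.sum() - 1.0) > _PROB_TOL:
            raise ValidationError(f"membership probabilities sum to {p.sum()}, not 1")

    def argmax_label(self) -> str:
        return self.labels[int(np.argmax(self.probabilities))]


@dataclass(frozen=True)
class LinearDiscriminant:
    """A separating hyperplane: classify by the sign of ``weights . x + offset``."""

    weights: np.ndarray
    offset: float
    positive_label: str
    negative_label: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if not np.any(w != 0):
            raise ValidationError("discriminant weights must not all be zero")

    def decision(self, x: Sequence[float]) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != self.weights.shape:
            raise DimensionError(f"expected {self.weights.shape[0]} values, got {x.shape}")
        return float(self.weights @ x + self.offset)


def _distances(signature: Sequence[float], prototypes: PrototypeSet) -> np.ndarray:
    x = np.asarray(signature, dtype=float)
    if x.shape != (prototypes.dim,):
        raise DimensionError(
            f"signature has {x.shape} values, prototypes are {prototypes.dim}-dimensional"
        )
    return cdist(x[None, :], prototypes.centroids)[0]


def hard_assign(signature: Sequence[float], prototypes: PrototypeSet) -> str:
    """Label of the nearest centroid; exact ties go to the earlier label."""
    d = _distances(signature, prototypes)
    return prototypes.labels[int(np.argmin(d))]


def soft_assign(
    signature: Sequence[float],
    prototypes: PrototypeSet,
    temperature: float = 1.0,
    kernel: str = "gaussian",
) -> Membership:
    """Distance-based probabilistic class membership.

    The default Gaussian kernel sets ``p_k proportional to
    exp(-d_k^2 / (2 * temperature^2))``; its argmax always agrees with
    :func:`hard_assign`.  ``kernel='inverse'`` uses inverse-distance weights
    ``1 / d_k`` instead (one-hot if the signature sits on a centroid);
    temperature is ignored there.
    """
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    d = _distances(signature, prototypes)
    if kernel == "gaussian":
        logits = -(d**2) / (2.0 * temperature**2)
        logits -= logits.max()  # stabilize
        w = np.exp(logits)
    elif kernel == "inverse":
        if np.any(d == 0.0):
            w = (d == 0.0).astype(float)
        else:
            w = 1.0 / d
    else:
        raise ParameterError(f"unknown kernel {kernel!r}")
    return Membership(prototypes.labels, w / w.sum())


def apply_prior(membership: Membership, priors: Sequence[float]) -> Membership:
    """Bayes product of a membership (likelihood) and class priors, renormalized."""
    p = np.asarray(priors, dtype=float)
    if p.shape != (len(membership.labels),):
        raise DimensionError("priors must align with membership labels")
    if np.any(p < 0) or abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValidationError("priors must be non-negative and sum to 1")
    post = membership.probabilities * p
    total = post.sum()
    if total <= 0.0:
        raise DegenerateEvidenceError(
            "prior support is disjoint from membership support (zero posterior mass)"
        )
    return Membership(membership.labels, post / total)


def fit_discriminant(
    signatures: np.ndarray,
    labels: Sequence[str],
    positive_label: str | None = None,
) -> LinearDiscriminant:
    """Fisher linear discriminant for two classes.

    Weights are proportional to the inverse pooled within-class covariance
    applied to the difference of class means; the offset zeroes the decision
    score at the midpoint of the projected class means (equal-prior rule).
    A small ridge (1e-6 * trace / d) is added when the pooled covariance is
    singular.
    """
    X = np.asarray(signatures, dtype=float)
    y = np.asarray([str(v) for v in labels])
    if X.ndim != 2 or X.shape[0] != len(y):
        raise DimensionError("signatures must be n x d with one label per row")
    classes = list(dict.fromkeys(y))  # order of first appearance
    if len(classes) != 2:
        raise ValidationError(f"exactly two classes required, got {classes}")
    if X.shape[0] < 4:
        raise ValidationError("need at least 4 points (2 per class)")
    if positive_label is None:
        positive_label = classes[0]
    if positive_label not in classes:
        raise ParameterError(f"positive_label {positive_label!r} not among {classes}")
    negative_label = classes[1] if positive_label == classes[0] else classes[0]

    Xp, Xn = X[y == positive_label], X[y == negative_label]
    if len(Xp) < 2 or len(Xn) < 2:
        raise ValidationError("each class needs at least 2 points")
    mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
    scatter = (Xp - mu_p).T @ (Xp - mu_p) + (Xn - mu_n).T @ (Xn - mu_n)
    Sw = scatter / (len(Xp) + len(Xn) - 2)
    d = X.shape[1]
    try:
        w = np.linalg.solve(Sw, mu_p - mu_n)
    except np.linalg.LinAlgError:
        ridge = 1e-6 * np.trace(Sw) / d
        if ridge <= 0.0:
            ridge = 1e-6
        w = np.linalg.solve(Sw + ridge * np.eye(d), mu_p - mu_n)
    offset = -float(w @ (mu_p + mu_n)) / 2.0
    return LinearDiscriminant(w, offset, positive_label, negative_label)


def classify_side(signature: Sequence[float], discriminant: LinearDiscriminant) -> str:
    """Which side of the boundary a signature falls on.

    A decision score of exactly zero (on the boundary) maps to the positive
    label — arbitrary but deterministic.
    """
    score = discriminant.decision(signature)
    return discriminant.positive_label if score >= 0.0 else discriminant.negative_label
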