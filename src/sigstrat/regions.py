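"""Outcomes as regions of signature space.

Instead of thresholding a collapsed univariate score, a multivariate outcome
is a *region*: a closed ball around a prototype, one side of a linear
discriminant, or a union of such regions.  A trajectory endpoint that lands
inside the region counts as a response; cohort-level effectiveness is the
fraction of patients whose time-2 signatures fall inside.

Regions are closed sets — boundary points are inside — and are defined on
the same coordinates/standardization as the analysis that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, ParameterError, ValidationError
from .scales import Cohort, euclidean_distance
from .stratify import LinearDiscriminant

__all__ = ["Ball", "Halfspace", "RegionUnion", "Region", "contains", "evaluate_response", "region_from_dict"]


@dataclass(frozen=True)
class Ball:
    """Closed ball of given radius around a prototype/center point."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not self.radius > 0:
            raise ParameterError("radius must be positive")

    @property
    def dim(self) -> int:
        return len(self.center)

    def contains(self, x: Sequence[float]) -> bool:
        return euclidean_distance(self.center, x) <= self.radius

    def to_dict(self) -> dict:
        return {"kind": "ball", "center": self.center.tolist(), "radius": self.radius}


@dataclass(frozen=True)
class Halfspace:
    """One (closed) side of a linear discriminant boundary."""

    discriminant: LinearDiscriminant
    side: str

    def __post_init__(self) -> None:
        if self.side not in (self.discriminant.positive_label, self.discriminant.negative_label):
            raise ParameterError(
                f"side {self.side!r} is neither label of the discriminant"
            )

    @property
    def dim(self) -> int:
        return len(self.discriminant.weights)

    def contains(self, x: Sequence[float]) -> bool:
        score = self.discriminant.decision(x)
        if self.side == self.discriminant.positive_label:
            return score >= 0.0
        return score <= 0.0  # boundary belongs to both closed sides

    def to_dict(self) -> dict:
        return {
            "kind": "halfspace",
            "side": self.side,
            "discriminant": {
                "weights": self.discriminant.weights.tolist(),
                "offset": self.discriminant.offset,
                "positive_label": self.discriminant.positive_label,
                "negative_label": self.discriminant.negative_label,
            },
        }


@dataclass(frozen=True)
class RegionUnion:
    """Union of same-dimension member regions; inside iff inside any member."""

    members: tuple

    def __post_init__(self) -> None:
        members = tuple(self.members)
        object.__setattr__(self, "members", members)
        if not members:
            raise ValidationError("union must have at least one member region")
        dims = {m.dim for m in members}
        if len(dims) != 1:
            raise DimensionError(f"union members have inconsistent dimensions {sorted(dims)}")

    @property
    def dim(self) -> int:
        return self.members[0].dim

    def contains(self, x: Sequence[float]) -> bool:
        return any(m.contains(x) for m in self.members)

    def to_dict(self) -> dict:
        return {"kind": "union", "members": [m.to_dict() for m in self.members]}


Region = Ball | Halfspace | RegionUnion


def contains(region: Region, signature: Sequence[float]) -> bool:
    """True when the signature lies in the (closed) region."""
    x = np.asarray(signature, dtype=float)
    if x.shape != (region.dim,):
        raise DimensionError(
            f"signature has shape {x.shape}, region is {region.dim}-dimensional"
        )
    return bool(region.contains(x))


def evaluate_response(
    cohort: Cohort, region: Region, timepoint: str | None = None
) -> tuple[pd.Series, float]:
    """Per-patient region membership and the cohort response rate.

    Treatment effectiveness, crudely: the fraction of patients whose
    signatures (at the given timepoint, or all signatures) transitioned into
    the outcome region.
    """
    sigs = cohort.signatures if timepoint is None else cohort.subset(timepoint).signatures
    if not sigs:
        raise ValidationError("empty cohort")
    flags = pd.Series(
        {s.patient_id: contains(region, s.values) for s in sigs},
        name="response",
    )
    return flags, float(flags.mean())


def region_from_dict(spec: Mapping) -> Region:
    """Build a region from a structured-config mapping (see CLI docs)."""
    kind = spec.get("kind")
    if kind == "ball":
        return Ball(np.asarray(spec["center"], dtype=float), float(spec["radius"]))
    if kind == "halfspace":
        d = spec["discriminant"]
        disc = LinearDiscriminant(
            np.asarray(d["weights"], dtype=float),
            float(d["offset"]),
            str(d["positive_label"]),
            str(d["negative_label"]),
        )
        return Halfspace(disc, str(spec["side"]))
    if kind == "union":
        return RegionUnion(tuple(region_from_dict(m) for m in spec["members"]))
    raise ParameterError(f"unknown region kind {kind!r}")
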