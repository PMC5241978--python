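"""Clinical scales, signatures and cohorts.

A *scale* declares the axes of a signature space (e.g. 30 symptom items with
7 positive / 7 negative / 16 general domain groupings, or 5 neurocognitive
domain Z-scores).  A *signature* is one patient's point in that space at one
timepoint; a *cohort* is a collection of signatures sharing a scale.

Distances between signatures are plain Euclidean distances: similarity of two
patients is inversely related to the straight-line distance between their
points.  Missing item values are rejected at load time rather than imputed —
imputation silently changes cluster structure, so complete cases are required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, ParameterError, ValidationError

__all__ = [
    "ScaleDefinition",
    "Signature",
    "Cohort",
    "euclidean_distance",
    "load_cohort",
    "write_cohort",
    "aggregate_domain_scores",
    "standardize",
]

Bounds = tuple[float, float]


@dataclass(frozen=True)
class ScaleDefinition:
    """Names the dimensions of a signature space and their domain groupings.

    Parameters
    ----------
    name:
        Human-readable scale name.
    items:
        Ordered, unique item labels; one per axis of the space.
    domains:
        Mapping from domain label to the (non-empty, pairwise disjoint)
        subset of items it groups.
    item_range:
        Optional numeric bounds. Either a single ``(min, max)`` applied to
        every item, or a mapping ``item -> (min, max)`` for items that carry
        bounds. Values outside the declared range are a validation error.
    """

    name: str
    items: tuple[str, ...]
    domains: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    item_range: Bounds | Mapping[str, Bounds] | None = None

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if len(set(items)) != len(items):
            raise ValidationError(f"scale {self.name!r}: item labels are not unique")
        domains = {str(k): tuple(v) for k, v in dict(self.domains).items()}
        object.__setattr__(self, "domains", domains)
        seen: set[str] = set()
        for dom, members in domains.items():
            if not members:
                raise ValidationError(f"domain {dom!r} is empty")
            extra = set(members) - set(items)
            if extra:
                raise ValidationError(f"domain {dom!r} references unknown items {sorted(extra)}")
            overlap = seen & set(members)
            if overlap:
                raise ValidationError(f"domain {dom!r} overlaps another domain on {sorted(overlap)}")
            seen |= set(members)
        for item, bounds in self._bounds_items():
            lo, hi = bounds
            if not lo < hi:
                raise ValidationError(f"item {item!r}: bounds require min < max, got ({lo}, {hi})")

    def _bounds_items(self) -> Iterable[tuple[str, Bounds]]:
        if self.item_range is None:
            return []
        if isinstance(self.item_range, Mapping):
            return [(k, (float(v[0]), float(v[1]))) for k, v in self.item_range.items()]
        lo, hi = self.item_range
        return [(item, (float(lo), float(hi))) for item in self.items]

    def bounds_for(self, item: str) -> Bounds | None:
        """Declared (min, max) for *item*, or ``None`` if unbounded."""
        for k, v in self._bounds_items():
            if k == item:
                return v
        return None

    @property
    def n_items(self) -> int:
        return len(self.items)

    def has_uniform_range(self) -> bool:
        """True when every item carries the same declared bounds."""
        bounds = dict(self._bounds_items())
        if len(bounds) != len(self.items):
            return False
        return len(set(bounds.values())) == 1

    @classmethod
    def from_dict(cls, spec: Mapping) -> "ScaleDefinition":
        item_range = spec.get("item_range")
        if isinstance(item_range, (list, tuple)):
            item_range = (float(item_range[0]), float(item_range[1]))
        elif isinstance(item_range, Mapping):
            item_range = {k: (float(v[0]), float(v[1])) for k, v in item_range.items()}
        return cls(
            name=str(spec.get("name", "scale")),
            items=tuple(spec["items"]),
            domains={k: tuple(v) for k, v in dict(spec.get("domains", {})).items()},
            item_range=item_range,
        )


@dataclass(frozen=True)
class Signature:
    """One patient's point in signature space at a single timepoint."""

    patient_id: str
    timepoint: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class Cohort:
    """A collection of signatures over a shared scale.

    The order of ``signatures`` is canonical: it preserves first appearance in
    the input, and all per-point outputs downstream (rho, delta, labels) index
    against it.
    """

    scale: ScaleDefinition
    signatures: tuple[Signature, ...]

    def __post_init__(self) -> None:
        sigs = tuple(self.signatures)
        object.__setattr__(self, "signatures", sigs)
        seen: set[tuple[str, str]] = set()
        for sig in sigs:
            key = (sig.patient_id, sig.timepoint)
            if key in seen:
                raise ValidationError(f"duplicate (patient, timepoint) pair {key}")
            seen.add(key)
            if sig.values.shape != (self.scale.n_items,):
                raise DimensionError(
                    f"patient {sig.patient_id!r} at {sig.timepoint!r}: expected "
                    f"{self.scale.n_items} values, got {sig.values.shape}"
                )
            if np.any(~np.isfinite(sig.values)):
                raise ValidationError(
                    f"patient {sig.patient_id!r} at {sig.timepoint!r}: missing or non-finite value"
                )
            for j, item in enumerate(self.scale.items):
                bounds = self.scale.bounds_for(item)
                if bounds is not None and not bounds[0] <= sig.values[j] <= bounds[1]:
                    raise ValidationError(
                        f"patient {sig.patient_id!r}, item {item!r}: value "
                        f"{sig.values[j]} outside declared range {bounds}"
                    )

    def __len__(self) -> int:
        return len(self.signatures)

    @property
    def timepoints(self) -> tuple[str, ...]:
        out: list[str] = []
        for sig in self.signatures:
            if sig.timepoint not in out:
                out.append(sig.timepoint)
        return tuple(out)

    def subset(self, timepoint: str) -> "Cohort":
        sigs = tuple(s for s in self.signatures if s.timepoint == timepoint)
        if not sigs:
            raise ValidationError(f"no signatures at timepoint {timepoint!r}")
        return Cohort(self.scale, sigs)

    def matrix(self, timepoint: str | None = None) -> np.ndarray:
        """n x d value matrix in canonical order, optionally for one timepoint."""
        sigs = self.signatures if timepoint is None else self.subset(timepoint).signatures
        return np.vstack([s.values for s in sigs])

    def patient_ids(self, timepoint: str | None = None) -> tuple[str, ...]:
        sigs = self.signatures if timepoint is None else self.subset(timepoint).signatures
        return tuple(s.patient_id for s in sigs)

    def to_frame(self, layout: str = "wide") -> pd.DataFrame:
        """Tabular export; inverse of :func:`load_cohort` for both layouts."""
        if layout == "wide":
            rows = [
                {"patient_id": s.patient_id, "timepoint": s.timepoint,
                 **dict(zip(self.scale.items, s.values))}
                for s in self.signatures
            ]
            return pd.DataFrame(rows)
        if layout == "long":
            rows = [
                {"patient_id": s.patient_id, "timepoint": s.timepoint, "item": item, "value": val}
                for s in self.signatures
                for item, val in zip(self.scale.items, s.values)
            ]
            return pd.DataFrame(rows)
        raise ParameterError(f"unknown layout {layout!r}")


def euclidean_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Straight-line distance between two signatures.

    Symmetric, non-negative, and zero iff ``a == b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def load_cohort(path, scale: ScaleDefinition, layout: str = "wide") -> Cohort:
    """Read a cohort CSV (wide or long) against a scale definition.

    Wide layout: ``patient_id,timepoint,<item1>,...,<itemd>``.
    Long layout: ``patient_id,timepoint,item,value``.
    Row order of the input is preserved as canonical patient order.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "timepoint": str})
    for col in ("patient_id", "timepoint"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if layout == "wide":
        for item in scale.items:
            if item not in df.columns:
                raise FormatError(f"missing item column {item!r}")
        sigs = [
            Signature(row["patient_id"], row["timepoint"],
                      np.array([row[item] for item in scale.items], dtype=float))
            for _, row in df.iterrows()
        ]
        return Cohort(scale, tuple(sigs))
    if layout == "long":
        for col in ("item", "value"):
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
        unknown = set(df["item"]) - set(scale.items)
        if unknown:
            raise FormatError(f"unknown item(s) in long input: {sorted(unknown)}")
        order: list[tuple[str, str]] = []
        cells: dict[tuple[str, str], dict[str, float]] = {}
        for _, row in df.iterrows():
            key = (row["patient_id"], row["timepoint"])
            if key not in cells:
                cells[key] = {}
                order.append(key)
            if row["item"] in cells[key]:
                raise ValidationError(
                    f"duplicate value for patient {key[0]!r}, timepoint {key[1]!r}, "
                    f"item {row['item']!r}"
                )
            cells[key][row["item"]] = float(row["value"])
        sigs = []
        for pid, tp in order:
            got = cells[(pid, tp)]
            missing = [item for item in scale.items if item not in got]
            if missing:
                raise ValidationError(
                    f"patient {pid!r} at {tp!r}: missing item(s) {missing}"
                )
            sigs.append(Signature(pid, tp, np.array([got[i] for i in scale.items])))
        return Cohort(scale, tuple(sigs))
    raise ParameterError(f"unknown layout {layout!r}")


def write_cohort(cohort: Cohort, path, layout: str = "wide") -> None:
    """Write a cohort CSV that :func:`load_cohort` round-trips bit-identically."""
    cohort.to_frame(layout).to_csv(path, index=False)


def aggregate_domain_scores(cohort: Cohort) -> pd.DataFrame:
    """Summed per-domain scores: one row per (patient, timepoint, domain).

    This is the reductive *univariate* view that collapses a multidimensional
    signature into per-domain totals.
    """
    if not cohort.scale.domains:
        raise ValidationError("scale declares no domains to aggregate")
    idx = {item: j for j, item in enumerate(cohort.scale.items)}
    rows = [
        {
            "patient_id": s.patient_id,
            "timepoint": s.timepoint,
            "domain": dom,
            "score": float(sum(s.values[idx[i]] for i in members)),
        }
        for s in cohort.signatures
        for dom, members in cohort.scale.domains.items()
    ]
    return pd.DataFrame(rows, columns=["patient_id", "timepoint", "domain", "score"])


def standardize(cohort: Cohort, method: str = "none") -> Cohort:
    """Per-item standardization across all signatures.

    ``zscore`` subtracts the per-item mean and divides by the per-item
    population standard deviation; zero-variance items are centred at 0.
    Euclidean distance is scale-sensitive, so z-scoring is recommended when
    item ranges differ (e.g. mixing Likert items with Z-scored measures);
    single-instrument ordinal scales sharing one range can stay raw.
    """
    if method == "none":
        return cohort
    if method != "zscore":
        raise ParameterError(f"unknown standardization method {method!r}")
    if len(cohort) < 2:
        raise ParameterError("zscore standardization needs at least 2 signatures")
    X = cohort.matrix()
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    Z = (X - mean) / sd_safe
    scale = replace(cohort.scale, item_range=None)
    sigs = tuple(
        Signature(s.patient_id, s.timepoint, Z[i])
        for i, s in enumerate(cohort.signatures)
    )
    return Cohort(scale, sigs)


def warn_if_mixed_ranges(scale: ScaleDefinition, method: str) -> None:
    """Warn when raw Euclidean distances mix differently-bounded items."""
    if method == "none" and scale.item_range is not None and not scale.has_uniform_range():
        warnings.warn(
            "items carry heterogeneous declared ranges; Euclidean distances are "
            "scale-sensitive — consider standardize='zscore'",
            stacklevel=2,
        )
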