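"""Cluster-transition models between two timepoints.

A patient's trajectory is summarized as movement between the cluster they
occupied before treatment and the cluster they occupy after.  At cohort
level this is a conditional probability table (CPT): P(time-2 cluster |
time-1 cluster), estimated from per-patient memberships either by hard
counting of argmax assignments or by soft (fractional) counts.  The model is
queried with *soft evidence* — a probability distribution over time-1
clusters — returning the marginal distribution over time-2 clusters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError, ParameterError, ValidationError
from .stratify import Membership

__all__ = ["TransitionModel", "estimate_transition", "predict", "trajectory_graph"]

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic CPT from time-1 cluster labels to time-2 cluster labels."""

    t1_labels: tuple[str, ...]
    t2_labels: tuple[str, ...]
    cpt: np.ndarray
    t1_marginal: np.ndarray
    counts: np.ndarray
    smoothing_alpha: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "t1_labels", tuple(str(x) for x in self.t1_labels))
        object.__setattr__(self, "t2_labels", tuple(str(x) for x in self.t2_labels))
        cpt = np.asarray(self.cpt, dtype=float)
        object.__setattr__(self, "cpt", cpt)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        marg = np.asarray(self.t1_marginal, dtype=float)
        object.__setattr__(self, "t1_marginal", marg)
        shape = (len(self.t1_labels), len(self.t2_labels))
        if cpt.shape != shape or counts.shape != shape:
            raise ValidationError(f"cpt/counts must have shape {shape}")
        if np.any(cpt < 0) or np.any(np.abs(cpt.sum(axis=1) - 1.0) > _PROB_TOL):
            raise ValidationError("every cpt row must be non-negative and sum to 1")
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        if np.any(marg < 0) or abs(marg.sum() - 1.0) > _PROB_TOL:
            raise ValidationError("t1_marginal must be a probability vector")
        if self.smoothing_alpha < 0:
            raise ValidationError("smoothing_alpha must be non-negative")

    def to_dict(self) -> dict:
        return {
            "t1_labels": list(self.t1_labels),
            "t2_labels": list(self.t2_labels),
            "cpt": self.cpt.tolist(),
            "t1_marginal": self.t1_marginal.tolist(),
            "counts": self.counts.tolist(),
            "smoothing_alpha": self.smoothing_alpha,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModel":
        return cls(
            t1_labels=tuple(d["t1_labels"]),
            t2_labels=tuple(d["t2_labels"]),
            cpt=np.asarray(d["cpt"], dtype=float),
            t1_marginal=np.asarray(d["t1_marginal"], dtype=float),
            counts=np.asarray(d["counts"], dtype=float),
            smoothing_alpha=float(d["smoothing_alpha"]),
        )

    @classmethod
    def from_json(cls, path) -> "TransitionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _membership_matrix(memberships: Sequence[Membership]) -> tuple[tuple[str, ...], np.ndarray]:
    labels = memberships[0].labels
    rows = []
    for m in memberships:
        if m.labels != labels:
            raise AlignmentError("memberships carry inconsistent label sets")
        rows.append(m.probabilities)
    return labels, np.vstack(rows)


def estimate_transition(
    memberships_t1: Sequence[Membership],
    memberships_t2: Sequence[Membership],
    mode: str = "hard",
    smoothing_alpha: float = 0.5,
    patient_ids_t1: Sequence[str] | None = None,
    patient_ids_t2: Sequence[str] | None = None,
) -> TransitionModel:
    """Estimate the CPT from aligned per-patient memberships at two timepoints.

    ``mode='hard'`` counts argmax assignments; ``'soft'`` accumulates
    fractional counts ``P(t1=i) * P(t2=j)`` per patient (identical to hard
    counting when all memberships are one-hot).  Rows are smoothed with a
    symmetric Dirichlet pseudo-count ``smoothing_alpha`` (default 0.5, which
    avoids zero rows at small n); a zero-count row with alpha = 0 falls back
    to uniform with a logged warning.

    When patient ids are given, the two sides are aligned on their shared
    ids (time-1 order) and single-timepoint patients are dropped with a
    logged count; otherwise positional alignment is assumed.
    """
    if mode not in ("hard", "soft"):
        raise ParameterError(f"mode must be 'hard' or 'soft', got {mode!r}")
    if smoothing_alpha < 0:
        raise ParameterError("smoothing_alpha must be non-negative")
    if len(memberships_t1) == 0 or len(memberships_t2) == 0:
        raise AlignmentError("need at least one patient at each timepoint")

    if patient_ids_t1 is not None or patient_ids_t2 is not None:
        if patient_ids_t1 is None or patient_ids_t2 is None:
            raise AlignmentError("provide patient ids for both timepoints or neither")
        if len(patient_ids_t1) != len(memberships_t1) or len(patient_ids_t2) != len(memberships_t2):
            raise AlignmentError("patient id lists must match membership lists")
        pos2 = {pid: i for i, pid in enumerate(patient_ids_t2)}
        keep1, keep2 = [], []
        for i, pid in enumerate(patient_ids_t1):
            if pid in pos2:
                keep1.append(i)
                keep2.append(pos2[pid])
        dropped = (len(patient_ids_t1) - len(keep1)) + (len(patient_ids_t2) - len(keep2))
        if dropped:
            logger.warning("dropped %d single-timepoint patient record(s)", dropped)
        if not keep1:
            raise AlignmentError("no patients shared between the two timepoints")
        memberships_t1 = [memberships_t1[i] for i in keep1]
        memberships_t2 = [memberships_t2[i] for i in keep2]
    elif len(memberships_t1) != len(memberships_t2):
        raise AlignmentError(
            f"{len(memberships_t1)} patients at time 1 vs {len(memberships_t2)} at "
            "time 2; pass patient ids to align"
        )

    t1_labels, M1 = _membership_matrix(memberships_t1)
    t2_labels, M2 = _membership_matrix(memberships_t2)
    if mode == "hard":
        M1 = np.eye(len(t1_labels))[np.argmax(M1, axis=1)]
        M2 = np.eye(len(t2_labels))[np.argmax(M2, axis=1)]
    counts = M1.T @ M2

    n_t2 = len(t2_labels)
    row_totals = counts.sum(axis=1)
    cpt = np.empty_like(counts)
    for i, total in enumerate(row_totals):
        denom = total + smoothing_alpha * n_t2
        if denom > 0.0:
            cpt[i] = (counts[i] + smoothing_alpha) / denom
        else:
            logger.warning(
                "t1 class %r has zero counts and alpha=0; using a uniform row",
                t1_labels[i],
            )
            cpt[i] = 1.0 / n_t2
    grand = row_totals.sum()
    marginal = row_totals / grand if grand > 0 else np.full(len(t1_labels), 1.0 / len(t1_labels))

    return TransitionModel(
        t1_labels=t1_labels,
        t2_labels=t2_labels,
        cpt=cpt,
        t1_marginal=marginal,
        counts=counts,
        smoothing_alpha=float(smoothing_alpha),
    )


def predict(membership_t1: Membership, model: TransitionModel) -> Membership:
    """Soft-evidence query: marginal over time-2 clusters given a time-1 membership.

    ``result_j = sum_i membership_i * cpt_ij`` — linear in the evidence, and
    exactly the matching CPT row for one-hot evidence.
    """
    if membership_t1.labels != model.t1_labels:
        raise AlignmentError(
            f"membership labels {membership_t1.labels} do not match model "
            f"t1 labels {model.t1_labels}"
        )
    out = membership_t1.probabilities @ model.cpt
    return Membership(model.t2_labels, out / out.sum())


def trajectory_graph(
    model: TransitionModel, min_weight: float = 0.0
) -> list[tuple[str, str, float]]:
    """Edge list ``(t1_label, t2_label, probability)`` for entries >= min_weight.

    Sorted by t1 label order, then descending probability (heavier edges
    first), then t2 label order.
    """
    if not 0.0 <= min_weight <= 1.0:
        raise ParameterError("min_weight must lie in [0, 1]")
    edges = []
    for i, a in enumerate(model.t1_labels):
        row = [
            (a, b, float(model.cpt[i, j]))
            for j, b in enumerate(model.t2_labels)
            if model.cpt[i, j] >= min_weight
        ]
        row.sort(key=lambda e: (-e[2], model.t2_labels.index(e[1])))
        edges.extend(row)
    return edges
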