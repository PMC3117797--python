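"""Multi-label K-nearest-neighbor classifier with accumulation-layer scoring.

Prediction of a query protein proceeds in two steps over its K nearest
training proteins (Euclidean distance, modes matched per the
self-consistency contract):

1. *Cardinality rule* — the number m of predicted locations equals the
   number of locations of the single nearest neighbor.
2. *Accumulation-layer (AL) scale* — each location code i in 1..8 scores
   A_i = the number of the K neighbors whose label set contains i; the m
   highest-scoring codes form the predicted set.

Ties are resolved deterministically: equal distances in the neighbor search
fall back to training order; equal AL scores prefer the code whose carriers
among the neighbors have the smaller summed distance, then the smaller code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .representation import (
    FeatureContext,
    FeatureVector,
    Mode,
    ModeMismatchError,
    matched_training_vectors,
)

logger = logging.getLogger(__name__)

LOCATION_CODES = tuple(range(1, 9))


class EmptyCandidatePoolError(ValueError):
    """Raised when no training protein is available for the neighbor search."""


@dataclass(frozen=True)
class Neighbor:
    accession: str
    distance: float
    labels: frozenset[int]


#: the K nearest training proteins, ascending by distance
NeighborSet = list[Neighbor]


@dataclass
class TrainedModel:
    """A feature context plus the classifier hyper-parameters."""

    ctx: FeatureContext
    k: int | None = None
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k is None:
            self.k = self.ctx.k
        if self.k < 1:
            raise ValueError(f"K must be >= 1, got {self.k}")
        if self.metric != "euclidean":
            raise ValueError(f"unsupported distance metric: {self.metric!r}")

    @property
    def labels(self) -> dict[str, frozenset[int]]:
        return self.ctx.labels


@dataclass
class Prediction:
    """Predicted location set of one query, with its supporting evidence."""

    accession: str
    labels: frozenset[int]
    m: int
    al: dict[int, int]
    nearest: str
    mode: Mode
    neighbors: NeighborSet = field(default_factory=list, repr=False)


def euclidean_distance(a: FeatureVector, b: FeatureVector) -> float:
    """Euclidean distance between two same-mode feature vectors.

    GO-mode vectors are sparse; the sum runs over the union of their nonzero
    ranks, which is exact because absent components are zero.
    """
    if a.mode is not b.mode:
        raise ModeMismatchError(
            f"cannot mix modes: {a.accession} is {a.mode.value}, "
            f"{b.accession} is {b.mode.value}"
        )
    if a.mode is Mode.SEQEVO:
        return float(np.linalg.norm(a.seqevo - b.seqevo))
    if a.go.U != b.go.U:
        raise ValueError("GO vectors live in different index spaces")
    total = 0.0
    ca, cb = a.go.components, b.go.components
    for rank in ca.keys() | cb.keys():
        diff = ca.get(rank, 0.0) - cb.get(rank, 0.0)
        total += diff * diff
    return math.sqrt(total)


def _go_query_dense(q: FeatureVector, go_dim: int) -> np.ndarray:
    v = np.zeros(max(go_dim, 1))
    for rank, value in q.go.components.items():
        v[rank - 1] = value
    return v


def k_nearest(
    q: FeatureVector,
    model: TrainedModel,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> NeighborSet:
    """The K training proteins nearest to the query, mode-matched.

    ``exclude`` removes training proteins from the candidate pool (the query
    itself during jackknife testing).  Ties on distance are broken by
    training order; K is clamped (with a warning) when fewer candidates
    exist than requested.
    """
    ctx = model.ctx
    if q.mode is Mode.GO:
        accs, mat, norms = ctx.go_matrix()
        if not accs:
            raise EmptyCandidatePoolError("no GO-usable training proteins")
        qv = _go_query_dense(q, ctx.go_dim)
        cross = np.asarray(mat @ qv).ravel()
        d2 = norms - 2.0 * cross + float(qv @ qv)
    else:
        accs = ctx.accessions
        mat, norms = ctx.seqevo_matrix()
        if not accs:
            raise EmptyCandidatePoolError("empty training set")
        qv = q.seqevo
        d2 = norms - 2.0 * (mat @ qv) + float(qv @ qv)
    dists = np.sqrt(np.clip(d2, 0.0, None))

    keep = [i for i, acc in enumerate(accs) if acc not in exclude]
    if not keep:
        raise EmptyCandidatePoolError(
            "candidate pool empty after exclusions"
        )
    keep = np.asarray(keep)
    # stable sort: equal distances keep training order
    order = keep[np.argsort(dists[keep], kind="stable")]

    k = model.k
    if k > len(order):
        logger.warning(
            "%s: K=%d clamped to %d available candidates",
            q.accession, k, len(order),
        )
        k = len(order)
    return [
        Neighbor(accs[i], float(dists[i]), model.labels[accs[i]])
        for i in order[:k]
    ]


def al_scale(ns: NeighborSet) -> dict[int, int]:
    """Accumulation-layer scores: A_i = #neighbors carrying location i."""
    A = {code: 0 for code in LOCATION_CODES}
    for nb in ns:
        for code in nb.labels:
            A[code] += 1
    return A


def predict_cardinality(ns: NeighborSet) -> int:
    """Predicted number of locations = cardinality of the nearest neighbor."""
    if not ns:
        raise ValueError("neighbor set is empty")
    return len(ns[0].labels)


def predict(
    q: FeatureVector,
    model: TrainedModel,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> Prediction:
    """Full two-step prediction for one query."""
    ns = k_nearest(q, model, exclude)
    A = al_scale(ns)
    m = predict_cardinality(ns)
    summed_dist = {
        code: sum(nb.distance for nb in ns if code in nb.labels)
        for code in LOCATION_CODES
    }
    ranked = sorted(
        LOCATION_CODES, key=lambda c: (-A[c], summed_dist[c], c)
    )
    labels = frozenset(ranked[:m])
    return Prediction(
        accession=q.accession,
        labels=labels,
        m=m,
        al=A,
        nearest=ns[0].accession,
        mode=q.mode,
        neighbors=ns,
    )


__all__ = [
    "EmptyCandidatePoolError",
    "Neighbor",
    "NeighborSet",
    "TrainedModel",
    "Prediction",
    "euclidean_distance",
    "k_nearest",
    "al_scale",
    "predict_cardinality",
    "predict",
    "matched_training_vectors",
]
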