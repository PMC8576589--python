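"""Triplet confidence weights and sampling distributions.

Each predication gets a raw weight

    W = (w_j * s_subject) * (w_i * s_object) * (w_p * c)

the product of its subject mapping score, object mapping score and
co-occurrence count, each under a tunable multiplier.  Raw weights are then
max-normalized over the whole graph to f = W / max(W) in (0, 1] — the raw
products can be very large (up to ~3.3e10 on real SemMedDB score scales) and
the normalization tames them while preserving order.  A softmax over the f
values of a vertex's neighborhood turns them into the next-step sampling
distribution of a confidence-biased walk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:
    from .io import KnowledgeGraph, TripletRecord

__all__ = [
    "WeightParams",
    "TripletScore",
    "raw_weight",
    "normalize_scores",
    "softmax_distribution",
    "score_graph",
    "grid_search_weights",
]


@dataclass(frozen=True)
class WeightParams:
    """Multipliers for the three confidence signals, plus numerical guards.

    ``score_floor`` replaces zero scores so no triplet ever gets weight zero
    (Weighted TransE later divides by the normalized weight).  ``temperature``
    scales the softmax; 1 reproduces the plain softmax over f values.
    """

    w_subject: float = 1.0
    w_object: float = 1.0
    w_predicate: float = 1.0
    score_floor: float = 1e-6
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_subject, self.w_object, self.w_predicate) < 0:
            raise ValueError("weight multipliers must be nonnegative")
        if self.score_floor <= 0:
            raise ValueError("score_floor must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class TripletScore:
    """Raw product weight W and its max-normalized value f in (0, 1]."""

    raw_weight: float
    normalized: float

    def __post_init__(self) -> None:
        if not (0.0 < self.normalized <= 1.0):
            raise ValueError(f"normalized score must lie in (0, 1], got {self.normalized}")


def raw_weight(record: "TripletRecord", params: WeightParams = WeightParams()) -> float:
    """Product weight of one predication, with zero scores lifted to the floor."""
    s_j = max(record.subject_score, params.score_floor)
    s_i = max(record.object_score, params.score_floor)
    c_p = max(float(record.cooccurrence), params.score_floor)
    return (params.w_subject * s_j) * (params.w_object * s_i) * (params.w_predicate * c_p)


def normalize_scores(raw_weights: Sequence[float]) -> np.ndarray:
    """Divide by the global maximum so the largest weight maps to exactly 1."""
    arr = np.asarray(raw_weights, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty weight list")
    if np.any(arr < 0):
        raise ValueError("raw weights must be nonnegative")
    m = arr.max()
    if m <= 0:
        raise ValueError("all raw weights are zero; nothing to normalize")
    return arr / m


def softmax_distribution(
    f_values: Sequence[float], temperature: float = 1.0
) -> np.ndarray:
    """Softmax with max-shift: p_k = exp(f_k/T) / sum_m exp(f_m/T)."""
    arr = np.asarray(f_values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot take softmax of an empty list")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = arr / temperature
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def score_graph(
    graph: "KnowledgeGraph", params: WeightParams = WeightParams()
) -> dict[tuple[str, str, str], TripletScore]:
    """Score every aggregated predication in a graph.

    The normalization denominator is the global maximum raw weight over the
    whole graph, computed once, so softmax comparisons are consistent across
    neighborhoods.  Returns a map keyed by (subject, predicate, object).
    """
    raws = np.array([raw_weight(rec, params) for rec in graph.records])
    normalized = normalize_scores(raws)
    # keep strictly positive after normalization (division by f downstream)
    normalized = np.maximum(normalized, params.score_floor)
    return {
        rec.key: TripletScore(raw_weight=float(w), normalized=float(f))
        for rec, w, f in zip(graph.records, raws, normalized)
    }


def grid_search_weights(
    candidates: dict[str, Sequence[float]],
    evaluate,
) -> tuple[WeightParams, float]:
    """Pick (w_subject, w_object, w_predicate) by downstream validation score.

    ``candidates`` maps 'w_subject' / 'w_object' / 'w_predicate' to candidate
    values; ``evaluate(params) -> float`` is a user-supplied figure of merit
    (higher is better), e.g. validation F1 of the downstream classifier.
    """
    from itertools import product

    best: tuple[WeightParams, float] | None = None
    for wj, wi, wp in product(
        candidates.get("w_subject", [1.0]),
        candidates.get("w_object", [1.0]),
        candidates.get("w_predicate", [1.0]),
    ):
        params = WeightParams(w_subject=wj, w_object=wi, w_predicate=wp)
        score = float(evaluate(params))
        if best is None or score > best[1]:
            best = (params, score)
    assert best is not None
    return best
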