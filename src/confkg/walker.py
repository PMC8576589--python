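"""Random-walk corpus generation: uniform (DeepWalk) and confidence-biased.

The uniform sampler picks the next (predicate, vertex) pair with probability
1/|H'(v)|.  The weighted sampler biases the choice toward high-confidence
predications by taking a softmax over the max-normalized triplet scores of the
neighborhood, so walks spend more time on well-supported parts of a noisy
literature-derived graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AdjacencyEntry, KnowledgeGraph
from .weighting import TripletScore, WeightParams, softmax_distribution

__all__ = [
    "WalkParams",
    "WalkCorpus",
    "DeadEndError",
    "uniform_next",
    "weighted_next",
    "generate_walks",
    "write_corpus",
    "read_corpus",
]

ScoreMap = dict[tuple[str, str, str], TripletScore]


class DeadEndError(RuntimeError):
    """A vertex with no outgoing adjacency was asked for a next step."""


@dataclass(frozen=True)
class WalkParams:
    """Walk-corpus shape: N walks of (up to) L vertices from every vertex."""

    num_walks_per_vertex: int = 20
    walk_length: int = 500
    seed: int = 0
    sampler: str = "uniform"
    emit_predicates: bool = False

    def __post_init__(self) -> None:
        if self.num_walks_per_vertex < 1 or self.walk_length < 1:
            raise ValueError("num_walks_per_vertex and walk_length must be >= 1")
        if self.sampler not in ("uniform", "weighted"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


@dataclass
class WalkCorpus:
    """Token sequences produced by walking, plus the token vocabulary."""

    sequences: list[list[str]]
    vocabulary: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.vocabulary:
            self.vocabulary = {t for seq in self.sequences for t in seq}

    def __len__(self) -> int:
        return len(self.sequences)


def uniform_next(
    graph: KnowledgeGraph, v: str, rng: np.random.Generator
) -> tuple[str, str]:
    """Sample a (predicate, neighbor) pair uniformly from H'(v)."""
    entries = graph.neighbors(v)
    if not entries:
        raise DeadEndError(f"vertex {v!r} has no outgoing adjacency")
    entry = entries[rng.integers(len(entries))]
    return entry.predicate, entry.neighbor


def weighted_next(
    graph: KnowledgeGraph,
    v: str,
    scores: ScoreMap,
    params: WeightParams,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Sample a (predicate, neighbor) pair from the softmax over its f scores.

    Two entries reaching the same neighbor via different predicates are
    distinct outcomes; a missing score for any entry is an error.
    """
    entries = graph.neighbors(v)
    if not entries:
        raise DeadEndError(f"vertex {v!r} has no outgoing adjacency")
    probs = _neighborhood_probs(entries, scores, params.temperature)
    entry = entries[_draw(probs.cumsum(), rng)]
    return entry.predicate, entry.neighbor


def _neighborhood_probs(
    entries: list[AdjacencyEntry], scores: ScoreMap, temperature: float
) -> np.ndarray:
    try:
        f = np.array([scores[e.key].normalized for e in entries])
    except KeyError as exc:
        raise KeyError(f"no confidence score for triplet {exc.args[0]!r}") from None
    return softmax_distribution(f, temperature)


def _draw(cumprobs: np.ndarray, rng: np.random.Generator) -> int:
    return min(int(np.searchsorted(cumprobs, rng.random(), side="right")),
               len(cumprobs) - 1)


def generate_walks(
    graph: KnowledgeGraph,
    params: WalkParams,
    scores: ScoreMap | None = None,
    weight_params: WeightParams | None = None,
) -> WalkCorpus:
    """Generate N truncated random walks from every vertex of the graph.

    Each walk's RNG stream is derived from (seed, start-vertex index, walk
    index), so the corpus is reproducible regardless of iteration order.
    Walks that hit a dead end (possible only in directed mode) stop early.
    When ``emit_predicates`` is false, only vertex tokens are emitted.
    """
    if params.sampler == "weighted":
        if scores is None:
            raise ValueError("weighted sampler requires a triplet score map")
        if weight_params is None:
            weight_params = WeightParams()

    # Per-vertex sampling tables computed once: entries + cumulative probs.
    cache: dict[str, tuple[list[AdjacencyEntry], np.ndarray] | None] = {}
    for v in graph.vertices:
        entries = graph.neighbors(v)
        if not entries:
            cache[v] = None
        elif params.sampler == "uniform":
            cache[v] = (entries, np.arange(1, len(entries) + 1) / len(entries))
        else:
            probs = _neighborhood_probs(entries, scores, weight_params.temperature)
            cache[v] = (entries, probs.cumsum())

    seed = int(params.seed) % (2**31)
    sequences: list[list[str]] = []
    for v_idx, start in enumerate(graph.vertices):
        for walk_i in range(params.num_walks_per_vertex):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, v_idx, walk_i))
            )
            tokens = [start]
            current = start
            for _ in range(params.walk_length - 1):
                table = cache[current]
                if table is None:
                    break
                entries, cum = table
                entry = entries[_draw(cum, rng)]
                if params.emit_predicates:
                    tokens.append(entry.predicate)
                tokens.append(entry.neighbor)
                current = entry.neighbor
            sequences.append(tokens)
    return WalkCorpus(sequences=sequences)


def write_corpus(corpus: WalkCorpus, path) -> None:
    """One walk per line, space-separated tokens."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq in corpus.sequences:
            fh.write(" ".join(seq) + "\n")


def read_corpus(path) -> WalkCorpus:
    with open(path, "r", encoding="utf-8") as fh:
        sequences = [line.split() for line in fh if line.strip()]
    return WalkCorpus(sequences=sequences)
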