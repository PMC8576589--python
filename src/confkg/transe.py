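"""TransE and Weighted TransE via margin-ranking SGD over corrupted triplets.

TransE embeds entities and relations so that head + relation ~ tail; the
energy of a triplet is d(h + l, t) under an L1 or L2 dissimilarity, and
training minimizes the margin-ranking loss

    L = sum over (h,l,t) in S, (h',l,t') in S'  [ gamma + d(h+l,t) - d(h'+l,t') ]_+

where S' contains corrupted triplets with the head or tail (never both)
replaced by a random entity.  The weighted variant divides the energy of the
true triplet by its confidence f in (0, 1]:

    L_w = sum [ gamma + d(h+l,t)/f - d(h'+l,t') ]_+

With all f = 1 this reduces exactly to the unweighted loss.  Confidences are
clipped to [f_min, 1] before the division so tiny f cannot produce unbounded
gradient steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embeddings import EmbeddingTable
from .io import KnowledgeGraph
from .weighting import TripletScore

__all__ = [
    "TransEParams",
    "TrainingTriplet",
    "TransEModel",
    "energy",
    "corrupt",
    "margin_loss",
    "train_transe",
    "training_triplets",
    "mean_rank",
]


@dataclass(frozen=True)
class TransEParams:
    dimension: int = 100
    margin: float = 1.0
    norm: str = "L2"
    alpha: float = 0.001
    batch_size: int = 256
    epochs: int = 100
    negatives_per_positive: int = 1
    f_min: float = 1e-3
    seed: int = 0
    # ablation: multiply the positive energy by f instead of dividing (off by
    # default; the division form is the reference behavior)
    multiply_by_f: bool = False

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.norm not in ("L1", "L2"):
            raise ValueError("norm must be 'L1' or 'L2'")
        if not (0.0 < self.f_min <= 1.0):
            raise ValueError("f_min must lie in (0, 1]")
        if self.negatives_per_positive < 1:
            raise ValueError("negatives_per_positive must be >= 1")


@dataclass(frozen=True)
class TrainingTriplet:
    """A (head, relation, tail) training example with confidence f in (0, 1]."""

    head: str
    relation: str
    tail: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.head or not self.tail:
            raise ValueError("head and tail must be non-empty")
        if not (0.0 < self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in (0, 1], got {self.confidence}")


def energy(
    h_vec: np.ndarray, l_vec: np.ndarray, t_vec: np.ndarray, norm: str = "L2"
) -> float:
    """Dissimilarity d(h + l, t): L1 or L2 norm of the translation residual."""
    h_vec, l_vec, t_vec = map(np.asarray, (h_vec, l_vec, t_vec))
    if not (h_vec.shape == l_vec.shape == t_vec.shape):
        raise ValueError("h, l, t must share one dimension")
    diff = h_vec + l_vec - t_vec
    if norm == "L1":
        return float(np.abs(diff).sum())
    if norm == "L2":
        return float(np.sqrt((diff**2).sum()))
    raise ValueError("norm must be 'L1' or 'L2'")


def corrupt(
    triplet: TrainingTriplet, entity_pool: list[str], rng: np.random.Generator
) -> TrainingTriplet:
    """Replace head or tail (50/50, never both, never the relation) by a
    uniformly drawn entity different from the original."""
    if len(entity_pool) < 2:
        raise ValueError("entity pool must contain at least 2 entities")
    replace_head = rng.random() < 0.5
    original = triplet.head if replace_head else triplet.tail
    replacement = original
    while replacement == original:
        replacement = entity_pool[rng.integers(len(entity_pool))]
    if replace_head:
        return TrainingTriplet(replacement, triplet.relation, triplet.tail, triplet.confidence)
    return TrainingTriplet(triplet.head, triplet.relation, replacement, triplet.confidence)


def margin_loss(
    positives: list[TrainingTriplet],
    negatives: list[TrainingTriplet],
    embeddings: tuple[EmbeddingTable, EmbeddingTable],
    params: TransEParams = TransEParams(),
) -> float:
    """Hinge loss sum [gamma + d(h+l,t)/f - d(h'+l,t')]_+ over aligned pairs.

    ``negatives`` holds negatives_per_positive corrupted triplets per positive,
    in positive-major order.  Confidences are clipped to [f_min, 1]; with all
    f = 1 the value equals the unweighted TransE loss exactly.
    """
    npp = params.negatives_per_positive
    if len(negatives) != len(positives) * npp:
        raise ValueError(
            f"expected {len(positives) * npp} negatives, got {len(negatives)}"
        )
    ent, rel = embeddings
    total = 0.0
    for i, pos in enumerate(positives):
        f = min(max(pos.confidence, params.f_min), 1.0)
        if not (0.0 < f <= 1.0):
            raise ValueError(f"confidence {f} outside (0, 1] after clipping")
        d_pos = energy(ent[pos.head], rel[pos.relation], ent[pos.tail], params.norm)
        scaled = d_pos * f if params.multiply_by_f else d_pos / f
        for neg in negatives[i * npp : (i + 1) * npp]:
            d_neg = energy(ent[neg.head], rel[neg.relation], ent[neg.tail], params.norm)
            total += max(params.margin + scaled - d_neg, 0.0)
    return total


@dataclass
class TransEModel:
    """Trained entity/relation tables plus the epoch-mean loss trajectory."""

    entity_table: EmbeddingTable
    relation_table: EmbeddingTable
    loss_history: list[float] = field(default_factory=list)
    params: TransEParams | None = None

    def __iter__(self):
        return iter((self.entity_table, self.relation_table))


def _distances(diff: np.ndarray, norm: str) -> np.ndarray:
    if norm == "L1":
        return np.abs(diff).sum(axis=-1)
    return np.sqrt((diff**2).sum(axis=-1))


def _grad(diff: np.ndarray, d: np.ndarray, norm: str) -> np.ndarray:
    """d(dissimilarity)/d(diff) for each row."""
    if norm == "L1":
        return np.sign(diff)
    return diff / np.maximum(d, 1e-12)[:, None]


def train_transe(
    triplets: list[TrainingTriplet], params: TransEParams = TransEParams()
) -> TransEModel:
    """Minibatch SGD on the (weighted) margin-ranking loss.

    Entities initialize uniform in [-6/sqrt(k), 6/sqrt(k)] and are renormalized
    to unit L2 after every update step; relations are normalized once at
    initialization.  For unweighted TransE pass triplets with confidence 1.
    Deterministic given the seed.
    """
    if not triplets:
        raise ValueError("cannot train on an empty triplet list")
    entities: list[str] = []
    relations: list[str] = []
    e_idx: dict[str, int] = {}
    r_idx: dict[str, int] = {}
    for t in triplets:
        for e in (t.head, t.tail):
            if e not in e_idx:
                e_idx[e] = len(entities)
                entities.append(e)
        if t.relation not in r_idx:
            r_idx[t.relation] = len(relations)
            relations.append(t.relation)

    k = params.dimension
    rng = np.random.default_rng(int(params.seed) % (2**31))
    bound = 6.0 / np.sqrt(k)
    E = rng.uniform(-bound, bound, size=(len(entities), k))
    R = rng.uniform(-bound, bound, size=(len(relations), k))
    R /= np.maximum(np.linalg.norm(R, axis=1, keepdims=True), 1e-12)
    E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)

    h = np.array([e_idx[t.head] for t in triplets])
    r = np.array([r_idx[t.relation] for t in triplets])
    t_ = np.array([e_idx[t.tail] for t in triplets])
    f = np.clip([t.confidence for t in triplets], params.f_min, 1.0)

    n = len(triplets)
    npp = params.negatives_per_positive
    n_ent = len(entities)
    history: list[float] = []
    for _ in range(params.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, params.batch_size):
            sel = perm[start : start + params.batch_size]
            rep = np.repeat(sel, npp)
            hb, rb, tb, fb = h[rep], r[rep], t_[rep], f[rep]
            m = rep.size

            # corrupt: replace head or tail, never both, replacement != original
            replace_head = rng.random(m) < 0.5
            original = np.where(replace_head, hb, tb)
            repl = rng.integers(n_ent, size=m)
            while True:
                clash = repl == original
                if not clash.any():
                    break
                repl[clash] = rng.integers(n_ent, size=int(clash.sum()))
            hn = np.where(replace_head, repl, hb)
            tn = np.where(replace_head, tb, repl)

            diff_p = E[hb] + R[rb] - E[tb]
            diff_n = E[hn] + R[rb] - E[tn]
            d_p = _distances(diff_p, params.norm)
            d_n = _distances(diff_n, params.norm)
            scale = fb if params.multiply_by_f else 1.0 / fb
            viol = params.margin + d_p * scale - d_n
            active = viol > 0
            epoch_loss += float(viol[active].sum())
            if not active.any():
                continue

            a = active
            g_p = _grad(diff_p[a], d_p[a], params.norm) * scale[a][:, None]
            g_n = _grad(diff_n[a], d_n[a], params.norm)
            lr = params.alpha
            np.add.at(E, hb[a], -lr * g_p)
            np.add.at(E, tb[a], lr * g_p)
            np.add.at(E, hn[a], lr * g_n)
            np.add.at(E, tn[a], -lr * g_n)
            np.add.at(R, rb[a], -lr * (g_p - g_n))
            E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
        history.append(epoch_loss / n)

    return TransEModel(
        entity_table=EmbeddingTable(entities, E, normalized=True),
        relation_table=EmbeddingTable(relations, R),
        loss_history=history,
        params=params,
    )


def training_triplets(
    graph: KnowledgeGraph,
    scores: dict[tuple[str, str, str], TripletScore] | None = None,
    f_min: float = 1e-3,
) -> list[TrainingTriplet]:
    """Convert a graph's aggregated predications into training triplets.

    With ``scores`` the confidence is the max-normalized triplet weight
    (Weighted TransE); without, every confidence is 1 (plain TransE).
    """
    out = []
    for rec in graph.records:
        if scores is None:
            conf = 1.0
        else:
            conf = float(np.clip(scores[rec.key].normalized, f_min, 1.0))
        out.append(TrainingTriplet(rec.subject_id, rec.predicate, rec.object_id, conf))
    return out


def mean_rank(
    triplets: list[TrainingTriplet],
    entity_table: EmbeddingTable,
    relation_table: EmbeddingTable,
    norm: str = "L2",
    filtered: bool = True,
) -> float:
    """Mean rank of the true tail under exhaustive candidate scoring.

    For each triplet, every entity is scored as a candidate tail by energy and
    the true tail's 1-based rank recorded (average rank over ties).  With
    ``filtered``, other known true tails for the same (head, relation) are
    excluded from the candidate list.
    """
    ents = entity_table.tokens
    M = entity_table.matrix
    known: dict[tuple[str, str], set[str]] = {}
    for t in triplets:
        known.setdefault((t.head, t.relation), set()).add(t.tail)
    ranks = []
    for t in triplets:
        query = entity_table[t.head] + relation_table[t.relation]
        diff = query[None, :] - M
        d = np.abs(diff).sum(axis=1) if norm == "L1" else np.linalg.norm(diff, axis=1)
        mask = np.ones(len(ents), dtype=bool)
        if filtered:
            for other in known[(t.head, t.relation)]:
                if other != t.tail:
                    mask[entity_table.tokens.index(other)] = False
        d_true = d[ents.index(t.tail)]
        d_cand = d[mask]
        rank = 1 + (d_cand < d_true).sum() + 0.5 * ((d_cand == d_true).sum() - 1)
        ranks.append(rank)
    return float(np.mean(ranks))
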