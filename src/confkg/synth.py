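"""Synthetic noisy knowledge graphs with planted drug-ADE structure.

The generator emulates the salient statistics of a literature-derived
predication store: concepts (drugs, diseases, filler concepts) are organised
into causal blocks; true predications connect concepts within a block, while
spurious predications connect uniformly random concept pairs.  Confidence
scores are truth-correlated — true triplets draw high subject/object mapping
scores and high co-occurrence counts, spurious ones draw from a low regime —
so confidence-weighted methods have signal to exploit.  Benchmark drug-ADE
pairs are labeled positive exactly when the drug and disease share a block.

The spurious fraction is budgeted exactly (not Bernoulli-sampled) and every
draw flows from the seed, so outputs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ade import LabeledPair, LabeledTriple, write_pairs, write_triples
from .io import TripletRecord, write_triplets

__all__ = ["ScoreModel", "SynthConfig", "SynthOutput", "generate", "export",
           "generate_polypharmacy"]


@dataclass(frozen=True)
class ScoreModel:
    """Score distributions conditional on a triplet being true or spurious.

    Co-occurrence counts are 1 + Poisson(lambda); subject/object mapping
    scores are uniform over the given range (SemMedDB-like 0-1000 scale).
    """

    true_cooc_lambda: float = 8.0
    spurious_cooc_lambda: float = 1.0
    true_score_range: tuple[float, float] = (600.0, 1000.0)
    spurious_score_range: tuple[float, float] = (50.0, 400.0)


@dataclass(frozen=True)
class SynthConfig:
    """Shape and noise level of the generated knowledge graph.

    The triplet budget is ``round(edges_per_vertex * n_vertices)`` with a
    fraction ``noise_rate`` of exactly-budgeted spurious triplets.
    ``benchmark_pairs_per_class`` caps each class of the drug-ADE benchmark.
    """

    n_drugs: int = 50
    n_diseases: int = 10
    n_filler_concepts: int = 100
    n_predicates: int = 4
    n_blocks: int = 2
    edges_per_vertex: float = 12.0
    noise_rate: float = 0.3
    score_model: ScoreModel = field(default_factory=ScoreModel)
    benchmark_pairs_per_class: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate must lie in [0, 1)")
        if self.n_blocks > min(self.n_drugs, self.n_diseases):
            raise ValueError("n_blocks cannot exceed min(n_drugs, n_diseases)")
        if self.edges_per_vertex <= 0:
            raise ValueError("edges_per_vertex must be positive")

    @property
    def n_vertices(self) -> int:
        return self.n_drugs + self.n_diseases + self.n_filler_concepts


@dataclass
class SynthOutput:
    """Generated triplets with per-triplet truth flags and derived benchmarks."""

    triplets: list[TripletRecord]
    truth_flags: list[bool]
    benchmark_pairs: list[LabeledPair]
    benchmark_triples: list[LabeledTriple] | None = None
    blocks: dict[str, int] = field(default_factory=dict)


def _concept_ids(config: SynthConfig) -> tuple[list[str], list[str], list[str]]:
    drugs = [f"DRUG{i:03d}" for i in range(config.n_drugs)]
    diseases = [f"DIS{i:03d}" for i in range(config.n_diseases)]
    filler = [f"CONC{i:03d}" for i in range(config.n_filler_concepts)]
    return drugs, diseases, filler


def _assign_blocks(ids: list[str], n_blocks: int) -> dict[str, int]:
    # round-robin keeps every block populated for every concept class
    return {cid: i % n_blocks for i, cid in enumerate(ids)}


def _draw_scores(
    rng: np.random.Generator, model: ScoreModel, true: bool, size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo, hi = model.true_score_range if true else model.spurious_score_range
    lam = model.true_cooc_lambda if true else model.spurious_cooc_lambda
    subj = rng.uniform(lo, hi, size)
    obj = rng.uniform(lo, hi, size)
    cooc = 1 + rng.poisson(lam, size)
    return subj, obj, cooc


def generate(config: SynthConfig) -> SynthOutput:
    """Generate the noisy KG and its drug-ADE benchmark, reproducibly."""
    rng = np.random.default_rng(int(config.seed) % (2**31))
    drugs, diseases, filler = _concept_ids(config)
    all_ids = drugs + diseases + filler
    blocks = {}
    for group in (drugs, diseases, filler):
        blocks.update(_assign_blocks(group, config.n_blocks))
    members = [
        [cid for cid in all_ids if blocks[cid] == b] for b in range(config.n_blocks)
    ]
    predicates = [f"PRED{i}" for i in range(config.n_predicates)]

    total = int(round(config.edges_per_vertex * config.n_vertices))
    n_spurious = int(round(config.noise_rate * total))
    n_true = total - n_spurious
    if n_true < 1:
        raise ValueError("edge budget leaves no true triplets")

    triplets: list[TripletRecord] = []
    flags: list[bool] = []
    used: set[tuple[str, str, str]] = set()

    subj_s, obj_s, cooc = _draw_scores(rng, config.score_model, True, n_true)
    for i in range(n_true):
        b = int(rng.integers(config.n_blocks))
        group = members[b]
        si, oi = rng.choice(len(group), size=2, replace=False)
        triplets.append(
            TripletRecord(
                group[si],
                predicates[int(rng.integers(config.n_predicates))],
                group[oi],
                float(subj_s[i]),
                float(obj_s[i]),
                int(cooc[i]),
            )
        )
        used.add(triplets[-1].key)
        flags.append(True)

    subj_s, obj_s, cooc = _draw_scores(rng, config.score_model, False, n_spurious)
    i = 0
    while i < n_spurious:
        si, oi = rng.choice(len(all_ids), size=2, replace=False)
        key = (
            all_ids[si],
            predicates[int(rng.integers(config.n_predicates))],
            all_ids[oi],
        )
        if key in used:  # keep truth flags unambiguous per (s, p, o)
            continue
        used.add(key)
        triplets.append(
            TripletRecord(*key, float(subj_s[i]), float(obj_s[i]), int(cooc[i]))
        )
        flags.append(False)
        i += 1

    benchmark = _benchmark_pairs(rng, config, drugs, diseases, blocks)
    return SynthOutput(
        triplets=triplets,
        truth_flags=flags,
        benchmark_pairs=benchmark,
        blocks=blocks,
    )


def _benchmark_pairs(
    rng: np.random.Generator,
    config: SynthConfig,
    drugs: list[str],
    diseases: list[str],
    blocks: dict[str, int],
) -> list[LabeledPair]:
    positives = [
        (d, z) for d in drugs for z in diseases if blocks[d] == blocks[z]
    ]
    negatives = [
        (d, z) for d in drugs for z in diseases if blocks[d] != blocks[z]
    ]
    k = config.benchmark_pairs_per_class
    pos_idx = rng.choice(len(positives), size=min(k, len(positives)), replace=False)
    neg_idx = rng.choice(len(negatives), size=min(k, len(negatives)), replace=False)
    pairs = [LabeledPair(*positives[i], label=1) for i in sorted(pos_idx)]
    pairs += [LabeledPair(*negatives[i], label=-1) for i in sorted(neg_idx)]
    return pairs


def generate_polypharmacy(
    config: SynthConfig, n_side_effects: int = 6, triples_per_side_effect: int = 40
) -> list[LabeledTriple]:
    """Valid polypharmacy triples: drug pairs sharing a block cause the side
    effects assigned to that block.  Pair with
    :func:`confkg.ade.sample_negative_triples` for the invalid class."""
    rng = np.random.default_rng((int(config.seed) + 1) % (2**31))
    drugs, _, _ = _concept_ids(config)
    blocks = _assign_blocks(drugs, config.n_blocks)
    ses = [f"SE{i:02d}" for i in range(n_side_effects)]
    se_block = {se: i % config.n_blocks for i, se in enumerate(ses)}
    triples: list[LabeledTriple] = []
    seen: set[tuple[str, str, str]] = set()
    for se in ses:
        b = se_block[se]
        pool = [d for d in drugs if blocks[d] == b]
        attempts = 0
        while (
            sum(1 for t in triples if t.side_effect_id == se)
            < triples_per_side_effect
            and attempts < 50 * triples_per_side_effect
        ):
            attempts += 1
            i, j = rng.choice(len(pool), size=2, replace=False)
            t = LabeledTriple(pool[i], se, pool[j], label=1)
            if t.key in seen:
                continue
            seen.add(t.key)
            triples.append(t)
    return triples


def export(output: SynthOutput, directory: str | Path) -> dict[str, Path]:
    """Write the triplet TSV, benchmark CSV(s), and a truth-flag sidecar.

    The sidecar is test-only ground truth; no pipeline stage reads it.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "triplets": directory / "triplets.tsv",
        "pairs": directory / "benchmark_pairs.csv",
        "truth": directory / "truth_flags.tsv",
    }
    write_triplets(output.triplets, paths["triplets"])
    write_pairs(output.benchmark_pairs, paths["pairs"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("SUBJECT_ID\tPREDICATE\tOBJECT_ID\tIS_TRUE\n")
        for rec, flag in zip(output.triplets, output.truth_flags):
            fh.write(
                f"{rec.subject_id}\t{rec.predicate}\t{rec.object_id}\t{int(flag)}\n"
            )
    if output.benchmark_triples is not None:
        paths["triples"] = directory / "benchmark_triples.csv"
        write_triples(output.benchmark_triples, paths["triples"])
    return paths
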