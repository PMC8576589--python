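import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")

from confkg.io import TripletRecord, build_graph
from confkg.synth import SynthConfig, generate
from confkg.transe import TrainingTriplet


@pytest.fixture
def toy_records():
    return [
        TripletRecord("C01", "TREATS", "C02", 800, 900, 5),
        TripletRecord("C01", "CAUSES", "C03", 700, 650, 2),
        TripletRecord("C03", "ISA", "C04", 1000, 1000, 1),
    ]


@pytest.fixture
def toy_graph(toy_records):
    return build_graph(toy_records, mode="undirected")


@pytest.fixture(scope="session")
def synth_default():
    """One synthetic noisy KG at the default configuration."""
    return generate(SynthConfig(seed=0))


def random_triplet_kg(seed, n_entities=20, n_relations=2, n_triplets=60):
    """Random distinct (h, l, t) training triplets over a small entity set."""
    rng = np.random.default_rng(seed)
    ents = [f"E{i}" for i in range(n_entities)]
    rels = [f"R{i}" for i in range(n_relations)]
    seen, trips = set(), []
    while len(trips) < n_triplets:
        h, t = rng.choice(n_entities, 2, replace=False)
        r = int(rng.integers(n_relations))
        key = (ents[h], rels[r], ents[t])
        if key in seen:
            continue
        seen.add(key)
        trips.append(TrainingTriplet(*key))
    return ents, rels, trips


def ring_kg_with_spurious(seed, n=20, n_spurious=12, f_spurious=1e-3):
    """A translation-realizable ring (NEXT/PREV) plus low-confidence chords.

    The ring is exactly embeddable by translations, so consistent triplets can
    reach genuinely low energy; the chords are the spurious, low-confidence
    contamination.
    """
    ents = [f"E{i}" for i in range(n)]
    true_t = [TrainingTriplet(ents[i], "NEXT", ents[(i + 1) % n]) for i in range(n)]
    true_t += [TrainingTriplet(ents[i], "PREV", ents[(i - 1) % n]) for i in range(n)]
    seen = {(t.head, t.relation, t.tail) for t in true_t}
    rng = np.random.default_rng(900 + seed)
    spur = []
    while len(spur) < n_spurious:
        h, t = rng.choice(n, 2, replace=False)
        r = ["NEXT", "PREV"][int(rng.integers(2))]
        key = (ents[h], r, ents[t])
        if key in seen:
            continue
        seen.add(key)
        spur.append(TrainingTriplet(*key, confidence=f_spurious))
    return true_t, spur
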