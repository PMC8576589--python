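"""Named hyperparameter profiles.

The ``drug_ade_*`` and ``polypharmacy_*`` profiles carry the settings used for
the two benchmark tasks on the full literature-derived graph; the
``semmeddb_augmented_*`` profiles are the heavier settings for a
93M-predication graph and are cluster-scale.  The ``synthetic_*`` profiles are
this package's desk-scale settings for the bundled synthetic benchmark.
"""

from __future__ import annotations

from .sgns import SGNSParams
from .transe import TransEParams
from .walker import WalkParams

__all__ = ["DEEPWALK_PROFILES", "TRANSE_PROFILES", "deepwalk_profile",
           "transe_profile"]

# (walk params, sgns params); dicts are overlaid onto the dataclass defaults
DEEPWALK_PROFILES: dict[str, dict] = {
    "drug_ade_deepwalk": {
        "walk": {"num_walks_per_vertex": 20, "walk_length": 500},
        "sgns": {"window": 4, "alpha": 0.025, "dimension": 256},
    },
    "polypharmacy_deepwalk": {
        "walk": {"num_walks_per_vertex": 25, "walk_length": 500},
        "sgns": {"window": 10, "alpha": 0.025, "dimension": 256},
    },
    # cluster-scale: 93M-triplet augmented graph
    "semmeddb_augmented_deepwalk": {
        "walk": {"num_walks_per_vertex": 375, "walk_length": 500},
        "sgns": {"window": 10, "alpha": 0.025, "dimension": 256},
    },
    # desk-scale synthetic benchmark: walk count and window as in the
    # drug-ADE profile, walk length and dimension scaled to the graph size
    "synthetic_deepwalk": {
        "walk": {"num_walks_per_vertex": 20, "walk_length": 40},
        "sgns": {"window": 4, "alpha": 0.025, "dimension": 64, "epochs": 5},
    },
}

TRANSE_PROFILES: dict[str, dict] = {
    "drug_ade_transe": {
        "alpha": 0.001, "batch_size": 256, "epochs": 100,
        "negatives_per_positive": 1, "dimension": 100,
    },
    "polypharmacy_transe": {
        "alpha": 0.001, "batch_size": 512, "epochs": 100,
        "negatives_per_positive": 1, "dimension": 100,
    },
    # cluster-scale: 93M-triplet augmented graph
    "semmeddb_augmented_transe": {
        "alpha": 0.001, "batch_size": 512, "epochs": 1500,
        "negatives_per_positive": 2, "dimension": 100,
    },
    # desk-scale synthetic benchmark: reduced dimension, learning rate raised
    # until the epoch-mean loss converges within the shortened epoch budget
    "synthetic_transe": {
        "alpha": 0.01, "batch_size": 256, "epochs": 60,
        "negatives_per_positive": 1, "dimension": 32,
    },
}


def deepwalk_profile(
    name: str, seed: int = 0, sampler: str = "uniform"
) -> tuple[WalkParams, SGNSParams]:
    spec = DEEPWALK_PROFILES[name]
    walk = WalkParams(seed=seed, sampler=sampler, **spec["walk"])
    sgns = SGNSParams(seed=seed, **spec["sgns"])
    return walk, sgns


def transe_profile(name: str, seed: int = 0) -> TransEParams:
    return TransEParams(seed=seed, **TRANSE_PROFILES[name])
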