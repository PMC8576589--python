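"""Downstream prediction pipelines: drug-ADE pairs and polypharmacy triples.

Embeddings learned from the knowledge graph become classifier features by
concatenation: drug ++ disease for adverse-drug-event (ADE) pair
classification, drug1 ++ drug2 ++ side-effect for polypharmacy triple
classification.  Evaluation follows leave-one-out (LOO), stratified 5-fold
(S5F) and cross-dataset protocols with F1/AUC, plus per-side-effect
AUC/AUPRC/AP@50 for the polypharmacy task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .embeddings import EmbeddingTable
from .io import TripletRecord

__all__ = [
    "LabeledPair",
    "LabeledTriple",
    "ClassifierSpec",
    "MetricsReport",
    "read_pairs",
    "write_pairs",
    "read_triples",
    "write_triples",
    "filter_missing",
    "filter_missing_triples",
    "build_pair_features",
    "build_triple_features",
    "make_cv_splits",
    "sample_negative_triples",
    "compute_occurrence_scores",
    "polypharmacy_records",
    "train_eval",
    "cross_dataset_eval",
    "per_side_effect_eval",
    "compute_metrics",
]


@dataclass(frozen=True)
class LabeledPair:
    """A drug-disease pair labeled +1 (the drug causes the ADE) or -1."""

    drug_id: str
    disease_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (1, -1):
            raise ValueError("pair label must be +1 or -1")


@dataclass(frozen=True)
class LabeledTriple:
    """A drug1-side_effect-drug2 triple labeled 1 (valid) or 0.

    The drug pair is unordered; construction canonicalizes to drug1 <= drug2.
    """

    drug1_id: str
    side_effect_id: str
    drug2_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("triple label must be 0 or 1")
        if self.drug1_id > self.drug2_id:
            d1, d2 = self.drug2_id, self.drug1_id
            object.__setattr__(self, "drug1_id", d1)
            object.__setattr__(self, "drug2_id", d2)

    @property
    def drug_pair(self) -> tuple[str, str]:
        return (self.drug1_id, self.drug2_id)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.drug1_id, self.side_effect_id, self.drug2_id)


# The three classifier families, pinned to fixed hyperparameters so results
# do not drift with library-version default changes.
_CLASSIFIER_DEFAULTS: dict[str, dict] = {
    "LR": {"l1_ratio": 1.0, "solver": "liblinear", "C": 1.0, "max_iter": 1000},
    "KNN": {"n_neighbors": 5, "weights": "uniform", "metric": "minkowski", "p": 2},
    "RF": {"criterion": "entropy", "n_estimators": 100, "max_depth": None},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the named classifier configurations: LR (L1), KNN (k=5), RF
    (entropy); ``settings`` overrides are merged over the pinned defaults.
    The polypharmacy RF uses 100 trees with max depth 20."""

    family: str
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _CLASSIFIER_DEFAULTS:
            raise ValueError(f"unknown classifier family {self.family!r}")

    @classmethod
    def polypharmacy_rf(cls) -> "ClassifierSpec":
        return cls("RF", {"n_estimators": 100, "max_depth": 20})

    def build(self, seed: int = 0):
        kwargs = dict(_CLASSIFIER_DEFAULTS[self.family])
        kwargs.update(self.settings)
        if self.family == "LR":
            return LogisticRegression(random_state=seed, **kwargs)
        if self.family == "KNN":
            return KNeighborsClassifier(**kwargs)
        return RandomForestClassifier(random_state=seed, **kwargs)


@dataclass
class MetricsReport:
    """Per-fold and aggregate classification metrics.

    For S5F, ``per_fold`` holds one metric dict per fold and mean/sd aggregate
    them.  For LOO, predictions are pooled across the n singleton test folds
    and scored once (per-fold AUC is undefined at test size 1), so sd is 0.
    """

    scheme: str
    per_fold: list[dict[str, float]]
    mean: dict[str, float]
    sd: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "sd": self.sd,
        }


def read_pairs(path: str | Path) -> list[LabeledPair]:
    """CSV with columns DRUG_ID, DISEASE_ID, LABEL (+1/-1)."""
    df = pd.read_csv(path, dtype={"DRUG_ID": str, "DISEASE_ID": str})
    return [
        LabeledPair(row.DRUG_ID, row.DISEASE_ID, int(row.LABEL))
        for row in df.itertuples()
    ]


def write_pairs(pairs: list[LabeledPair], path: str | Path) -> None:
    pd.DataFrame(
        [(p.drug_id, p.disease_id, p.label) for p in pairs],
        columns=["DRUG_ID", "DISEASE_ID", "LABEL"],
    ).to_csv(path, index=False)


def read_triples(path: str | Path) -> list[LabeledTriple]:
    """CSV with columns DRUG1, SIDE_EFFECT, DRUG2, LABEL (1/0)."""
    df = pd.read_csv(path, dtype={"DRUG1": str, "SIDE_EFFECT": str, "DRUG2": str})
    return [
        LabeledTriple(row.DRUG1, row.SIDE_EFFECT, row.DRUG2, int(row.LABEL))
        for row in df.itertuples()
    ]


def write_triples(triples: list[LabeledTriple], path: str | Path) -> None:
    pd.DataFrame(
        [(t.drug1_id, t.side_effect_id, t.drug2_id, t.label) for t in triples],
        columns=["DRUG1", "SIDE_EFFECT", "DRUG2", "LABEL"],
    ).to_csv(path, index=False)


def filter_missing(
    pairs: list[LabeledPair], table: EmbeddingTable
) -> tuple[list[LabeledPair], list[str]]:
    """Drop pairs whose drug or disease has no embedding; report dropped ids."""
    kept, removed = [], set()
    for p in pairs:
        missing = [c for c in (p.drug_id, p.disease_id) if c not in table]
        if missing:
            removed.update(missing)
        else:
            kept.append(p)
    return kept, sorted(removed)


def filter_missing_triples(
    triples: list[LabeledTriple], table: EmbeddingTable
) -> tuple[list[LabeledTriple], list[str]]:
    kept, removed = [], set()
    for t in triples:
        missing = [c for c in t.key if c not in table]
        if missing:
            removed.update(missing)
        else:
            kept.append(t)
    return kept, sorted(removed)


def build_pair_features(table: EmbeddingTable, pair: LabeledPair) -> np.ndarray:
    """Concatenate drug then disease embedding: a 2*dim feature vector."""
    return np.concatenate([table[pair.drug_id], table[pair.disease_id]])


def build_triple_features(table: EmbeddingTable, triple: LabeledTriple) -> np.ndarray:
    """Concatenate drug1, drug2, then side-effect embedding: 3*dim features."""
    return np.concatenate(
        [table[triple.drug1_id], table[triple.drug2_id], table[triple.side_effect_id]]
    )


def make_cv_splits(
    labels, scheme: str, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cross-validation folds: 'LOO' (n singleton folds) or 'S5F' (stratified
    5-fold, shuffled by seed; per-fold class counts within 1 of proportional).
    For the cross-dataset protocol see :func:`cross_dataset_eval`."""
    y = np.asarray(labels)
    if y.size < 2:
        raise ValueError("need at least 2 samples to cross-validate")
    if scheme == "LOO":
        return list(LeaveOneOut().split(np.zeros((y.size, 1)), y))
    if scheme == "S5F":
        values, counts = np.unique(y, return_counts=True)
        small = values[counts < 5]
        if small.size:
            raise ValueError(
                f"stratified 5-fold needs >= 5 members per class; class "
                f"{small[0]!r} has {int(counts[counts < 5][0])}"
            )
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        return list(skf.split(np.zeros((y.size, 1)), y))
    raise ValueError(f"unknown CV scheme {scheme!r}")


def sample_negative_triples(
    known_triples: list[LabeledTriple],
    n: int,
    drug_pool: list[str],
    side_effect_pool: list[str],
    rng: np.random.Generator,
) -> list[LabeledTriple]:
    """Draw n distinct invalid triples (label 0) avoiding all known triples.

    The candidate space is unordered distinct drug pairs x side effects; an n
    beyond the free space is an error.
    """
    drugs = sorted(set(drug_pool))
    ses = sorted(set(side_effect_pool))
    known = {t.key for t in known_triples}
    n_pairs = len(drugs) * (len(drugs) - 1) // 2
    space = n_pairs * len(ses)
    known_in_space = sum(
        1
        for k in known
        if k[0] in drugs and k[2] in drugs and k[1] in ses and k[0] != k[2]
    )
    free = space - known_in_space
    if n > free:
        raise ValueError(f"requested {n} negatives but only {free} are available")

    out: list[LabeledTriple] = []
    chosen: set[tuple[str, str, str]] = set()
    if space <= 200_000:
        candidates = [
            (drugs[i], s, drugs[j])
            for i in range(len(drugs))
            for j in range(i + 1, len(drugs))
            for s in ses
            if (drugs[i], s, drugs[j]) not in known
        ]
        idx = rng.choice(len(candidates), size=n, replace=False)
        return [LabeledTriple(*candidates[i], label=0) for i in idx]
    while len(out) < n:
        i, j = rng.choice(len(drugs), size=2, replace=False)
        d1, d2 = sorted((drugs[i], drugs[j]))
        s = ses[rng.integers(len(ses))]
        key = (d1, s, d2)
        if key in known or key in chosen:
            continue
        chosen.add(key)
        out.append(LabeledTriple(d1, s, d2, label=0))
    return out


def compute_occurrence_scores(triples: list[LabeledTriple]) -> np.ndarray:
    """Occurrence score of each triple: how many input triples share its drug
    pair, regardless of side effect."""
    counts: dict[tuple[str, str], int] = {}
    for t in triples:
        counts[t.drug_pair] = counts.get(t.drug_pair, 0) + 1
    return np.array([counts[t.drug_pair] for t in triples])


def polypharmacy_records(triples: list[LabeledTriple]) -> list[TripletRecord]:
    """Valid triples as KG predications (side effect = relation) with the
    occurrence score as co-occurrence and subject/object scores set to 1."""
    valid = [t for t in triples if t.label == 1]
    occ = compute_occurrence_scores(valid)
    return [
        TripletRecord(t.drug1_id, t.side_effect_id, t.drug2_id, 1.0, 1.0, int(c))
        for t, c in zip(valid, occ)
    ]


def compute_metrics(
    y_true, y_score, threshold: float = 0.5, ap_k: int = 50
) -> dict[str, float]:
    """F1 (positive class, score >= threshold), AUC, AUPRC, and AP@k.

    AUC uses the rank statistic with midrank tie handling; AUPRC is the
    step-wise integral of the precision-recall curve; AP@k averages
    precision-at-i over the relevant items in the top k,
    sum_{i<=k} precision@i * rel(i) / min(k, #positives).
    """
    y = (np.asarray(y_true) > 0).astype(int)
    s = np.asarray(y_score, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("AUC/AUPRC undefined: y_true contains a single class")
    order = np.argsort(-s, kind="stable")
    rel = y[order][:ap_k]
    hits = np.cumsum(rel)
    prec_at_i = hits / np.arange(1, rel.size + 1)
    ap_at_k = float((prec_at_i * rel).sum() / min(ap_k, int(y.sum())))
    return {
        "F1": float(f1_score(y, (s >= threshold).astype(int), zero_division=0.0)),
        "AUC": float(roc_auc_score(y, s)),
        "AUPRC": float(average_precision_score(y, s)),
        "AP@50": ap_at_k,
    }


def _positive_scores(clf, X: np.ndarray) -> np.ndarray:
    proba = clf.predict_proba(X)
    pos_col = int(np.argmax(clf.classes_))
    return proba[:, pos_col]


def _aggregate(per_fold: list[dict[str, float]]) -> tuple[dict, dict]:
    keys = per_fold[0].keys()
    mean = {k: float(np.mean([f[k] for f in per_fold])) for k in keys}
    sd = {k: float(np.std([f[k] for f in per_fold])) for k in keys}
    return mean, sd


def train_eval(
    features: np.ndarray,
    labels,
    spec: ClassifierSpec,
    folds: list[tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
    threshold: float = 0.5,
) -> MetricsReport:
    """Fit/predict per fold and aggregate metrics.

    Singleton test folds (LOO) are detected and pooled into one scored set.
    A training fold containing a single class is an error naming the fold.
    """
    X = np.asarray(features, dtype=float)
    y = (np.asarray(labels) > 0).astype(int)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    loo_like = all(len(test) == 1 for _, test in folds)

    pooled_true, pooled_score = [], []
    per_fold = []
    for fold_i, (train, test) in enumerate(folds):
        if np.unique(y[train]).size < 2:
            raise ValueError(f"training fold {fold_i} contains a single class")
        clf = spec.build(seed=seed)
        clf.fit(X[train], y[train])
        scores = _positive_scores(clf, X[test])
        if loo_like:
            pooled_true.extend(y[test])
            pooled_score.extend(scores)
        else:
            per_fold.append(compute_metrics(y[test], scores, threshold))
    if loo_like:
        pooled = compute_metrics(pooled_true, pooled_score, threshold)
        return MetricsReport(
            scheme="LOO",
            per_fold=[pooled],
            mean=pooled,
            sd={k: 0.0 for k in pooled},
        )
    mean, sd = _aggregate(per_fold)
    return MetricsReport(scheme="S5F", per_fold=per_fold, mean=mean, sd=sd)


def cross_dataset_eval(
    train_features: np.ndarray,
    train_labels,
    test_features: np.ndarray,
    test_labels,
    spec: ClassifierSpec,
    seed: int = 0,
    threshold: float = 0.5,
) -> MetricsReport:
    """Train on one full dataset, evaluate on the other's 5 stratified folds."""
    X_tr = np.asarray(train_features, dtype=float)
    y_tr = (np.asarray(train_labels) > 0).astype(int)
    X_te = np.asarray(test_features, dtype=float)
    y_te = (np.asarray(test_labels) > 0).astype(int)
    clf = spec.build(seed=seed)
    clf.fit(X_tr, y_tr)
    folds = make_cv_splits(y_te, "S5F", seed=seed)
    per_fold = [
        compute_metrics(y_te[test], _positive_scores(clf, X_te[test]), threshold)
        for _, test in folds
    ]
    mean, sd = _aggregate(per_fold)
    return MetricsReport(scheme="cross_dataset", per_fold=per_fold, mean=mean, sd=sd)


def per_side_effect_eval(
    triples: list[LabeledTriple],
    y_true,
    y_score,
    ap_k: int = 50,
) -> pd.DataFrame:
    """AUC/AUPRC/AP@k per side effect (rows) for pooled test predictions.

    Side effects whose test triples are single-class are skipped (their AUC is
    undefined).  Average the columns for the headline numbers.
    """
    y = (np.asarray(y_true) > 0).astype(int)
    s = np.asarray(y_score, dtype=float)
    by_se: dict[str, list[int]] = {}
    for i, t in enumerate(triples):
        by_se.setdefault(t.side_effect_id, []).append(i)
    rows = []
    for se, idx in sorted(by_se.items()):
        idx = np.asarray(idx)
        if np.unique(y[idx]).size < 2:
            continue
        m = compute_metrics(y[idx], s[idx], ap_k=ap_k)
        rows.append({"side_effect": se, "AUC": m["AUC"], "AUPRC": m["AUPRC"],
                     "AP@50": m["AP@50"]})
    return pd.DataFrame(rows)
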