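"""Reading SemMedDB-style triplet files and building knowledge graphs.

A predication is a ``[subject-predicate-object]`` assertion extracted from the
literature, carrying three confidence signals: the subject and object mapping
scores (how confidently an NLP span was mapped to the stated concept) and the
co-occurrence count (how many times the triplet was extracted).  The default
file dialect is a six-column TSV; column order is configurable because local
SemMedDB exports differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

__all__ = [
    "TripletRecord",
    "TripletDialect",
    "TripletParseError",
    "AdjacencyEntry",
    "KnowledgeGraph",
    "read_triplets",
    "build_graph",
]


class TripletParseError(ValueError):
    """Raised when a triplet file line cannot be parsed; carries the line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True)
class TripletRecord:
    """One ``[subject-predicate-object]`` predication with its confidence scores.

    ``subject_score`` and ``object_score`` are nonnegative concept-mapping
    confidences; ``cooccurrence`` is the (positive) number of times the triplet
    was extracted from the literature.
    """

    subject_id: str
    predicate: str
    object_id: str
    subject_score: float = 1.0
    object_score: float = 1.0
    cooccurrence: int = 1

    def __post_init__(self) -> None:
        if not self.subject_id or not self.object_id:
            raise ValueError("subject_id and object_id must be non-empty")
        if self.cooccurrence < 1:
            raise ValueError(f"cooccurrence must be >= 1, got {self.cooccurrence}")
        if self.subject_score < 0 or self.object_score < 0:
            raise ValueError("subject/object scores must be nonnegative")

    @property
    def key(self) -> tuple[str, str, str]:
        """The (subject, predicate, object) identity of this predication."""
        return (self.subject_id, self.predicate, self.object_id)


@dataclass(frozen=True)
class TripletDialect:
    """Column mapping for a triplet file.

    Fields give the zero-based column index of each attribute.  The default is
    the tab-separated order SUBJECT_ID, PREDICATE, OBJECT_ID, SUBJECT_SCORE,
    OBJECT_SCORE, COOCCURRENCE.
    """

    subject: int = 0
    predicate: int = 1
    object: int = 2
    subject_score: int = 3
    object_score: int = 4
    cooccurrence: int = 5
    separator: str = "\t"

    @property
    def n_columns(self) -> int:
        return 1 + max(
            self.subject,
            self.predicate,
            self.object,
            self.subject_score,
            self.object_score,
            self.cooccurrence,
        )


DEFAULT_DIALECT = TripletDialect()

_HEADER_NAMES = {
    "SUBJECT_ID",
    "PREDICATE",
    "OBJECT_ID",
    "SUBJECT_SCORE",
    "OBJECT_SCORE",
    "COOCCURRENCE",
}


def read_triplets(
    path: str | Path, dialect: TripletDialect = DEFAULT_DIALECT
) -> list[TripletRecord]:
    """Parse a triplet file into records, in file order.

    A header line (recognised by the standard column names) is skipped.  Blank
    lines are ignored.  A line with the wrong column count or a non-numeric
    score raises :class:`TripletParseError` naming the line number.
    """
    path = Path(path)
    records: list[TripletRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            cells = line.split(dialect.separator)
            if lineno == 1 and _HEADER_NAMES.intersection(c.upper() for c in cells):
                continue
            if len(cells) < dialect.n_columns:
                raise TripletParseError(
                    lineno,
                    f"expected at least {dialect.n_columns} columns, got {len(cells)}",
                )
            try:
                record = TripletRecord(
                    subject_id=cells[dialect.subject],
                    predicate=cells[dialect.predicate],
                    object_id=cells[dialect.object],
                    subject_score=float(cells[dialect.subject_score]),
                    object_score=float(cells[dialect.object_score]),
                    cooccurrence=int(float(cells[dialect.cooccurrence])),
                )
            except ValueError as exc:
                raise TripletParseError(lineno, str(exc)) from exc
            records.append(record)
    return records


def write_triplets(
    records: Iterable[TripletRecord],
    path: str | Path,
    dialect: TripletDialect = DEFAULT_DIALECT,
    header: bool = True,
) -> None:
    """Write records in the given dialect (inverse of :func:`read_triplets`)."""
    names = {
        dialect.subject: "SUBJECT_ID",
        dialect.predicate: "PREDICATE",
        dialect.object: "OBJECT_ID",
        dialect.subject_score: "SUBJECT_SCORE",
        dialect.object_score: "OBJECT_SCORE",
        dialect.cooccurrence: "COOCCURRENCE",
    }
    n = dialect.n_columns
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(dialect.separator.join(names.get(i, "") for i in range(n)) + "\n")
        for rec in records:
            cells = [""] * n
            cells[dialect.subject] = rec.subject_id
            cells[dialect.predicate] = rec.predicate
            cells[dialect.object] = rec.object_id
            cells[dialect.subject_score] = repr(rec.subject_score)
            cells[dialect.object_score] = repr(rec.object_score)
            cells[dialect.cooccurrence] = str(rec.cooccurrence)
            fh.write(dialect.separator.join(cells) + "\n")


class AdjacencyEntry(NamedTuple):
    """One traversable (predicate, neighbor) pair, carrying its source record.

    ``record`` is the aggregated :class:`TripletRecord` this entry came from;
    for a mirrored (undirected) entry it is the same record as the forward
    entry, so both directions share one confidence score.
    """

    predicate: str
    neighbor: str
    record: TripletRecord

    @property
    def key(self) -> tuple[str, str, str]:
        return self.record.key


@dataclass
class KnowledgeGraph:
    """Vertex set plus (predicate, neighbor) adjacency built from predications.

    ``adjacency[v]`` is the list of :class:`AdjacencyEntry` traversable from
    ``v`` (the neighborhood H'(v)).  In undirected mode every triplet also
    contributes a reverse entry so walks never strand at sink objects.
    """

    vertices: list[str]
    predicates: set[str]
    adjacency: dict[str, list[AdjacencyEntry]]
    records: list[TripletRecord]
    mode: str
    entity_index: dict[str, int] = field(default_factory=dict)
    predicate_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entity_index:
            self.entity_index = {v: i for i, v in enumerate(self.vertices)}
        if not self.predicate_index:
            self.predicate_index = {
                p: i for i, p in enumerate(sorted(self.predicates))
            }

    def neighbors(self, v: str) -> list[AdjacencyEntry]:
        return self.adjacency.get(v, [])

    @property
    def num_vertices(self) -> int:
        return len(self.vertices)

    @property
    def num_triplets(self) -> int:
        return len(self.records)


def build_graph(
    records: list[TripletRecord], mode: str = "undirected"
) -> KnowledgeGraph:
    """Aggregate records and index them into a queryable heterogeneous graph.

    Duplicate (subject, predicate, object) records are merged into one entry:
    co-occurrence counts are summed (they are extraction counts) while subject
    and object scores take the maximum (they are mapping confidences).  In
    undirected mode (the default) each triplet is mirrored so that
    ``(p, B) in H'(A)`` iff ``(p, A) in H'(B)``.
    """
    if not records:
        raise ValueError("cannot build a graph from an empty record list")
    if mode not in ("directed", "undirected"):
        raise ValueError(f"mode must be 'directed' or 'undirected', got {mode!r}")

    aggregated: dict[tuple[str, str, str], TripletRecord] = {}
    order: list[tuple[str, str, str]] = []
    for rec in records:
        prev = aggregated.get(rec.key)
        if prev is None:
            aggregated[rec.key] = rec
            order.append(rec.key)
        else:
            aggregated[rec.key] = TripletRecord(
                subject_id=rec.subject_id,
                predicate=rec.predicate,
                object_id=rec.object_id,
                subject_score=max(prev.subject_score, rec.subject_score),
                object_score=max(prev.object_score, rec.object_score),
                cooccurrence=prev.cooccurrence + rec.cooccurrence,
            )

    vertices: list[str] = []
    seen: set[str] = set()
    adjacency: dict[str, list[AdjacencyEntry]] = {}
    predicates: set[str] = set()
    merged = [aggregated[k] for k in order]
    for rec in merged:
        for v in (rec.subject_id, rec.object_id):
            if v not in seen:
                seen.add(v)
                vertices.append(v)
                adjacency[v] = []
        predicates.add(rec.predicate)
        adjacency[rec.subject_id].append(
            AdjacencyEntry(rec.predicate, rec.object_id, rec)
        )
        if mode == "undirected" and rec.subject_id != rec.object_id:
            adjacency[rec.object_id].append(
                AdjacencyEntry(rec.predicate, rec.subject_id, rec)
            )
    return KnowledgeGraph(
        vertices=vertices,
        predicates=predicates,
        adjacency=adjacency,
        records=merged,
        mode=mode,
    )
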