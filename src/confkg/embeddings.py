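"""Embedding tables and the word2vec text interchange format."""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = ["EmbeddingTable", "l2_normalize", "write_embeddings", "read_embeddings"]


class EmbeddingTable:
    """Identifier -> fixed-dimension real vector, optionally unit-L2.

    Backed by a dense matrix with a token index; supports dict-style access.
    """

    def __init__(
        self, tokens: list[str], matrix: np.ndarray, normalized: bool = False
    ):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[0] != len(tokens):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match {len(tokens)} tokens"
            )
        if len(set(tokens)) != len(tokens):
            raise ValueError("duplicate tokens in embedding table")
        self.tokens = list(tokens)
        self.matrix = matrix
        self.normalized = normalized
        self._index = {t: i for i, t in enumerate(self.tokens)}

    @classmethod
    def from_dict(
        cls, vectors: Mapping[str, np.ndarray], normalized: bool = False
    ) -> "EmbeddingTable":
        if not vectors:
            raise ValueError("empty embedding table")
        tokens = list(vectors)
        matrix = np.array([np.asarray(vectors[t], dtype=np.float64) for t in tokens])
        return cls(tokens, matrix, normalized=normalized)

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __getitem__(self, token: str) -> np.ndarray:
        return self.matrix[self._index[token]]

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        for t in self.tokens:
            yield t, self.matrix[self._index[t]]

    def subset(self, tokens: list[str]) -> "EmbeddingTable":
        idx = [self._index[t] for t in tokens]
        return EmbeddingTable(tokens, self.matrix[idx], normalized=self.normalized)


def l2_normalize(table: EmbeddingTable) -> EmbeddingTable:
    """Scale every vector to unit L2 norm; errors on a zero vector, naming it."""
    norms = np.linalg.norm(table.matrix, axis=1)
    zero = np.nonzero(norms == 0.0)[0]
    if zero.size:
        raise ValueError(
            f"cannot L2-normalize zero vector for token {table.tokens[zero[0]]!r}"
        )
    return EmbeddingTable(
        table.tokens, table.matrix / norms[:, None], normalized=True
    )


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Write in word2vec text format: header "<vocab> <dim>", then one row per id."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty embedding table")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dimension}\n")
        for token, vec in table.items():
            fh.write(token + " " + " ".join(f"{x:.12g}" for x in vec) + "\n")


def read_embeddings(path: str | Path) -> EmbeddingTable:
    """Read word2vec text format; errors on header/row dimension mismatch."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("malformed embedding header (expected '<vocab> <dim>')")
        vocab, dim = int(header[0]), int(header[1])
        tokens: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip().split(" ")
            if len(parts) == 1 and not parts[0]:
                continue
            if len(parts) != dim + 1:
                raise ValueError(
                    f"line {lineno}: expected {dim} components, got {len(parts) - 1}"
                )
            tokens.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(tokens) != vocab:
        raise ValueError(f"header declared {vocab} vectors, file has {len(tokens)}")
    return EmbeddingTable(tokens, np.array(rows))
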