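"""Read, write and subset word-embedding tables in the standard text dialects.

Two on-disk dialects are supported:

* ``glove-text`` — one record per line, the word followed by ``d``
  space-separated real coordinates, no header (the format of the GloVe
  pre-trained releases);
* ``word2vec-text`` — identical, but preceded by a ``"V d"`` header line.

File order is preserved and treated as descending corpus frequency, which is
how the GloVe releases are sorted; "the k most frequent words" therefore means
the first k records. Plain and gzip-compressed files are both accepted, by
extension.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from .errors import EmbeddingFormatError

Dialect = Literal["auto", "glove-text", "word2vec-text"]

__all__ = ["WordEmbeddings", "read_embeddings", "write_embeddings", "top_k", "lookup"]


@dataclass
class WordEmbeddings:
    """An ordered vocabulary and its V x d coordinate matrix.

    ``words[i]`` labels ``matrix[i]``; the order is the file order, which for
    frequency-sorted releases doubles as the frequency rank. ``case_fold``
    records the lookup policy: when True (default, matching the uncased GloVe
    6B vocabulary) queries and vocabulary are lowercased before matching.
    """

    words: list[str]
    matrix: np.ndarray
    case_fold: bool = True
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise EmbeddingFormatError("matrix must be two-dimensional")
        if len(self.words) != self.matrix.shape[0]:
            raise EmbeddingFormatError(
                f"{len(self.words)} words but {self.matrix.shape[0]} matrix rows"
            )
        if len(self.words) < 1 or self.matrix.shape[1] < 1:
            raise EmbeddingFormatError("need at least one word and one dimension")
        if not np.all(np.isfinite(self.matrix)):
            raise EmbeddingFormatError("non-finite coordinate in embedding matrix")
        if len(set(self.words)) != len(self.words):
            seen: set[str] = set()
            for w in self.words:
                if w in seen:
                    raise EmbeddingFormatError(f"duplicate word: {w!r}")
                seen.add(w)
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        self._index = {}
        for i, w in enumerate(self.words):
            key = self._fold(w)
            # first (most frequent) occurrence wins under folding
            self._index.setdefault(key, i)

    def _fold(self, word: str) -> str:
        return word.lower() if self.case_fold else word

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def d(self) -> int:
        return int(self.matrix.shape[1])

    def index_of(self, word: str) -> Optional[int]:
        """Row index of ``word`` under the folding policy, or None."""
        return self._index.get(self._fold(word))

    def __contains__(self, word: str) -> bool:
        return self.index_of(word) is not None

    def __len__(self) -> int:
        return self.n_words


def _open_text(path: Path, mode: str) -> io.TextIOBase:
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="utf-8")  # type: ignore[return-value]
    return open(path, mode, encoding="utf-8")


def _sniff_dialect(first_line: str) -> Dialect:
    toks = first_line.split()
    if len(toks) == 2 and all(t.lstrip("+-").isdigit() for t in toks):
        return "word2vec-text"
    return "glove-text"


def read_embeddings(
    path: str | Path,
    limit: Optional[int] = None,
    dialect: Dialect = "auto",
    case_fold: bool = True,
) -> WordEmbeddings:
    """Parse an embedding table, keeping the first ``limit`` records.

    ``dialect="auto"`` sniffs the first line: exactly two integer tokens mean
    a word2vec-text header. Malformed lines raise :class:`EmbeddingFormatError`
    naming the line number rather than being skipped, so a bad file cannot
    silently shift the vocabulary.
    """
    path = Path(path)
    if limit is not None and limit < 1:
        raise ValueError("limit must be a positive integer")
    words: list[str] = []
    rows: list[np.ndarray] = []
    d: Optional[int] = None
    declared_v: Optional[int] = None
    seen: set[str] = set()

    with _open_text(path, "r") as fh:
        first = fh.readline()
        if first == "":
            raise EmbeddingFormatError(f"{path}: empty file")
        if dialect == "auto":
            dialect = _sniff_dialect(first)
        lineno = 1
        if dialect == "word2vec-text":
            toks = first.split()
            if len(toks) != 2:
                raise EmbeddingFormatError(
                    f"{path}:1: expected 'V d' header, got {first.rstrip()!r}"
                )
            try:
                declared_v, d = int(toks[0]), int(toks[1])
            except ValueError:
                raise EmbeddingFormatError(
                    f"{path}:1: non-integer header tokens {first.rstrip()!r}"
                ) from None
            if declared_v < 1 or d < 1:
                raise EmbeddingFormatError(f"{path}:1: header values must be >= 1")
            line = fh.readline()
            lineno = 2
        else:
            line = first

        while line != "":
            stripped = line.rstrip("\n").rstrip("\r")
            if stripped:
                toks = stripped.split(" ")
                word, coords = toks[0], toks[1:]
                if d is None:
                    if not coords:
                        raise EmbeddingFormatError(
                            f"{path}:{lineno}: record has no coordinates"
                        )
                    d = len(coords)
                if len(coords) != d:
                    raise EmbeddingFormatError(
                        f"{path}:{lineno}: expected {d} coordinates, found {len(coords)}"
                    )
                if word in seen:
                    raise EmbeddingFormatError(f"{path}:{lineno}: duplicate word {word!r}")
                seen.add(word)
                try:
                    row = np.array(coords, dtype=float)
                except ValueError:
                    raise EmbeddingFormatError(
                        f"{path}:{lineno}: non-numeric coordinate"
                    ) from None
                words.append(word)
                rows.append(row)
                if limit is not None and len(words) >= limit:
                    break
            line = fh.readline()
            lineno += 1

    if not words:
        raise EmbeddingFormatError(f"{path}: no embedding records found")
    if (
        declared_v is not None
        and limit is None
        and len(words) != declared_v
    ):
        raise EmbeddingFormatError(
            f"{path}: header declares {declared_v} records, found {len(words)}"
        )
    return WordEmbeddings(words=words, matrix=np.vstack(rows), case_fold=case_fold)


def write_embeddings(
    emb: WordEmbeddings,
    path: str | Path,
    dialect: Literal["glove-text", "word2vec-text"] = "glove-text",
) -> Path:
    """Serialize ``emb`` so that :func:`read_embeddings` reproduces it.

    Coordinates are written with 8 significant digits, so one round trip is
    exact to well under 1e-6 and a second round trip is byte-identical.
    """
    path = Path(path)
    with _open_text(path, "w") as fh:
        if dialect == "word2vec-text":
            fh.write(f"{emb.n_words} {emb.d}\n")
        for word, row in zip(emb.words, emb.matrix):
            fh.write(word + " " + " ".join(f"{x:.8g}" for x in row) + "\n")
    return path


def top_k(emb: WordEmbeddings, k: int) -> WordEmbeddings:
    """The k most frequent words, i.e. the first min(k, V) rows in file order."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    k = min(k, emb.n_words)
    return WordEmbeddings(
        words=list(emb.words[:k]), matrix=emb.matrix[:k].copy(), case_fold=emb.case_fold
    )


def lookup(emb: WordEmbeddings, word: str) -> Optional[np.ndarray]:
    """The vector of ``word`` under the folding policy, or None if absent."""
    i = emb.index_of(word)
    return None if i is None else emb.matrix[i]
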