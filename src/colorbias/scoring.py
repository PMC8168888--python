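"""Concept mean vectors, cosine similarity scoring, and dyadic bias scores.

A concept (male, female, posemo, negemo, ...) is represented by the
arithmetic mean mu of the raw embedding vectors of its lexicon words; the
direction of mu stands for the concept in embedding space. A word w is scored
against a concept by the cosine of the angle between w and mu — a real number
in [-1, 1], higher meaning more similar. A dyadic bias pairs two opposed
concepts into an axis and scores a word by the *difference* of its two
cosines, so bias values lie in [-2, 2]:

    gender bias  = cos(w, mu_male)   - cos(w, mu_female)   (+ => masculine)
    valence bias = cos(w, mu_posemo) - cos(w, mu_negemo)   (+ => positive)

Averaging happens on raw vectors and normalisation afterwards
(average-then-normalise), not the other way around.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .embeddings import WordEmbeddings, lookup
from .errors import ConfigurationError, DegenerateConceptError

__all__ = [
    "ConceptVector",
    "BiasAxis",
    "ScoreRecord",
    "mean_vector",
    "cosine_similarity",
    "bias_score",
    "axis_bias",
    "similarity_profile",
    "score_words",
    "DEFAULT_AXES",
]


@dataclass(frozen=True)
class ConceptVector:
    """A concept's mean vector with provenance: how many words were averaged."""

    name: str
    mu: np.ndarray
    n_words: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        if self.n_words < 1:
            raise DegenerateConceptError(f"concept {self.name!r}: n_words < 1")
        if not np.all(np.isfinite(self.mu)):
            raise DegenerateConceptError(f"concept {self.name!r}: non-finite mean")
        if not np.any(self.mu):
            raise DegenerateConceptError(f"concept {self.name!r}: zero mean vector")


@dataclass(frozen=True)
class BiasAxis:
    """An opposed concept pair; positive bias points toward ``positive_pole``."""

    name: str
    positive_pole: str
    negative_pole: str

    def __post_init__(self) -> None:
        if self.positive_pole == self.negative_pole:
            raise ConfigurationError(f"axis {self.name!r}: poles must be distinct")


#: gender = male - female (+ masculine), valence = posemo - negemo (+ positive)
DEFAULT_AXES: tuple[BiasAxis, ...] = (
    BiasAxis("gender", positive_pole="male", negative_pole="female"),
    BiasAxis("valence", positive_pole="posemo", negative_pole="negemo"),
)


@dataclass(frozen=True)
class ScoreRecord:
    """Per-word similarities to every concept and biases on every axis.

    Every bias equals the difference of its pole similarities bit-for-bit.
    """

    word: str
    similarities: Mapping[str, float]
    biases: Mapping[str, float]


def mean_vector(emb: WordEmbeddings, words: Sequence[str], name: str) -> ConceptVector:
    """Mean of the raw (unnormalised) vectors of ``words``."""
    if not words:
        raise DegenerateConceptError(f"concept {name!r}: empty word list")
    rows = []
    for w in words:
        v = lookup(emb, w)
        if v is None:
            raise KeyError(f"concept {name!r}: word {w!r} not in vocabulary")
        rows.append(v)
    mu = np.mean(rows, axis=0)
    return ConceptVector(name=name, mu=mu, n_words=len(words))


def _check_vector(v: np.ndarray, label: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{label} must be one-dimensional")
    if not np.all(np.isfinite(v)):
        raise DegenerateConceptError(f"{label} has non-finite coordinates")
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise DegenerateConceptError(f"{label} is the zero vector")
    return v


def cosine_similarity(w: np.ndarray, mu: np.ndarray) -> float:
    """Inner product of the unit-normalised vectors; in [-1, 1]."""
    w = _check_vector(w, "w")
    mu = _check_vector(mu, "mu")
    if w.shape != mu.shape:
        raise ValueError(f"dimension mismatch: {w.shape[0]} vs {mu.shape[0]}")
    return float(np.dot(w, mu) / (np.linalg.norm(w) * np.linalg.norm(mu)))


def bias_score(w: np.ndarray, mu1: np.ndarray, mu2: np.ndarray) -> float:
    """cos(w, mu1) - cos(w, mu2); antisymmetric in the poles, in [-2, 2]."""
    return axis_bias(cosine_similarity(w, mu1), cosine_similarity(w, mu2))


def axis_bias(sim_positive: float, sim_negative: float) -> float:
    """The bias operation at similarity level: positive minus negative pole."""
    return sim_positive - sim_negative


def similarity_profile(emb: WordEmbeddings, concept: ConceptVector) -> np.ndarray:
    """Cosine of every vocabulary row against the concept, one matrix pass.

    This is the vectorised route used for the normative population; it is
    numerically identical to calling :func:`cosine_similarity` row by row.
    """
    norms = np.linalg.norm(emb.matrix, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise DegenerateConceptError(
            f"zero vector in vocabulary at row {zero[0]} ({emb.words[zero[0]]!r})"
        )
    mu = _check_vector(concept.mu, f"concept {concept.name!r}")
    mu_hat = mu / np.linalg.norm(mu)
    return (emb.matrix @ mu_hat) / norms


def score_words(
    emb: WordEmbeddings,
    targets: Sequence[str],
    concepts: Sequence[ConceptVector],
    axes: Sequence[BiasAxis] = DEFAULT_AXES,
) -> tuple[list[ScoreRecord], list[str]]:
    """Score each target against every concept and axis.

    Returns ``(records, missing)``: one record per target found in the
    vocabulary, in target order, plus the list of out-of-vocabulary targets
    (reported, never silently dropped).
    """
    by_name = {c.name: c for c in concepts}
    for ax in axes:
        for pole in (ax.positive_pole, ax.negative_pole):
            if pole not in by_name:
                raise ConfigurationError(
                    f"axis {ax.name!r} references unknown concept {pole!r}"
                )
    records: list[ScoreRecord] = []
    missing: list[str] = []
    for word in targets:
        v = lookup(emb, word)
        if v is None:
            missing.append(word)
            continue
        sims = {c.name: cosine_similarity(v, c.mu) for c in concepts}
        biases = {
            ax.name: axis_bias(sims[ax.positive_pole], sims[ax.negative_pole])
            for ax in axes
        }
        records.append(ScoreRecord(word=word, similarities=sims, biases=biases))
    return records, missing
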