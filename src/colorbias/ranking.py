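"""Normative percentile ranking and the 5th/95th-percentile extremeness rule.

A score is judged against the distribution of the same score over a normative
word population — by default the 100,000 most frequent words of the corpus.
The percentile rank of x is the percentage of the population scoring
*strictly* below x (no interpolation, no midranking of ties; with a large
population of continuous scores ties are measure-zero). A score is called
extreme when its percentile is strictly below the low threshold (default 5)
or strictly above the high threshold (default 95); a percentile exactly at a
threshold is not extreme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .embeddings import WordEmbeddings, top_k
from .errors import ConfigurationError
from .scoring import BiasAxis, ConceptVector, similarity_profile

__all__ = [
    "NormativeDistribution",
    "ExtremenessCall",
    "ScoreSpec",
    "build_distribution",
    "percentile_rank",
    "classify_extreme",
]

#: ("similarity", concept name) or ("bias", axis name)
ScoreSpec = tuple[Literal["similarity", "bias"], str]


@dataclass(frozen=True)
class NormativeDistribution:
    """Sorted score population for one concept similarity or one axis bias."""

    label: str
    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.n < 1 or values.shape != (self.n,):
            raise ValueError("values must be a length-n vector with n >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite value in normative distribution")
        if np.any(np.diff(values) < 0):
            raise ValueError("values must be sorted ascending")


@dataclass(frozen=True)
class ExtremenessCall:
    """A percentile and its classification under the strict threshold rule."""

    percentile: float
    call: Literal["below_low", "none", "above_high"]
    low_threshold: float = 5.0
    high_threshold: float = 95.0


def build_distribution(
    emb: WordEmbeddings,
    k: int,
    score_spec: ScoreSpec,
    concepts: Sequence[ConceptVector],
    axes: Sequence[BiasAxis] = (),
) -> NormativeDistribution:
    """Score the top-k (most frequent) words and return the sorted values.

    k larger than the vocabulary is clamped. Scoring is a single
    matrix-vector pass per concept; an axis distribution is the elementwise
    difference of its two pole similarity profiles, re-sorted.
    """
    pop = top_k(emb, k)
    kind, name = score_spec
    by_name = {c.name: c for c in concepts}
    if kind == "similarity":
        if name not in by_name:
            raise ConfigurationError(f"unknown concept {name!r}")
        scores = similarity_profile(pop, by_name[name])
    elif kind == "bias":
        ax = next((a for a in axes if a.name == name), None)
        if ax is None:
            raise ConfigurationError(f"unknown axis {name!r}")
        for pole in (ax.positive_pole, ax.negative_pole):
            if pole not in by_name:
                raise ConfigurationError(
                    f"axis {name!r} references unknown concept {pole!r}"
                )
        scores = similarity_profile(pop, by_name[ax.positive_pole]) - similarity_profile(
            pop, by_name[ax.negative_pole]
        )
    else:
        raise ConfigurationError(f"unknown score spec kind {kind!r}")
    label = f"{kind}:{name}"
    return NormativeDistribution(label=label, values=np.sort(scores), n=pop.n_words)


def percentile_rank(dist: NormativeDistribution, x: float) -> float:
    """100 * (number of population values strictly below x) / n, in [0, 100]."""
    if not math.isfinite(x):
        raise ValueError(f"cannot rank non-finite value {x!r}")
    below = int(np.searchsorted(dist.values, x, side="left"))
    return 100.0 * below / dist.n


def classify_extreme(
    percentile: float, low: float = 5.0, high: float = 95.0
) -> ExtremenessCall:
    """Strict-threshold call: below_low iff pct < low, above_high iff pct > high."""
    if not (0.0 <= low < high <= 100.0):
        raise ValueError("need 0 <= low < high <= 100")
    if percentile < low:
        call = "below_low"
    elif percentile > high:
        call = "above_high"
    else:
        call = "none"
    return ExtremenessCall(
        percentile=percentile, call=call, low_threshold=low, high_threshold=high
    )
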