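"""Concept word lists and their resolution against an embedding vocabulary.

A lexicon file is UTF-8 plain text with one pattern per line; ``#`` comment
lines and blank lines are ignored. A pattern is either a literal word or a
stem with a single trailing ``*`` wildcard (the convention of LIWC-style
category files, e.g. ``happ*`` covering *happy*, *happiness*, ...). The LIWC
2015 categories themselves are proprietary and are not shipped; small openly
authored stand-in lists live under ``colorbias/data/lexicons`` and a licensee
can drop in the real category files in the same one-pattern-per-line format.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal

from .embeddings import WordEmbeddings
from .errors import LexiconCoverageWarning, LexiconFormatError, LexiconResolutionError

ResolveMode = Literal["literal", "expand"]

__all__ = ["ConceptLexicon", "load_lexicon", "resolve", "bundled_lexicon_path"]


@dataclass(frozen=True)
class ConceptLexicon:
    """A named, ordered list of literal or trailing-wildcard patterns."""

    name: str
    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise LexiconFormatError("lexicon name must be nonempty")
        if not self.patterns:
            raise LexiconFormatError(f"lexicon {self.name!r} has no patterns")
        if len(set(self.patterns)) != len(self.patterns):
            raise LexiconFormatError(f"lexicon {self.name!r} has duplicate patterns")
        for p in self.patterns:
            if "*" in p[:-1] or p == "*":
                raise LexiconFormatError(
                    f"lexicon {self.name!r}: wildcard only allowed in final "
                    f"position of a nonempty stem, got {p!r}"
                )


def load_lexicon(path: str | Path, name: str, case_fold: bool = True) -> ConceptLexicon:
    """Parse a lexicon file; duplicates collapse with a warning, order kept."""
    path = Path(path)
    patterns: list[str] = []
    seen: set[str] = set()
    dupes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if case_fold:
                line = line.lower()
            if "*" in line[:-1] or line == "*":
                raise LexiconFormatError(
                    f"{path}:{lineno}: wildcard must be a single trailing "
                    f"asterisk, got {line!r}"
                )
            if line in seen:
                dupes.append(line)
                continue
            seen.add(line)
            patterns.append(line)
    if not patterns:
        raise LexiconFormatError(f"{path}: empty effective word list")
    if dupes:
        warnings.warn(
            f"lexicon {name!r}: collapsed duplicate patterns {dupes}",
            LexiconCoverageWarning,
            stacklevel=2,
        )
    return ConceptLexicon(name=name, patterns=tuple(patterns))


def _expand_stem(stem: str, sorted_vocab: list[str], order: dict[str, int]) -> list[int]:
    """Row indices of all vocabulary words with the given prefix."""
    lo = bisect.bisect_left(sorted_vocab, stem)
    hi = bisect.bisect_left(sorted_vocab, stem + "\U0010ffff")
    return [order[w] for w in sorted_vocab[lo:hi]]


def resolve(
    lex: ConceptLexicon, emb: WordEmbeddings, mode: ResolveMode = "expand"
) -> list[str]:
    """Vocabulary words covered by the lexicon, deduplicated, vocabulary order.

    ``literal``: a literal pattern contributes itself when present; a wildcard
    contributes only its bare stem. ``expand``: a wildcard contributes every
    vocabulary word having the stem as a prefix (faithful to how LIWC
    categories are applied to text). Patterns that match nothing are skipped
    with a :class:`LexiconCoverageWarning`; an entirely unmatched lexicon is
    an error, since a concept vector averaged over zero words is undefined.
    """
    if mode not in ("literal", "expand"):
        raise ValueError(f"unknown resolve mode {mode!r}")
    folded = [emb._fold(w) for w in emb.words]
    order: dict[str, int] = {}
    for i, w in enumerate(folded):
        order.setdefault(w, i)
    hit_rows: set[int] = set()
    unmatched: list[str] = []
    sorted_vocab: list[str] | None = None
    for pat in lex.patterns:
        fp = emb._fold(pat)
        if fp.endswith("*"):
            stem = fp[:-1]
            if mode == "expand":
                if sorted_vocab is None:
                    sorted_vocab = sorted(order)
                rows = _expand_stem(stem, sorted_vocab, order)
            else:
                rows = [order[stem]] if stem in order else []
        else:
            rows = [order[fp]] if fp in order else []
        if rows:
            hit_rows.update(rows)
        else:
            unmatched.append(pat)
    if not hit_rows:
        raise LexiconResolutionError(
            f"lexicon {lex.name!r}: no pattern matched the vocabulary"
        )
    if unmatched:
        warnings.warn(
            f"lexicon {lex.name!r}: {len(unmatched)} pattern(s) out of "
            f"vocabulary: {unmatched}",
            LexiconCoverageWarning,
            stacklevel=2,
        )
    return [emb.words[i] for i in sorted(hit_rows)]


def bundled_lexicon_path(concept: str) -> Path:
    """Path of one of the bundled stand-in lexicons (male/female/posemo/negemo)."""
    ref = resources.files("colorbias") / "data" / "lexicons" / f"{concept}.txt"
    with resources.as_file(ref) as p:
        return Path(p)
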