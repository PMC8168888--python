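"""End-to-end orchestration: load, resolve, score, rank, classify, report.

The report has the shape of the analysis' summary table: one row per target
word with its similarity to each of the four concepts, each axis bias, the
normative percentile of every score, and the extremeness call for each axis.
It is written as TSV (human-facing, deterministic, no timestamps in the data
section) and JSON (machine-readable, full precision); re-reading the JSON
reproduces every number printed in the TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import __version__
from .embeddings import WordEmbeddings, read_embeddings
from .errors import ConfigurationError
from .lexicons import ConceptLexicon, load_lexicon, resolve
from .ranking import build_distribution, classify_extreme, percentile_rank
from .scoring import (
    BiasAxis,
    ConceptVector,
    DEFAULT_AXES,
    mean_vector,
    score_words,
)

__all__ = ["RunConfig", "Report", "run_analysis", "analyze"]

DEFAULT_TARGETS = (
    "red", "orange", "yellow", "green", "blue", "purple",
    "pink", "brown", "grey", "white", "black",
    "happy", "sad", "nun", "priest",
)

_SIM_FMT = "{:.4f}"   # similarities and biases, 4 decimals
_PCT_FMT = "{:.2f}"   # percentiles, 2 decimals


@dataclass
class RunConfig:
    """Everything one analysis run depends on.

    ``lexicons`` maps concept name -> lexicon file path; the axes must
    reference those concepts. ``k`` is the size of the normative population
    (most frequent words; clamped to the vocabulary). Thresholds are the
    strict extremeness percentiles.
    """

    embeddings: str | Path
    lexicons: Mapping[str, str | Path]
    targets: Sequence[str] = DEFAULT_TARGETS
    dialect: str = "auto"
    limit: Optional[int] = None
    axes: Sequence[BiasAxis] = DEFAULT_AXES
    k: int = 100_000
    low: float = 5.0
    high: float = 95.0
    mode: str = "expand"
    case_fold: bool = True
    out_tsv: Optional[str | Path] = None
    out_json: Optional[str | Path] = None


@dataclass
class Report:
    """Provenance header plus the scored table and the missing-word list."""

    header: dict
    columns: list[str]
    rows: list[dict]
    missing_targets: list[str] = field(default_factory=list)

    def _format_cell(self, column: str, value) -> str:
        if column == "word" or column.startswith("call_"):
            return str(value)
        if column.startswith("pct_"):
            return _PCT_FMT.format(value)
        return _SIM_FMT.format(value)

    def to_tsv(self) -> str:
        lines = [f"# {key}: {self.header[key]}" for key in self.header]
        if self.missing_targets:
            lines.append(f"# missing_targets: {','.join(self.missing_targets)}")
        lines.append("\t".join(self.columns))
        for row in self.rows:
            lines.append("\t".join(self._format_cell(c, row[c]) for c in self.columns))
        return "\n".join(lines) + "\n"

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_tsv(), encoding="utf-8")
        return path

    def to_dict(self) -> dict:
        return {
            "header": dict(self.header),
            "columns": list(self.columns),
            "rows": [dict(r) for r in self.rows],
            "missing_targets": list(self.missing_targets),
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "Report":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            header=data["header"],
            columns=data["columns"],
            rows=data["rows"],
            missing_targets=data.get("missing_targets", []),
        )

    def calls(self) -> dict[str, dict[str, str]]:
        """word -> axis -> extremeness call, for recovery checks."""
        axes = [c[len("call_"):] for c in self.columns if c.startswith("call_")]
        return {r["word"]: {a: r[f"call_{a}"] for a in axes} for r in self.rows}


def analyze(
    emb: WordEmbeddings,
    lexicons: Mapping[str, ConceptLexicon],
    targets: Sequence[str] = DEFAULT_TARGETS,
    axes: Sequence[BiasAxis] = DEFAULT_AXES,
    k: int = 100_000,
    low: float = 5.0,
    high: float = 95.0,
    mode: str = "expand",
    extra_header: Optional[dict] = None,
) -> Report:
    """Run the in-memory analysis over already-loaded inputs."""
    for ax in axes:
        for pole in (ax.positive_pole, ax.negative_pole):
            if pole not in lexicons:
                raise ConfigurationError(
                    f"axis {ax.name!r} references concept {pole!r} with no lexicon"
                )
    concept_order = list(lexicons)
    concepts: list[ConceptVector] = []
    resolution_counts: dict[str, int] = {}
    for name in concept_order:
        words = resolve(lexicons[name], emb, mode=mode)  # type: ignore[arg-type]
        resolution_counts[name] = len(words)
        concepts.append(mean_vector(emb, words, name))

    records, missing = score_words(emb, targets, concepts, axes)

    sim_dists = {
        c.name: build_distribution(emb, k, ("similarity", c.name), concepts, axes)
        for c in concepts
    }
    bias_dists = {
        ax.name: build_distribution(emb, k, ("bias", ax.name), concepts, axes)
        for ax in axes
    }

    columns = ["word"]
    for name in concept_order:
        columns += [f"sim_{name}", f"pct_{name}"]
    for ax in axes:
        columns += [f"bias_{ax.name}", f"pct_bias_{ax.name}", f"call_{ax.name}"]

    rows: list[dict] = []
    for rec in records:
        row: dict = {"word": rec.word}
        for name in concept_order:
            sim = rec.similarities[name]
            row[f"sim_{name}"] = sim
            row[f"pct_{name}"] = percentile_rank(sim_dists[name], sim)
        for ax in axes:
            bias = rec.biases[ax.name]
            pct = percentile_rank(bias_dists[ax.name], bias)
            row[f"bias_{ax.name}"] = bias
            row[f"pct_bias_{ax.name}"] = pct
            row[f"call_{ax.name}"] = classify_extreme(pct, low, high).call
        rows.append(row)

    header = {
        "colorbias_version": __version__,
        "vocabulary_size": emb.n_words,
        "dimensions": emb.d,
        "normative_k": k,
        "normative_n": sim_dists[concept_order[0]].n,
        "thresholds": f"{low}/{high}",
        "lexicon_mode": mode,
        "case_fold": emb.case_fold,
        "axes": ";".join(
            f"{ax.name}={ax.positive_pole}-{ax.negative_pole}" for ax in axes
        ),
        "lexicon_resolution_counts": ";".join(
            f"{name}={resolution_counts[name]}" for name in concept_order
        ),
        "deterministic": "analysis involves no randomness; identical inputs give identical output",
    }
    if extra_header:
        header.update(extra_header)
    return Report(header=header, columns=columns, rows=rows, missing_targets=missing)


def run_analysis(config: RunConfig) -> Report:
    """File-level entry point: load inputs per the config, analyse, write outputs."""
    emb = read_embeddings(
        config.embeddings,
        limit=config.limit,
        dialect=config.dialect,  # type: ignore[arg-type]
        case_fold=config.case_fold,
    )
    lexicons = {
        name: load_lexicon(path, name, case_fold=config.case_fold)
        for name, path in config.lexicons.items()
    }
    extra = {
        "embeddings_path": str(config.embeddings),
        "dialect": config.dialect,
        "lexicon_paths": ";".join(f"{n}={p}" for n, p in config.lexicons.items()),
    }
    report = analyze(
        emb,
        lexicons,
        targets=config.targets,
        axes=config.axes,
        k=config.k,
        low=config.low,
        high=config.high,
        mode=config.mode,
        extra_header=extra,
    )
    if config.out_tsv is not None:
        report.write_tsv(config.out_tsv)
    if config.out_json is not None:
        report.write_json(config.out_json)
    return report
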