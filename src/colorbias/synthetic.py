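"""Synthetic embedding spaces with planted gender/valence structure.

The generator emulates the statistical structure the bias analysis assumes:
words nearer a pole's lexicon words score higher on that concept. It draws
five orthonormal directions in d-dimensional space — a *common* direction u
shared by every word (the dominant mean direction of trained embeddings), a
latent *gender* axis g, a latent *valence* axis v, and one *pole-shared*
direction per axis (p_g, p_v) carried by both of an axis' pole lexicons, the
way the masculine and feminine pronoun lists share "person-ness" and the two
emotion lists share "affect-ness". Each word vector is

    word = common_loading * u + gender_loading * g + valence_loading * v
           + shared_g * p_g + shared_v * p_v + eps

with isotropic Gaussian noise eps scaled so its expected norm is ``noise_sd``
(per-coordinate sd ``noise_sd / sqrt(d)``), putting signal (loadings of order
one) and noise on the same scale.

Pole lexicon words carry +/- ``pole_loading`` on their own axis plus
``pole_shared_loading`` on their axis' shared direction; background
(normative) words draw axis loadings from N(0, background_loading_sd^2) and
shared loadings from N(0, shared_loading_sd^2); target words use their
configured axis loadings and no shared loading. The common and pole-shared
components cancel exactly in every bias difference, so planted loadings map
monotonically onto recovered biases — exactly so when ``noise_sd`` is zero —
while making similarities to opposed poles positively correlated across the
population, as in real embeddings: a background word rich in a pole-shared
direction scores extreme toward *both* poles without an extreme bias.

The vocabulary is ordered background words first (generation order stands in
for descending frequency), then pole words, then targets, so the whole
pipeline — including the top-k normative population — runs on the synthetic
fixture. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .embeddings import WordEmbeddings, write_embeddings
from .errors import DegenerateSpaceError
from .lexicons import ConceptLexicon
from .ranking import classify_extreme, percentile_rank, NormativeDistribution
from .scoring import ScoreRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "write_fixture",
    "recovery_targets",
    "demo_study_config",
    "recovery_report",
    "CONCEPTS",
]

CONCEPTS = ("male", "female", "posemo", "negemo")

#: axis name -> truth column holding its planted loadings
AXIS_LOADING = {"gender": "gender_loading", "valence": "valence_loading"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic embedding space.

    Defaults are the package's reference parameter-recovery conditions:
    a 50-dimensional space, 2,000 background words, four 20-word pole
    lexicons with unit pole loadings, background loadings of spread 0.3,
    noise of norm 0.5, and 30 recovery targets with loadings evenly spaced
    in [-1, 1] (valence order decoupled from gender by a seeded shuffle).
    """

    d: int = 50
    n_background: int = 2000
    pole_size: int = 20
    targets: Optional[tuple[tuple[str, float, float], ...]] = None
    pole_loading: float = 1.0
    noise_sd: float = 0.5
    background_loading_sd: float = 0.3
    common_loading: float = 3.0
    pole_shared_loading: float = 1.5
    shared_loading_sd: float = 0.45
    seed: int = 42
    target_rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.d < 5:
            raise ValueError("d must be >= 5 (five latent directions plus noise room)")
        if self.n_background < 1 or self.pole_size < 1:
            raise ValueError("n_background and pole_size must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.targets is not None:
            for _, g, v in self.targets:
                if not (-1.0 <= g <= 1.0 and -1.0 <= v <= 1.0):
                    raise ValueError("target loadings must lie in [-1, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-word loadings plus the latent axis vectors themselves."""

    loadings: pd.DataFrame  # index word; columns gender_loading, valence_loading
    gender_axis: np.ndarray
    valence_axis: np.ndarray
    common_axis: np.ndarray

    @property
    def target_words(self) -> list[str]:
        return list(self.loadings.index[self.loadings["is_target"]])


def recovery_targets(
    n: int = 30, seed: int = 42, prefix: str = "tgt"
) -> tuple[tuple[str, float, float], ...]:
    """n targets with gender loadings evenly spaced in [-1, 1] and the same
    loading values assigned to valence in a seeded shuffled order."""
    grid = np.linspace(-1.0, 1.0, n)
    perm = np.random.default_rng(seed).permutation(n)
    return tuple(
        (f"{prefix}{i:02d}", float(grid[i]), float(grid[perm[i]])) for i in range(n)
    )


#: planted loadings (gender, valence) for the demonstration study: 11 colour
#: terms plus four anchors, with one strongly feminine colour and a block of
#: clearly positive colours, mirroring the structure the method should detect.
DEMO_TARGETS: tuple[tuple[str, float, float], ...] = (
    ("red", 0.15, 0.10),
    ("orange", 0.00, 0.05),
    ("yellow", 0.05, 0.10),
    ("green", 0.10, 0.85),
    ("blue", 0.05, 0.85),
    ("purple", -0.10, 0.05),
    ("pink", -0.90, 0.75),
    ("brown", 0.10, 0.75),
    ("grey", -0.05, 0.00),
    ("white", 0.10, 0.75),
    ("black", 0.05, 0.05),
    ("happy", 0.00, 1.00),
    ("sad", 0.00, -1.00),
    ("nun", -1.00, 0.00),
    ("priest", 1.00, 0.00),
)


def demo_study_config(seed: int = 42, **overrides) -> SyntheticConfig:
    """The bundled colour-term demonstration study at the default conditions."""
    return replace(SyntheticConfig(seed=seed, targets=DEMO_TARGETS), **overrides)


def generate(
    config: SyntheticConfig,
) -> tuple[WordEmbeddings, dict[str, ConceptLexicon], SyntheticTruth]:
    """Draw the embedding space, its four pole lexicons, and the truth table."""
    targets = config.targets
    if targets is None:
        targets = recovery_targets(seed=config.seed)
    rng = np.random.default_rng(config.seed)

    basis, _ = np.linalg.qr(rng.standard_normal((config.d, 5)))
    u_common, g_axis, v_axis, pg_axis, pv_axis = basis.T

    words: list[str] = []
    gender: list[float] = []
    valence: list[float] = []
    shared_g: list[float] = []
    shared_v: list[float] = []
    is_target: list[bool] = []

    bg_load = rng.normal(0.0, config.background_loading_sd, size=(config.n_background, 2))
    bg_shared = rng.normal(0.0, config.shared_loading_sd, size=(config.n_background, 2))
    for i in range(config.n_background):
        words.append(f"w{i:05d}")
        gender.append(float(bg_load[i, 0]))
        valence.append(float(bg_load[i, 1]))
        shared_g.append(float(bg_shared[i, 0]))
        shared_v.append(float(bg_shared[i, 1]))
        is_target.append(False)

    lexicons: dict[str, ConceptLexicon] = {}
    a = config.pole_loading
    q = config.pole_shared_loading
    # (gender, valence, shared_g, shared_v) planted loadings per pole concept
    pole_plan = {
        "male": (a, 0.0, q, 0.0),
        "female": (-a, 0.0, q, 0.0),
        "posemo": (0.0, a, 0.0, q),
        "negemo": (0.0, -a, 0.0, q),
    }
    for concept, (gl, vl, sgl, svl) in pole_plan.items():
        members = [f"{concept}{j:02d}" for j in range(config.pole_size)]
        lexicons[concept] = ConceptLexicon(name=concept, patterns=tuple(members))
        for m in members:
            words.append(m)
            gender.append(gl)
            valence.append(vl)
            shared_g.append(sgl)
            shared_v.append(svl)
            is_target.append(False)

    insert_at = len(words) if config.target_rank is None else min(config.target_rank, len(words))
    n_tgt = len(targets)
    words[insert_at:insert_at] = [w for w, _, _ in targets]
    gender[insert_at:insert_at] = [g for _, g, _ in targets]
    valence[insert_at:insert_at] = [v for _, _, v in targets]
    shared_g[insert_at:insert_at] = [0.0] * n_tgt
    shared_v[insert_at:insert_at] = [0.0] * n_tgt
    is_target[insert_at:insert_at] = [True] * n_tgt

    g_arr = np.asarray(gender)
    v_arr = np.asarray(valence)
    sg_arr = np.asarray(shared_g)
    sv_arr = np.asarray(shared_v)
    if (
        config.noise_sd == 0.0
        and config.common_loading == 0.0
        and not any(np.any(arr) for arr in (g_arr, v_arr, sg_arr, sv_arr))
    ):
        raise DegenerateSpaceError("all loadings and the noise scale are zero")

    matrix = (
        config.common_loading * u_common[None, :]
        + g_arr[:, None] * g_axis[None, :]
        + v_arr[:, None] * v_axis[None, :]
        + sg_arr[:, None] * pg_axis[None, :]
        + sv_arr[:, None] * pv_axis[None, :]
    )
    if config.noise_sd > 0.0:
        matrix = matrix + rng.normal(
            0.0, config.noise_sd / np.sqrt(config.d), size=(len(words), config.d)
        )

    emb = WordEmbeddings(words=words, matrix=matrix)
    truth = SyntheticTruth(
        loadings=pd.DataFrame(
            {"gender_loading": g_arr, "valence_loading": v_arr, "is_target": is_target},
            index=pd.Index(words, name="word"),
        ),
        gender_axis=g_axis,
        valence_axis=v_axis,
        common_axis=u_common,
    )
    return emb, lexicons, truth


def write_fixture(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialise a fixture directory: GloVe-text embeddings, four lexicon
    files, and a TSV truth table (word, gender_loading, valence_loading)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    emb, lexicons, truth = generate(config)
    paths: dict[str, Path] = {}
    paths["embeddings"] = write_embeddings(emb, out_dir / "embeddings.txt", "glove-text")
    for concept, lex in lexicons.items():
        p = out_dir / f"{concept}.txt"
        p.write_text("\n".join(lex.patterns) + "\n", encoding="utf-8")
        paths[concept] = p
    truth_path = out_dir / "truth.tsv"
    truth.loadings[["gender_loading", "valence_loading"]].to_csv(
        truth_path, sep="\t", float_format="%.8g"
    )
    paths["truth"] = truth_path
    return paths


def _planted_call(loading: float, population: np.ndarray, low: float, high: float) -> str:
    dist = NormativeDistribution(
        label="planted", values=np.sort(population), n=population.size
    )
    return classify_extreme(percentile_rank(dist, loading), low, high).call


def recovery_report(
    truth: SyntheticTruth | pd.DataFrame,
    records: Sequence[ScoreRecord],
    calls: Optional[Mapping[str, Mapping[str, str]]] = None,
    low: float = 5.0,
    high: float = 95.0,
) -> dict:
    """How well recovered biases match the planted loadings.

    Per axis: Spearman rank correlation between planted loadings and
    recovered biases over the scored words present in the truth table, and —
    when extremeness ``calls`` (word -> axis -> call) are supplied — a 2x2
    confusion table of planted-extreme (loading beyond the low/high
    percentiles of the whole planted-loading population) versus called-extreme.
    """
    loadings = truth.loadings if isinstance(truth, SyntheticTruth) else truth
    scored = {r.word: r for r in records}
    overlap = [w for w in loadings.index if w in scored]
    if len(overlap) < 3:
        raise ValueError(
            f"need at least 3 scored truth words, got {len(overlap)}"
        )
    report: dict = {"n": len(overlap), "axes": {}}
    for axis, col in AXIS_LOADING.items():
        planted = np.array([loadings.at[w, col] for w in overlap])
        recovered = np.array([scored[w].biases[axis] for w in overlap])
        rho = stats.spearmanr(planted, recovered).statistic
        entry: dict = {"spearman": float(rho)}
        if calls is not None:
            population = loadings[col].to_numpy()
            confusion = {
                "planted_extreme_called_extreme": 0,
                "planted_extreme_called_none": 0,
                "planted_none_called_extreme": 0,
                "planted_none_called_none": 0,
            }
            for w, pl in zip(overlap, planted):
                p_ext = _planted_call(float(pl), population, low, high) != "none"
                c_ext = calls[w][axis] != "none"
                key = (
                    f"planted_{'extreme' if p_ext else 'none'}"
                    f"_called_{'extreme' if c_ext else 'none'}"
                )
                confusion[key] += 1
            entry["confusion"] = confusion
        report["axes"][axis] = entry
    return report
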