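"""The synthetic generator: determinism, planted geometry, parameter recovery."""

import numpy as np
import pytest
from scipy import stats

from colorbias import (
    SyntheticConfig,
    generate,
    read_embeddings,
    recovery_report,
    write_fixture,
)
from colorbias.errors import DegenerateSpaceError
from colorbias.scoring import ScoreRecord, score_words, mean_vector
from colorbias.lexicons import resolve
from colorbias.synthetic import recovery_targets


def _score_targets(emb, lexicons, targets):
    concepts = [mean_vector(emb, resolve(l, emb), n) for n, l in lexicons.items()]
    records, missing = score_words(emb, targets, concepts)
    assert not missing
    return records


def _target_frame(truth):
    return truth.loadings[truth.loadings.is_target]


class TestGeneration:
    def test_same_seed_is_identical(self):
        cfg = SyntheticConfig(n_background=50, pole_size=5)
        emb1, _, truth1 = generate(cfg)
        emb2, _, truth2 = generate(cfg)
        assert emb1.words == emb2.words
        np.testing.assert_array_equal(emb1.matrix, emb2.matrix)
        assert truth1.loadings.equals(truth2.loadings)

    def test_same_seed_writes_identical_files(self, tmp_path):
        cfg = SyntheticConfig(n_background=30, pole_size=4)
        p1 = write_fixture(cfg, tmp_path / "a")
        p2 = write_fixture(cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_axes_orthonormal(self, recovery_space):
        _, _, truth = recovery_space
        for ax in (truth.gender_axis, truth.valence_axis, truth.common_axis):
            assert np.linalg.norm(ax) == pytest.approx(1.0, abs=1e-10)
        assert truth.gender_axis @ truth.valence_axis == pytest.approx(0.0, abs=1e-10)
        assert truth.gender_axis @ truth.common_axis == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_space_rejected(self):
        with pytest.raises(DegenerateSpaceError):
            generate(
                SyntheticConfig(
                    n_background=5,
                    noise_sd=0.0,
                    pole_loading=0.0,
                    background_loading_sd=0.0,
                    common_loading=0.0,
                    pole_shared_loading=0.0,
                    shared_loading_sd=0.0,
                    targets=(("t", 0.0, 0.0),),
                )
            )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(d=3)
        with pytest.raises(ValueError):
            SyntheticConfig(noise_sd=-1)
        with pytest.raises(ValueError):
            SyntheticConfig(targets=(("t", 2.0, 0.0),))

    def test_target_rank_controls_insertion(self):
        cfg = SyntheticConfig(
            n_background=20, pole_size=3, targets=(("t0", 0.5, 0.0),), target_rank=0
        )
        emb, _, _ = generate(cfg)
        assert emb.words[0] == "t0"

    def test_fixture_round_trips_through_pipeline_io(self, tmp_path):
        cfg = SyntheticConfig(n_background=40, pole_size=4)
        paths = write_fixture(cfg, tmp_path / "fix")
        emb, _, truth = generate(cfg)
        back = read_embeddings(paths["embeddings"])
        assert back.words == emb.words
        np.testing.assert_allclose(back.matrix, emb.matrix, atol=1e-6)
        header = paths["truth"].read_text().splitlines()[0]
        assert header.split("\t") == ["word", "gender_loading", "valence_loading"]


class TestNoiseFreeGeometry:
    def test_strongly_feminine_target_has_minimum_gender_bias(self):
        targets = (("fem", -1.0, 0.0), ("neu", 0.0, 0.0), ("mas", 1.0, 0.0))
        cfg = SyntheticConfig(n_background=100, pole_size=5, noise_sd=0.0, targets=targets)
        emb, lexicons, _ = generate(cfg)
        records = _score_targets(emb, lexicons, [t[0] for t in targets])
        biases = {r.word: r.biases["gender"] for r in records}
        assert biases["fem"] == min(biases.values())
        assert biases["mas"] == max(biases.values())

    def test_zero_loading_word_has_zero_biases(self):
        cfg = SyntheticConfig(
            n_background=100, pole_size=5, noise_sd=0.0, targets=(("flat", 0.0, 0.0),)
        )
        emb, lexicons, _ = generate(cfg)
        (rec,) = _score_targets(emb, lexicons, ["flat"])
        assert rec.biases["gender"] == pytest.approx(0.0, abs=1e-10)
        assert rec.biases["valence"] == pytest.approx(0.0, abs=1e-10)

    def test_bias_ordering_equals_planted_ordering_exactly(self):
        cfg = SyntheticConfig(noise_sd=0.0)
        emb, lexicons, truth = generate(cfg)
        records = _score_targets(emb, lexicons, [w for w, _, _ in recovery_targets()])
        tf = _target_frame(truth)
        for axis, col in (("gender", "gender_loading"), ("valence", "valence_loading")):
            planted = tf[col].to_numpy()
            recovered = np.array([r.biases[axis] for r in records])
            assert (np.argsort(planted) == np.argsort(recovered)).all()


class TestRecoveryReport:
    def test_noise_free_correlations_are_one(self):
        cfg = SyntheticConfig(n_background=200, noise_sd=0.0)
        emb, lexicons, truth = generate(cfg)
        records = _score_targets(emb, lexicons, truth.target_words)
        rep = recovery_report(truth, records)
        assert rep["axes"]["gender"]["spearman"] == pytest.approx(1.0)
        assert rep["axes"]["valence"]["spearman"] == pytest.approx(1.0)

    def test_default_conditions_recover_loadings(self, recovery_run):
        """Spearman(planted, recovered) >= 0.95 on both axes at sigma=0.5."""
        report, truth = recovery_run
        records = [
            ScoreRecord(
                r["word"],
                {c: r[f"sim_{c}"] for c in ("male", "female", "posemo", "negemo")},
                {a: r[f"bias_{a}"] for a in ("gender", "valence")},
            )
            for r in report.rows
        ]
        rep = recovery_report(truth, records, calls=report.calls())
        assert rep["n"] == 30
        for axis in ("gender", "valence"):
            assert rep["axes"][axis]["spearman"] >= 0.95
            confusion = rep["axes"][axis]["confusion"]
            assert sum(confusion.values()) == 30

    def test_fewer_than_three_overlapping_words_is_error(self, recovery_space):
        _, _, truth = recovery_space
        records = [ScoreRecord("tgt00", {}, {"gender": 0.1, "valence": 0.0})]
        with pytest.raises(ValueError, match="at least 3"):
            recovery_report(truth, records)

    def test_permuted_loadings_decorrelate(self, recovery_run):
        """Shuffling recovered biases against planted loadings kills the
        association: the mean Spearman over 1000 shuffles is ~0."""
        report, truth = recovery_run
        tf = _target_frame(truth)
        planted = tf["gender_loading"].to_numpy()
        by_word = {r["word"]: r["bias_gender"] for r in report.rows}
        recovered = np.array([by_word[w] for w in tf.index])
        rng = np.random.default_rng(123)
        rhos = [
            stats.spearmanr(planted, rng.permutation(recovered)).statistic
            for _ in range(1000)
        ]
        assert abs(np.mean(rhos)) < 0.02

    def test_noise_degrades_recovery_monotonically_on_average(self):
        """Mean Spearman over 20 seeds shrinks as noise grows past the signal."""
        sigmas = [0.0, 0.5, 1.0, 2.0, 5.0]
        means = []
        for sigma in sigmas:
            rhos = []
            for seed in range(20):
                cfg = SyntheticConfig(
                    n_background=200, pole_size=10, noise_sd=sigma, seed=seed
                )
                emb, lexicons, truth = generate(cfg)
                records = _score_targets(emb, lexicons, truth.target_words)
                rep = recovery_report(truth, records)
                rhos.append(rep["axes"]["gender"]["spearman"])
            means.append(np.mean(rhos))
        assert all(a >= b for a, b in zip(means, means[1:]))
        assert means[0] == pytest.approx(1.0)
        assert means[-1] < 0.5

    def test_axis_independence(self):
        """Planting only gender structure leaves valence biases centred on
        zero: over 20 seeds the grand mean is within 3 standard errors of 0."""
        seed_means = []
        for seed in range(20):
            targets = tuple((f"t{i}", g, 0.0) for i, g in enumerate(np.linspace(-1, 1, 10)))
            cfg = SyntheticConfig(
                n_background=200, pole_size=10, seed=seed, targets=targets
            )
            emb, lexicons, truth = generate(cfg)
            records = _score_targets(emb, lexicons, truth.target_words)
            seed_means.append(np.mean([r.biases["valence"] for r in records]))
        grand = np.mean(seed_means)
        se = np.std(seed_means, ddof=1) / np.sqrt(len(seed_means))
        assert abs(grand) <= 3 * se + 1e-12
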