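import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from colorbias import SyntheticConfig, WordEmbeddings, analyze, generate
from colorbias.synthetic import demo_study_config, recovery_targets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_emb() -> WordEmbeddings:
    """Six words in 2-d with easy hand geometry."""
    return WordEmbeddings(
        words=["the", "happy", "happiness", "harp", "sad", "pink"],
        matrix=np.array(
            [
                [1.0, 1.0],
                [1.0, 0.0],
                [0.9, 0.1],
                [0.5, 0.5],
                [0.0, 1.0],
                [0.6, 0.8],
            ]
        ),
    )


@pytest.fixture(scope="session")
def recovery_space():
    """The reference parameter-recovery fixture (default study conditions)."""
    return generate(SyntheticConfig())


@pytest.fixture(scope="session")
def recovery_run(recovery_space):
    emb, lexicons, truth = recovery_space
    targets = [w for w, _, _ in recovery_targets()]
    report = analyze(emb, lexicons, targets=targets)
    return report, truth


@pytest.fixture(scope="session")
def demo_space():
    """The colour-term demonstration study: 11 colours + 4 anchors."""
    return generate(demo_study_config(seed=42))


@pytest.fixture(scope="session")
def demo_report(demo_space):
    emb, lexicons, _ = demo_space
    return analyze(emb, lexicons)
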