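#!/usr/bin/env python
"""Generate the two synthetic embedding fixtures used by the analyses.

Writes, under results/fixtures/:

* ``recovery/`` — the parameter-recovery study: a 50-dimensional space with
  2,000 background words, four 20-word pole lexicons, and 30 target words
  whose gender/valence loadings are evenly spaced in [-1, 1].
* ``demo/`` — the colour-term demonstration study: the same space but with
  the 11 basic colour terms and 4 anchor words as targets, one colour
  planted strongly feminine and several planted clearly positive.

Both are deterministic (seed 42) GloVe-text files with truth tables.
"""

from pathlib import Path

from colorbias.synthetic import SyntheticConfig, demo_study_config, write_fixture

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"


def main() -> None:
    recovery = write_fixture(SyntheticConfig(seed=42), FIXTURES / "recovery")
    demo = write_fixture(demo_study_config(seed=42), FIXTURES / "demo")
    for label, paths in (("recovery", recovery), ("demo", demo)):
        size = sum(p.stat().st_size for p in paths.values())
        print(f"{label}: {len(paths)} files, {size / 1e6:.1f} MB -> {paths['embeddings'].parent}")


if __name__ == "__main__":
    main()
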