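#!/usr/bin/env python
"""Measure how faithfully the pipeline recovers planted bias structure.

Runs the analysis over the recovery fixture (30 targets with known gender
and valence loadings), then compares recovered biases with the planted
loadings: Spearman rank correlation per axis and a confusion table of
planted-extreme versus called-extreme. Writes results/recovery.json.
"""

import json
from pathlib import Path

import pandas as pd

from colorbias import RunConfig, run_analysis, recovery_report
from colorbias.scoring import ScoreRecord

ROOT = Path(__file__).resolve().parents[1]
FIX = ROOT / "scratch" / "fixtures" / "recovery"
CONCEPTS = ("male", "female", "posemo", "negemo")


def main() -> None:
    report = run_analysis(
        RunConfig(
            embeddings=FIX / "embeddings.txt",
            lexicons={c: FIX / f"{c}.txt" for c in CONCEPTS},
            targets=[f"tgt{i:02d}" for i in range(30)],
        )
    )
    truth = pd.read_csv(FIX / "truth.tsv", sep="\t", index_col="word")
    records = [
        ScoreRecord(
            r["word"],
            {c: r[f"sim_{c}"] for c in CONCEPTS},
            {a: r[f"bias_{a}"] for a in ("gender", "valence")},
        )
        for r in report.rows
    ]
    metrics = recovery_report(truth, records, calls=report.calls())
    out = ROOT / "results" / "recovery.json"
    out.write_text(json.dumps(metrics, indent=2) + "\n", encoding="utf-8")
    for axis, entry in metrics["axes"].items():
        print(f"{axis}: spearman(planted, recovered) = {entry['spearman']:.4f}")
        print(f"  confusion: {entry['confusion']}")
    print(f"metrics -> {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
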