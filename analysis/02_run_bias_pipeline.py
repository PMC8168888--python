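#!/usr/bin/env python
"""Score the colour-term demonstration study end to end.

Loads the demo fixture written by 01_simulate_embeddings.py, builds the four
concept vectors, scores the 11 colour terms and 4 anchor words, ranks every
score against the normative population, and writes the summary table to
results/colour_bias_report.{tsv,json}. Prints the gender/valence columns and
states which targets the strict 5/95 rule flags as extreme.
"""

from pathlib import Path

from colorbias import RunConfig, run_analysis

ROOT = Path(__file__).resolve().parents[1]
FIX = ROOT / "scratch" / "fixtures" / "demo"
CONCEPTS = ("male", "female", "posemo", "negemo")


def main() -> None:
    report = run_analysis(
        RunConfig(
            embeddings=FIX / "embeddings.txt",
            lexicons={c: FIX / f"{c}.txt" for c in CONCEPTS},
            out_tsv=ROOT / "results" / "colour_bias_report.tsv",
            out_json=ROOT / "results" / "colour_bias_report.json",
        )
    )
    print(f"{'word':8s} {'gender':>8s} {'pct':>6s} {'call':10s} {'valence':>8s} {'pct':>6s} call")
    for r in report.rows:
        print(
            f"{r['word']:8s} {r['bias_gender']: .4f} {r['pct_bias_gender']:6.2f} "
            f"{r['call_gender']:10s} {r['bias_valence']: .4f} "
            f"{r['pct_bias_valence']:6.2f} {r['call_valence']}"
        )
    fem = [r["word"] for r in report.rows if r["call_gender"] == "below_low"]
    masc = [r["word"] for r in report.rows if r["call_gender"] == "above_high"]
    pos = [r["word"] for r in report.rows if r["call_valence"] == "above_high"]
    neg = [r["word"] for r in report.rows if r["call_valence"] == "below_low"]
    print(f"\nfeminine-biased: {fem}\nmasculine-biased: {masc}")
    print(f"positively biased: {pos}\nnegatively biased: {neg}")
    print("report -> results/colour_bias_report.tsv")


if __name__ == "__main__":
    main()
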