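#!/usr/bin/env python
"""Desk-scale consistency checks against the published reference table.

Exact reproduction of the published similarities would require the ~800 MB
GloVe 6B download and a LIWC 2015 licence, so this analysis instead checks
what is checkable from the printed numbers alone: (i) that the bias
operation reproduces every internally consistent printed bias from its
printed pole similarities, and (ii) that the >=95th-percentile rule applied
to the printed percentile columns reproduces the published extreme counts
(7 colour terms on male similarity, 5 on valence bias).
Writes results/reference_checks.json.
"""

import json
from pathlib import Path

from colorbias import axis_bias
from colorbias.reference import ARITHMETIC_CONSISTENT, extreme_counts, reference_scores

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    table = reference_scores()
    checks = {}
    for word, axis in ARITHMETIC_CONSISTENT:
        row = table.loc[word]
        pos, neg = ("male", "female") if axis == "gender" else ("posemo", "negemo")
        got = round(axis_bias(float(row[f"sim_{pos}"]), float(row[f"sim_{neg}"])), 4)
        ok = got == row[f"bias_{axis}"]
        checks[f"{word}_{axis}"] = {"recomputed": got, "published": row[f"bias_{axis}"], "ok": bool(ok)}
        print(f"{word:7s} {axis:7s} recomputed {got: .4f} published {row[f'bias_{axis}']: .4f} {'OK' if ok else 'MISMATCH'}")

    white = table.loc["white"]
    delta = round(white["sim_posemo"] - white["sim_negemo"], 4)
    print(f"white   valence recomputed {delta: .4f} published {white['bias_valence']: .4f} "
          "(known publication inconsistency, excluded)")

    counts = {
        "colours_extreme_male_similarity": extreme_counts("pct_male"),
        "colours_extreme_valence_bias": extreme_counts("pct_bias_valence"),
    }
    print(f"extreme colour counts: {counts}")

    out = ROOT / "results" / "reference_checks.json"
    out.write_text(
        json.dumps({"bias_arithmetic": checks, "extreme_counts": counts,
                    "white_valence_recomputed": delta}, indent=2) + "\n",
        encoding="utf-8",
    )
    print(f"checks -> {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
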