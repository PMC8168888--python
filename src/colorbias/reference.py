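"""Published reference scores for the GloVe 6B / LIWC 2015 colour-term analysis.

These are the similarity scores, biases, and normative percentiles reported
by the original corpus analysis of the 11 basic colour terms and four anchor
words over the 300-dimensional GloVe 6B embeddings (Wikipedia 2014 +
Gigaword5), scored against the LIWC 2015 he/she/posemo/negemo categories with
a normative population of the 100,000 most frequent words. They serve as
input data for desk-scale consistency checks: exact reproduction of the
underlying similarities would require the ~800 MB embedding download and a
LIWC licence, which this package deliberately does not bundle.

Values are as printed: similarities and biases to 4 decimals, percentiles to
2 decimals. One known inconsistency: the ``white`` valence bias is printed as
0.1130 although its printed pole similarities differ by 0.1113; that row is
therefore excluded from exact bias arithmetic. The ``red`` valence bias
(printed 0.1019 vs a pole difference of 0.1020) differs only by rounding of
the printed similarities.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_scores",
    "COLOUR_TERMS",
    "ANCHOR_WORDS",
    "ARITHMETIC_CONSISTENT",
    "extreme_counts",
]

COLOUR_TERMS = (
    "red", "orange", "yellow", "green", "blue", "purple",
    "pink", "brown", "grey", "white", "black",
)
ANCHOR_WORDS = ("nun", "priest", "happy", "sad")

_COLUMNS = (
    "sim_male", "pct_male", "sim_female", "pct_female",
    "bias_gender", "pct_bias_gender",
    "sim_posemo", "pct_posemo", "sim_negemo", "pct_negemo",
    "bias_valence", "pct_bias_valence",
)

_ROWS = {
    "red":    (0.2531, 97.29, 0.1622, 94.71,  0.0909, 90.83, 0.2659, 96.79, 0.1639, 91.63,  0.1019, 94.83),
    "orange": (0.1192, 87.23, 0.1441, 93.06, -0.0249, 27.49, 0.1326, 89.11, 0.0444, 60.41,  0.0882, 93.04),
    "yellow": (0.1985, 95.31, 0.1613, 94.65,  0.0372, 66.73, 0.1819, 93.24, 0.1276, 87.50,  0.0543, 85.02),
    "green":  (0.2909, 98.18, 0.2194, 97.55,  0.0714, 84.28, 0.2652, 96.77, 0.0927, 79.86,  0.1726, 98.83),
    "blue":   (0.2250, 96.41, 0.1982, 96.74,  0.0268, 60.05, 0.2690, 96.87, 0.0883, 78.52,  0.1807, 99.01),
    "purple": (0.1422, 91.03, 0.1809, 95.88, -0.0387, 20.56, 0.1819, 93.24, 0.1009, 82.11,  0.0810, 91.80),
    "pink":   (0.1303, 89.29, 0.2701, 98.79, -0.1397,  1.77, 0.2283, 95.51, 0.0903, 79.17,  0.1380, 97.56),
    "brown":  (0.3538, 99.10, 0.2680, 98.75,  0.0858, 89.35, 0.2419, 96.02, 0.1385, 89.00,  0.1034, 95.00),
    "white":  (0.3261, 98.78, 0.2568, 98.55,  0.0692, 83.42, 0.3120, 97.85, 0.2007, 94.04,  0.1130, 95.76),
    "grey":   (0.1072, 84.54, 0.1427, 92.91, -0.0355, 22.15, 0.0949, 82.49, 0.0213, 48.13,  0.0737, 90.34),
    "black":  (0.2977, 98.31, 0.2652, 98.71,  0.0325, 63.79, 0.2659, 96.79, 0.2267, 95.37,  0.0392, 79.16),
    "nun":    (0.1082, 84.79, 0.2670, 98.73, -0.1588,  1.22, 0.1024, 84.21, 0.1143, 85.17, -0.0119, 48.02),
    "priest": (0.3405, 98.94, 0.1985, 96.76,  0.1420, 98.47, 0.1437, 90.35, 0.1665, 91.83, -0.0227, 40.57),
    "happy":  (0.3812, 99.33, 0.3719, 99.72,  0.0094, 48.59, 0.7130, 99.99, 0.4568, 99.68,  0.2563, 99.84),
    "sad":    (0.1433, 91.17, 0.2079, 97.14, -0.0646, 11.17, 0.4151, 99.21, 0.5475, 99.94, -0.1325,  4.17),
}

#: (word, axis) rows whose printed bias equals the printed pole-similarity
#: difference exactly at 4 decimals; only these are used in exact arithmetic
#: fixtures (the remaining rows differ through rounding of the similarities,
#: and white/valence through the inconsistency noted above).
ARITHMETIC_CONSISTENT = (
    ("red", "gender"), ("priest", "gender"), ("nun", "gender"),
    ("blue", "valence"), ("pink", "valence"), ("brown", "valence"),
    ("orange", "valence"), ("black", "gender"),
)


def reference_scores() -> pd.DataFrame:
    """The reference table as a DataFrame indexed by word."""
    return pd.DataFrame.from_dict(_ROWS, orient="index", columns=list(_COLUMNS)).rename_axis(
        "word"
    )


def extreme_counts(column: str, words=COLOUR_TERMS, high: float = 95.0) -> int:
    """How many of ``words`` the reference table flags extreme-high on a column.

    Printed percentiles are rounded to 2 decimals, so the published boundary
    is inclusive here: a printed 95.00 (e.g. brown's valence bias, bolded as
    extreme in the source table) counts as above the threshold.
    """
    table = reference_scores()
    return int((table.loc[list(words), column] >= high).sum())
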