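"""Deliberately naive reference implementations used as independent oracles.

These stay loop-based and definition-literal so they cannot share a code path
(or a bug) with the vectorised implementations they check.
"""

import math
from typing import Sequence


def naive_mean(vectors: Sequence[Sequence[float]]) -> list[float]:
    """Coordinate-wise mean via an explicit accumulation loop."""
    n = len(vectors)
    d = len(vectors[0])
    out = [0.0] * d
    for vec in vectors:
        for i in range(d):
            out[i] += vec[i]
    return [s / n for s in out]


def naive_cosine(w: Sequence[float], mu: Sequence[float]) -> float:
    """Sum over coordinates of the two unit-normalised vectors' products."""
    nw = math.sqrt(sum(x * x for x in w))
    nm = math.sqrt(sum(x * x for x in mu))
    return sum((wi / nw) * (mi / nm) for wi, mi in zip(w, mu))
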