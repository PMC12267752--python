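"""Independent brute-force oracles used by the test suite.

These deliberately re-implement rules in the most naive way possible
(repeated full rescans, exhaustive enumeration) so they share no code with
the implementations they check.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-9


def persistence_oracle(segments: list[tuple[float, float, str]], min_duration: float):
    """Naive left-to-right blip merging by repeated full rescans.

    A segment list (start, end, category) within one invasive interval is
    reduced by repeatedly coalescing adjacent same-category runs and
    absorbing the leftmost run shorter than ``min_duration`` that has a
    predecessor, until stable.
    """

    def coalesce(ss):
        out = []
        for s in ss:
            if out and out[-1][2] == s[2]:
                out[-1][1] = s[1]
            else:
                out.append(list(s))
        return out

    segs = coalesce([list(s) for s in segments])
    while True:
        for i, s in enumerate(segs):
            if i > 0 and s[1] - s[0] < min_duration - _EPS:
                segs[i - 1][1] = s[1]
                del segs[i]
                segs = coalesce(segs)
                break
        else:
            break
    return [(a, b, c) for a, b, c in segs]


def fisher_oracle(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    from scipy.stats import hypergeom

    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return float(min(total, 1.0))


def quantile_oracle(x: np.ndarray, q: float) -> float:
    """Type-7 (linear interpolation) quantile computed from first principles."""
    xs = np.sort(np.asarray(x, dtype=float))
    h = (len(xs) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return float(xs[lo] + (h - lo) * (xs[hi] - xs[lo]))
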