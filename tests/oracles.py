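"""Brute-force reference implementations used only to check the library.

These are deliberately written from first principles, in forms different from
the library code: hinges as medians of data halves rather than via the hinge
depth, and chromosome selection as a full sort plus slicing.
"""

from __future__ import annotations

from statistics import median


def fivenum_oracle(values):
    """(min, lower hinge, median, upper hinge, max) via median-of-halves.

    The Tukey hinges equal the medians of the lower and upper halves of the
    sorted data, where an odd-length dataset includes its overall median in
    both halves.
    """
    x = sorted(values)
    n = len(x)
    half = (n + 1) // 2
    lower = x[:half]
    upper = x[n - half:]
    return min(x), median(lower), median(x), median(upper), max(x)


def boxplot_oracle(values, coef=1.5):
    """Five-number boxplot stats with outlier fences, brute force.

    Returns (q0, q1, q2, q3, q4, sorted outliers).
    """
    _, h1, med, h3, _ = fivenum_oracle(values)
    lo = h1 - coef * (h3 - h1)
    hi = h3 + coef * (h3 - h1)
    inside = [v for v in values if lo <= v <= hi]
    out = sorted(v for v in values if v < lo or v > hi)
    return min(inside), h1, med, h3, max(inside), out


def select_oracle(i_values, lengths=None):
    """Pair chromosomes by descending i via full sort + slicing.

    Returns a list of pairs of i values; ties broken by descending length
    then input position, matching the documented deterministic rule.
    """
    n = len(i_values)
    if lengths is None:
        lengths = [0.0] * n
    order = sorted(range(n), key=lambda j: (-i_values[j], -lengths[j], j))
    ranked = [i_values[j] for j in order]
    return [tuple(ranked[2 * k: 2 * k + 2]) for k in range(n // 2)]
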