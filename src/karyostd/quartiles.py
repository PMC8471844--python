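"""Tukey five-number summaries with IQR outlier fences.

Per identified chromosome, the pooled centromeric indices are summarised the
way a boxplot summarises them: hinges by the Tukey fivenum depth rule, whisker
fences at hinge +/- coef * (upper hinge - lower hinge) with coef = 1.5 by
default, Q0/Q4 the most extreme data values still inside the fences, and
everything outside reported as outliers.

Hinge semantics matter.  With n sorted values and hinge depth
d = (floor((n+1)/2) + 1) / 2, the lower hinge is the mean of the values at
positions floor(d) and ceil(d) from the bottom and the upper hinge the mirror
image from the top.  For n = 6, d = 2 and the hinges are the 2nd and 5th
values — not what linear-interpolation (type-7) quantiles give.  Both methods
are offered (``method="hinge"`` is the default); the median is identical under
either and is never affected by outlier elimination, because the fences are
anchored at the hinges and so can never exclude the centre of the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .ranking import IdentifiedChromosome

QuantileMethod = str  # "hinge" | "linear"


@dataclass(frozen=True)
class FiveNumberSummary:
    """Boxplot statistics of one chromosome's pooled values."""

    q0: float  # lower whisker (extreme data value within the lower fence)
    q1: float  # lower hinge
    q2: float  # median
    q3: float  # upper hinge
    q4: float  # upper whisker
    outliers: tuple[float, ...]
    n: int  # count of non-outlier values

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def tukey_hinges(values: Sequence[float]) -> tuple[float, float, float]:
    """(lower hinge, median, upper hinge) by the Tukey fivenum depth rule."""
    if len(values) == 0:
        raise EmptyInputError("tukey_hinges: no values")
    x = sorted(values)
    n = len(x)
    d = (math.floor((n + 1) / 2) + 1) / 2
    lo = math.floor(d) - 1, math.ceil(d) - 1  # 0-based
    lower = (x[lo[0]] + x[lo[1]]) / 2.0
    upper = (x[n - 1 - lo[0]] + x[n - 1 - lo[1]]) / 2.0
    return lower, median(x), upper


def _linear_quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    q1, q2, q3 = np.percentile(np.asarray(values, float), [25, 50, 75])
    return float(q1), float(q2), float(q3)


def boxplot_stats(
    values: Sequence[float],
    whisker_coef: float = 1.5,
    method: QuantileMethod = "hinge",
) -> FiveNumberSummary:
    """Five-number summary with outliers outside the whisker fences.

    ``whisker_coef`` is the usual 1.5; ``math.inf`` disables the fences
    entirely (Q0 = min, Q4 = max, no outliers).
    """
    if len(values) == 0:
        raise EmptyInputError("boxplot_stats: no values")
    if whisker_coef < 0:
        raise ValueError(f"whisker_coef must be >= 0, got {whisker_coef}")
    if method == "hinge":
        q1, q2, q3 = tukey_hinges(values)
    elif method == "linear":
        q1, q2, q3 = _linear_quartiles(values)
    else:
        raise ValueError(f"unknown quantile method {method!r}")
    iqr = q3 - q1
    if math.isinf(whisker_coef):
        lo_fence, hi_fence = -math.inf, math.inf
    else:
        lo_fence, hi_fence = q1 - whisker_coef * iqr, q3 + whisker_coef * iqr
    inside = [v for v in values if lo_fence <= v <= hi_fence]
    outliers = tuple(sorted(v for v in values if not (lo_fence <= v <= hi_fence)))
    # the fences bracket [q1, q3], so inside is never empty
    return FiveNumberSummary(
        q0=min(inside),
        q1=q1,
        q2=q2,
        q3=q3,
        q4=max(inside),
        outliers=outliers,
        n=len(inside),
    )


@dataclass(frozen=True)
class ChromosomeSummary:
    """Per-chromosome summary row: boxplot stats plus arithmetic means."""

    index: int
    stats: FiveNumberSummary
    mean_i: float
    mean_length: float


def summarize_karyotype(
    chromosomes: Iterable[IdentifiedChromosome],
    whisker_coef: float = 1.5,
    method: QuantileMethod = "hinge",
) -> list[ChromosomeSummary]:
    """One summary per identified chromosome, order preserved.

    Besides the five-number summary of i, each row carries the arithmetic
    means of i and of total length over the pooled values — the inputs to the
    mean-length-vs-mean-i species scatter.
    """
    chromosomes = list(chromosomes)
    if not chromosomes:
        raise EmptyInputError("summarize_karyotype: no chromosomes")
    out = []
    for c in chromosomes:
        if not c.i_values:
            raise EmptyInputError(f"chromosome {c.index} has no pooled values")
        out.append(
            ChromosomeSummary(
                index=c.index,
                stats=boxplot_stats(c.i_values, whisker_coef, method),
                mean_i=float(np.mean(c.i_values)),
                mean_length=float(np.mean(c.lengths)) if c.lengths else math.nan,
            )
        )
    return out


def summary_table(species: str, summaries: Sequence[ChromosomeSummary]) -> pd.DataFrame:
    """TSV-ready table: species,chromosome_index,q0..q4,n_outliers,mean_i,mean_length."""
    return pd.DataFrame(
        {
            "species": species,
            "chromosome_index": [s.index for s in summaries],
            "q0": [s.stats.q0 for s in summaries],
            "q1": [s.stats.q1 for s in summaries],
            "q2": [s.stats.q2 for s in summaries],
            "q3": [s.stats.q3 for s in summaries],
            "q4": [s.stats.q4 for s in summaries],
            "n_outliers": [len(s.stats.outliers) for s in summaries],
            "mean_i": [s.mean_i for s in summaries],
            "mean_length": [s.mean_length for s in summaries],
        }
    )


def quick_boxplot(summaries: Sequence[ChromosomeSummary], ax=None):
    """Quick-look boxplot of the per-chromosome i distributions (no styling).

    Requires matplotlib (``plot`` extra); not used by the pipeline.
    """
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 4))
    for s in summaries:
        st = s.stats
        ax.bxp(
            [
                {
                    "whislo": st.q0,
                    "q1": st.q1,
                    "med": st.q2,
                    "q3": st.q3,
                    "whishi": st.q4,
                    "fliers": list(st.outliers),
                }
            ],
            positions=[s.index],
            showfliers=True,
        )
    ax.set_xlabel("chromosome (ranked by descending i)")
    ax.set_ylabel("centromeric index i")
    return ax
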