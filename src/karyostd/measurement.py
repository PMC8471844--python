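"""Raw arm measurements and the arithmetic turning them into chromosome metrics.

The measured unit is one chromosome in one metaphase spread, recorded as four
chromatid-arm lengths in pixels: the two long-arm chromatids (``q1``, ``q2``)
and the two short-arm chromatids (``p1``, ``p2``).  Arm lengths are averaged
per chromatid pair,

    p = (p1 + p2) / 2,    q = (q1 + q2) / 2,

and the derived quantities are

    length = p + q            total chromosome length
    d      = q - p            arm difference
    r      = q / p            arm ratio (infinite for telocentrics)
    i      = 100 p / (p + q)  centromeric index, in [0, 50]

The centromeric index is the crucial statistic downstream: unlike ``r`` it is
bounded (0 = strictly terminal centromere, 50 = strictly median) and is
computed in the division-safe form ``100*p/(p+q)``, algebraically equal to
``100/(r+1)``, so telocentric chromosomes (p = 0) pose no problem.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidMeasurementError, OrientationWarning

logger = logging.getLogger(__name__)

#: chromatid pairs whose lengths differ by more than this factor are logged
CHROMATID_CONSISTENCY_FACTOR = 3.0

CSV_COLUMNS = ("species", "metaphase", "chromosome", "q1", "q2", "p1", "p2")
METRIC_COLUMNS = ("species", "metaphase", "p", "q", "length", "d", "r", "i")


@dataclass(frozen=True)
class ArmMeasurement:
    """Four chromatid-arm lengths (pixels) of one chromosome in one metaphase."""

    metaphase_id: str
    species_id: str
    q1: float
    q2: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "p1", "p2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidMeasurementError(
                    f"arm {name}={v!r} must be finite and >= 0 "
                    f"(species={self.species_id}, metaphase={self.metaphase_id})"
                )
        if self.q1 + self.q2 == 0 and self.p1 + self.p2 == 0:
            raise InvalidMeasurementError(
                "all four arm values are zero: a chromosome cannot have zero "
                f"total length (species={self.species_id}, metaphase={self.metaphase_id})"
            )


@dataclass(frozen=True)
class ChromosomeMetrics:
    """Derived per-chromosome quantities (pixels, except r and i)."""

    p: float
    q: float
    length: float
    d: float
    r: float  # math.inf when p == 0
    i: float  # centromeric index in [0, 50]


def arm_means(m: ArmMeasurement) -> tuple[float, float]:
    """Average the chromatid pairs into (p, q), enforcing the q >= p convention.

    Manual measurement tables routinely carry swapped short/long labels; when
    the averaged "short" arm exceeds the averaged "long" arm the two are
    swapped and an :class:`OrientationWarning` is issued rather than the row
    rejected, so the convention q >= p always holds downstream.
    """
    p = (m.p1 + m.p2) / 2.0
    q = (m.q1 + m.q2) / 2.0
    _check_chromatid_consistency(m)
    if p > q:
        warnings.warn(
            f"short-arm mean {p} exceeds long-arm mean {q}; swapping to "
            f"restore q >= p (species={m.species_id}, metaphase={m.metaphase_id})",
            OrientationWarning,
            stacklevel=2,
        )
        p, q = q, p
    return p, q


def _check_chromatid_consistency(m: ArmMeasurement) -> None:
    # No published filter exists for inconsistent chromatids; flag, never drop.
    for a, b, name in ((m.q1, m.q2, "q"), (m.p1, m.p2, "p")):
        lo, hi = min(a, b), max(a, b)
        if lo > 0 and hi / lo > CHROMATID_CONSISTENCY_FACTOR:
            logger.warning(
                "chromatid %s arms differ by more than %.1fx (%g vs %g) in "
                "species=%s metaphase=%s",
                name, CHROMATID_CONSISTENCY_FACTOR, a, b, m.species_id, m.metaphase_id,
            )


def metrics(p: float, q: float) -> ChromosomeMetrics:
    """Compute length, d, r and i from averaged arm lengths.

    Requires 0 <= p <= q and q > 0.  For p = 0 the arm ratio is infinite and
    i = 0 (telocentric sensu stricto).
    """
    if q <= 0:
        raise InvalidMeasurementError(f"long arm q={q} must be > 0")
    if p < 0 or p > q:
        raise InvalidMeasurementError(f"need 0 <= p <= q, got p={p}, q={q}")
    r = math.inf if p == 0 else q / p
    # p <= q gives i <= 50 mathematically; clamp the last-ulp rounding excess
    i = min(100.0 * p / (p + q), 50.0)
    return ChromosomeMetrics(p=p, q=q, length=p + q, d=q - p, r=r, i=i)


def measure(m: ArmMeasurement) -> ChromosomeMetrics:
    """Convenience composition of :func:`arm_means` and :func:`metrics`."""
    return metrics(*arm_means(m))


def centromeric_index_from_ratio(r: float) -> float:
    """i = 100/(r+1); accepts r = inf (returns 0)."""
    return 0.0 if math.isinf(r) else 100.0 / (r + 1.0)


def arm_ratio_from_index(i: float) -> float:
    """r = (100 - i)/i; returns inf at i = 0."""
    return math.inf if i == 0 else (100.0 - i) / i


# ---------------------------------------------------------------------------
# tabular I/O

def read_measurements(path: Union[str, Path]) -> pd.DataFrame:
    """Read a measurement CSV with columns species,metaphase,chromosome,q1,q2,p1,p2.

    The ``chromosome`` column is optional and ignored for identification (the
    toolkit identifies chromosomes by rank, not by the measurer's label).
    Raises a parse error naming the offending line for malformed rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"species": str, "metaphase": str})
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no measurement rows") from None
    required = {"species", "metaphase", "q1", "q2", "p1", "p2"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidMeasurementError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    if df.empty:
        raise EmptyInputError(f"{path}: no measurement rows")
    for col in ("q1", "q2", "p1", "p2"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        numeric = pd.to_numeric(df[col], errors="coerce")
        invalid = numeric.isna() | (numeric < 0) | ~numeric.apply(math.isfinite)
        if invalid.any():
            row = int(invalid.idxmax())
            # +2: header line and 1-based numbering
            raise InvalidMeasurementError(
                f"{path}:{row + 2}: column {col} value {df[col].iloc[row]!r} "
                "is not a finite non-negative number"
            )
        df[col] = numeric
        del bad
    zero = (df[["q1", "q2", "p1", "p2"]].sum(axis=1) == 0)
    if zero.any():
        row = int(zero.idxmax())
        raise InvalidMeasurementError(
            f"{path}:{row + 2}: all four arm values are zero"
        )
    return df


def compute_metrics_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`measure` over a measurement table.

    Returns a DataFrame with columns species,metaphase,p,q,length,d,r,i in the
    input row order.  Orientation swaps are applied silently row-wise here (the
    per-row API warns; bulk tables log a single summary instead).
    """
    p = (measurements["p1"].to_numpy(float) + measurements["p2"].to_numpy(float)) / 2.0
    q = (measurements["q1"].to_numpy(float) + measurements["q2"].to_numpy(float)) / 2.0
    swapped = p > q
    if swapped.any():
        logger.warning(
            "orientation-normalised %d/%d rows (p-labelled arm longer than q)",
            int(swapped.sum()), len(p),
        )
        p2 = p.copy()
        p = pd.Series(p).where(~swapped, q).to_numpy()
        q = pd.Series(q).where(~swapped, p2).to_numpy()
    length = p + q
    if (length == 0).any():
        raise InvalidMeasurementError("row with zero total chromosome length")
    out = pd.DataFrame(
        {
            "species": measurements["species"].to_numpy(),
            "metaphase": measurements["metaphase"].to_numpy(),
            "p": p,
            "q": q,
            "length": length,
            "d": q - p,
            # q > 0 wherever p == 0 (zero-length rows were rejected above)
            "r": np.divide(q, p, out=np.full_like(q, math.inf), where=p > 0),
            "i": np.minimum(100.0 * p / length, 50.0),
        }
    )
    return out


def relative_lengths(metrics_df: pd.DataFrame) -> pd.DataFrame:
    """Optional normalisation: lengths as percent of each metaphase's total.

    Returns a copy with length, d, p and q rescaled per (species, metaphase)
    group so lengths sum to 100; r and i are scale-invariant and unchanged.
    Off by default everywhere — the standard statistics are defined on raw
    pixel values.
    """
    out = metrics_df.copy()
    total = out.groupby(["species", "metaphase"])["length"].transform("sum")
    factor = 100.0 / total
    for col in ("p", "q", "length", "d"):
        out[col] = out[col] * factor
    return out


def write_metrics_table(metrics_df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the metrics table as TSV; infinite r is emitted as the literal ``inf``."""
    metrics_df.to_csv(path, sep="\t", index=False, columns=list(METRIC_COLUMNS))


def iter_measurements(df: pd.DataFrame) -> Iterable[ArmMeasurement]:
    """Yield :class:`ArmMeasurement` records from a measurement table."""
    for row in df.itertuples(index=False):
        yield ArmMeasurement(
            metaphase_id=str(row.metaphase),
            species_id=str(row.species),
            q1=float(row.q1),
            q2=float(row.q2),
            p1=float(row.p1),
            p2=float(row.p2),
        )
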