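"""Rank-based chromosome identification across metaphase spreads.

True homolog pairing is impossible from Giemsa measurements alone, so
chromosomes are identified positionally: within each metaphase, sort by
descending centromeric index, call the two highest-ranked chromosomes
"chromosome 1" (one homologous pair), ranks 3 and 4 "chromosome 2", and so on
down to the pair with the lowest indices.  Pooling the rank-k pair from every
metaphase of a species yields, for each identity chr_k, a sample of i values
(two per metaphase) whose distribution is summarised downstream.

Ties in i (pervasive at i = 0 among telocentrics) are broken by descending
total length, then by stable input order — a deterministic rule so repeated
runs agree; the pooled medians are insensitive to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import CardinalityError, EmptyInputError, PairingError
from .measurement import ChromosomeMetrics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Metaphase:
    """All measured chromosomes of one metaphase spread."""

    metaphase_id: str
    chromosomes: tuple[ChromosomeMetrics, ...]

    @property
    def count(self) -> int:
        return len(self.chromosomes)


@dataclass
class IdentifiedChromosome:
    """Cross-metaphase pool of values for one ranked chromosome identity chr_k."""

    index: int  # k in 1..n_pairs
    i_values: list[float] = field(default_factory=list)
    lengths: list[float] = field(default_factory=list)
    metaphase_ids: list[str] = field(default_factory=list)

    def extend(self, pair: tuple[ChromosomeMetrics, ...], metaphase_id: str = "") -> None:
        for c in pair:
            self.i_values.append(c.i)
            self.lengths.append(c.length)
            self.metaphase_ids.append(metaphase_id)


def _rank_key(indexed: tuple[int, ChromosomeMetrics]):
    pos, c = indexed
    # descending i, then descending length, then stable input order
    return (-c.i, -c.length, pos)


def select_chromosomes(
    m: Metaphase, n_pairs: int
) -> list[tuple[int, tuple[ChromosomeMetrics, ChromosomeMetrics]]]:
    """Sort one metaphase by descending i and pair consecutive ranks.

    Returns ``[(1, (rank1, rank2)), (2, (rank3, rank4)), ...]`` with exactly
    ``n_pairs`` entries.  The metaphase must contain exactly ``2 * n_pairs``
    chromosomes.
    """
    if m.count % 2 != 0:
        raise PairingError(
            f"metaphase {m.metaphase_id!r} has an odd chromosome count ({m.count})"
        )
    if m.count != 2 * n_pairs:
        raise CardinalityError(
            f"metaphase {m.metaphase_id!r} has {m.count} chromosomes, "
            f"expected {2 * n_pairs}"
        )
    ordered = [c for _, c in sorted(enumerate(m.chromosomes), key=_rank_key)]
    return [
        (k + 1, (ordered[2 * k], ordered[2 * k + 1])) for k in range(n_pairs)
    ]


def aggregate(
    metaphases: list[Metaphase], n_pairs: int, strict: bool = True
) -> list[IdentifiedChromosome]:
    """Pool rank-k pairs over metaphases into chr_1..chr_{n_pairs}.

    With ``strict`` (default) every metaphase must hold exactly ``2*n_pairs``
    chromosomes — the uniform-complement assumption.  In permissive mode a
    deviating metaphase contributes pairs only down to ``count // 2``
    (nothing is padded) and the deviation is logged.
    """
    if not metaphases:
        raise EmptyInputError("no metaphases to aggregate")
    pool = [IdentifiedChromosome(index=k + 1) for k in range(n_pairs)]
    for m in metaphases:
        if m.count == 2 * n_pairs:
            pairs = select_chromosomes(m, n_pairs)
        elif strict:
            raise CardinalityError(
                f"metaphase {m.metaphase_id!r} has {m.count} chromosomes, "
                f"expected {2 * n_pairs} (strict mode)"
            )
        else:
            local = m.count // 2
            logger.warning(
                "metaphase %s has %d chromosomes (expected %d); "
                "contributing only chr1..chr%d",
                m.metaphase_id, m.count, 2 * n_pairs, local,
            )
            trimmed = Metaphase(m.metaphase_id, m.chromosomes[: 2 * local]) \
                if m.count % 2 else m
            pairs = select_chromosomes(
                Metaphase(m.metaphase_id, trimmed.chromosomes), local
            )
        for k, pair in pairs:
            if k <= n_pairs:
                pool[k - 1].extend(pair, metaphase_id=m.metaphase_id)
    return pool


# ---------------------------------------------------------------------------
# tabular layer used by the pipeline

def metaphases_from_metrics(df: pd.DataFrame) -> list[Metaphase]:
    """Group a single-species metrics table into Metaphase objects."""
    out = []
    for mid, grp in df.groupby("metaphase", sort=True):
        chroms = tuple(
            ChromosomeMetrics(
                p=row.p, q=row.q, length=row.length, d=row.d, r=row.r, i=row.i
            )
            for row in grp.itertuples(index=False)
        )
        out.append(Metaphase(metaphase_id=str(mid), chromosomes=chroms))
    return out


def identification_table(
    species: str, identified: list[IdentifiedChromosome]
) -> pd.DataFrame:
    """Long-format table ``species,chromosome_index,metaphase,i,length``."""
    rows = [
        (species, c.index, mid, i, ln)
        for c in identified
        for mid, i, ln in zip(c.metaphase_ids, c.i_values, c.lengths)
    ]
    return pd.DataFrame(
        rows, columns=["species", "chromosome_index", "metaphase", "i", "length"]
    )
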