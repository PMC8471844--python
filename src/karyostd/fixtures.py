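"""Packaged reference karyotypes of three diploid Carassius species.

The shipped table holds the published standardized karyotypes of the goldfish
*Carassius auratus* (CAU), the crucian carp *C. carassius* (CCA) and the
Prussian carp *C. gibelio* (CGI): for each of the 50 ranked chromosomes of
the haploid complement (2n = 100), the median centromeric index over ten
measured metaphases and its Levan category.  It is the ground truth the test
suite and the acceptance checks classify against, and a convenient template
source for the synthetic generator.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .classification import StandardKaryotype, KaryotypeEntry
from .errors import FixtureIntegrityError

SPECIES = ("CAU", "CCA", "CGI")

_FIXTURE_NAME = "carassius_reference.tsv"
_FIXTURE_SHA256 = "89e8173797605e5e135686f2b955da6a17ca212de21906dd5973b8bf5f3150e0"


def _fixture_bytes() -> bytes:
    data = (
        resources.files("karyostd").joinpath("data").joinpath(_FIXTURE_NAME).read_bytes()
    )
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"{_FIXTURE_NAME}: checksum mismatch ({digest}); the packaged "
            "reference table is corrupted"
        )
    return data


def reference_table() -> pd.DataFrame:
    """The reference table as a DataFrame (50 rows, one per ranked chromosome)."""
    import io

    return pd.read_csv(io.BytesIO(_fixture_bytes()), sep="\t")


def reference_medians(species: str) -> list[float]:
    """The 50 median centromeric indices of one species, chr1 first."""
    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}; expected one of {SPECIES}")
    df = reference_table().sort_values("chromosome")
    return [float(v) for v in df[f"{species}_median_i"]]


def load_reference_karyotypes() -> dict[str, StandardKaryotype]:
    """The three reference karyotypes with their published categories.

    Categories come verbatim from the packaged table (not re-derived), so the
    objects can serve as an independent target for the classifier.
    """
    df = reference_table().sort_values("chromosome")
    out = {}
    for sp in SPECIES:
        entries = tuple(
            KaryotypeEntry(
                index=int(row.chromosome),
                median_i=float(getattr(row, f"{sp}_median_i")),
                category=str(getattr(row, f"{sp}_category")),
            )
            for row in df.itertuples(index=False)
        )
        out[sp] = StandardKaryotype(species_id=sp, entries=entries)
    return out
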