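"""Synthetic metaphase measurement generator.

Emulates the measurement setting the pipeline consumes: a species with a
known haploid set of chromosome templates (true centromeric index and true
length in pixels) photographed over several metaphase spreads.  Each spread
carries its own multiplicative condensation factor — chromosomes condense
differently from cell to cell, changing every length but never the relative
centromere position, so i is untouched by condensation.  Measurement noise is
additive zero-mean Gaussian on the four chromatid arms (the quantities a
person actually traces), with standard deviation proportional to the true arm
length and truncation at zero.  Telocentric templates have a structurally
zero short arm, so p1 = p2 = 0 at any noise level.

Defaults mirror the study design the toolkit standardizes: 10 metaphases per
species (five male + five female spreads, pooled), 50 templates (2n = 100),
1% chromatid-arm noise and a log-normal condensation spread of sigma = 0.1.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError
from .measurement import CSV_COLUMNS


class ChromosomeTemplate(BaseModel):
    """True (noise-free) i and length of one haploid chromosome identity."""

    i: float = Field(ge=0.0, le=50.0)
    length: float = Field(gt=0.0)


class KaryotypeSpec(BaseModel):
    """Generator configuration for one synthetic species."""

    species: str
    templates: list[ChromosomeTemplate]
    n_metaphases: int = Field(default=10, ge=1)
    condensation_sigma: float = Field(default=0.1, ge=0.0)
    arm_noise_frac: float = Field(default=0.01, ge=0.0)
    seed: Optional[int] = None

    @field_validator("templates")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("at least one chromosome template is required")
        return v

    @model_validator(mode="after")
    def _ok(self):
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "KaryotypeSpec":
        try:
            data = yaml.safe_load(Path(path).read_text())
            return cls.model_validate(data)
        except Exception as exc:  # surfaced as a config error for the CLI
            raise ConfigError(f"invalid karyotype spec {path}: {exc}") from exc

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def default_lengths(n: int, longest: float = 40.0, shortest: float = 15.5) -> np.ndarray:
    """Linear length ramp (pixels) over ranked chromosomes, longest first.

    The defaults span the chromosome sizes typical of small-chromosome fish
    karyotypes at metaphase magnification.
    """
    return np.linspace(longest, shortest, n)


def spec_from_medians(
    species: str,
    medians: Sequence[float],
    lengths: Optional[Sequence[float]] = None,
    **kwargs,
) -> KaryotypeSpec:
    """Build a generator spec whose true i values are a karyotype's medians."""
    meds = list(medians)
    if lengths is None:
        lengths = default_lengths(len(meds))
    return KaryotypeSpec(
        species=species,
        templates=[
            ChromosomeTemplate(i=float(i), length=float(ln))
            for i, ln in zip(meds, lengths)
        ],
        **kwargs,
    )


def generate(spec: KaryotypeSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a measurement table (CSV dialect) from a karyotype spec.

    Deterministic for a fixed seed (argument overrides ``spec.seed``).  Each
    metaphase contains exactly two chromosomes per template; each chromosome
    gets independent chromatid-arm noise.
    """
    if seed is None:
        seed = spec.seed
    if seed is None:
        raise ConfigError("a seed is required for reproducible generation")
    rng = np.random.default_rng(int(seed))

    n_templates = len(spec.templates)
    true_i = np.array([t.i for t in spec.templates])
    true_len = np.array([t.length for t in spec.templates])
    true_p = true_len * true_i / 100.0
    true_q = true_len - true_p

    rows = []
    for m in range(1, spec.n_metaphases + 1):
        scale = float(rng.lognormal(mean=0.0, sigma=spec.condensation_sigma))
        # two homologs per template, arms noised independently
        p_arm = np.repeat(true_p * scale, 2)
        q_arm = np.repeat(true_q * scale, 2)
        sd_p = spec.arm_noise_frac * p_arm
        sd_q = spec.arm_noise_frac * q_arm
        p1 = np.clip(p_arm + rng.normal(0.0, 1.0, p_arm.size) * sd_p, 0.0, None)
        p2 = np.clip(p_arm + rng.normal(0.0, 1.0, p_arm.size) * sd_p, 0.0, None)
        q1 = np.clip(q_arm + rng.normal(0.0, 1.0, q_arm.size) * sd_q, 0.0, None)
        q2 = np.clip(q_arm + rng.normal(0.0, 1.0, q_arm.size) * sd_q, 0.0, None)
        chrom_labels = np.repeat(np.arange(1, n_templates + 1), 2)
        rows.append(
            pd.DataFrame(
                {
                    "species": spec.species,
                    "metaphase": f"mp{m:02d}",
                    "chromosome": chrom_labels,
                    "q1": q1,
                    "q2": q2,
                    "p1": p1,
                    "p2": p2,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[list(CSV_COLUMNS)]


def write_measurements(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a generated measurement table as CSV (fixed float format, so a
    fixed seed gives a byte-identical file)."""
    df.to_csv(path, index=False, float_format="%.6f")
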