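"""End-to-end standardization pipeline: measurement CSV in, report bundle out.

``run_standardize`` chains the stages — metrics from raw arm measurements,
rank-based identification per species, quartile summaries, Levan
classification — and writes a bundle of plain-text tables:

    metrics.tsv          per-row derived metrics (p, q, length, d, r, i)
    identification.tsv   pooled i/length values per ranked chromosome
    summary.tsv          per-chromosome five-number summary + means
    karyotype.tsv        per-chromosome median i and category, per species
    formulas.txt         one karyotype formula line per species
    <species>.karyotype.json   machine-readable standardized karyotype
    run.log              row counts, warnings, and the effective config

Data tables are deterministic for identical inputs and config; only the log
carries timestamps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import measurement, ranking, quartiles
from .classification import LEVAN, CategoryScheme, StandardKaryotype, build_karyotype
from .errors import ConfigError, EmptyInputError

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Tunable settings of the standardization pipeline."""

    ploidy: int = Field(default=100, description="2n chromosome number")
    quantile_method: str = Field(default="hinge", pattern="^(hinge|linear)$")
    whisker_coef: float = Field(default=1.5, ge=0.0)
    strict: bool = True
    ploidy_factor: int = Field(default=2, ge=1)
    scheme: CategoryScheme = LEVAN
    log_level: str = "INFO"

    model_config = {"arbitrary_types_allowed": True}

    @field_validator("ploidy")
    @classmethod
    def _even(cls, v: int) -> int:
        if v <= 0 or v % 2 != 0:
            raise ValueError(f"ploidy (2n) must be a positive even integer, got {v}")
        return v

    @property
    def n_pairs(self) -> int:
        return self.ploidy // 2

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
            return cls.model_validate(data)
        except ValueError as exc:
            raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc


@dataclass
class StandardizeResult:
    """In-memory result bundle of one standardization run."""

    metrics: pd.DataFrame
    identification: pd.DataFrame
    summary: pd.DataFrame
    karyotypes: dict[str, StandardKaryotype]
    summaries: dict[str, list[quartiles.ChromosomeSummary]]


def standardize_frame(
    measurements: pd.DataFrame, config: Optional[PipelineConfig] = None
) -> StandardizeResult:
    """Run the full pipeline on an in-memory measurement table."""
    config = config or PipelineConfig()
    metrics_df = measurement.compute_metrics_table(measurements)
    if metrics_df.empty:
        raise EmptyInputError("no valid measurement rows")

    ident_tables, karyotypes, summaries = [], {}, {}
    for species, sp_metrics in metrics_df.groupby("species", sort=True):
        metas = ranking.metaphases_from_metrics(sp_metrics)
        identified = ranking.aggregate(metas, config.n_pairs, strict=config.strict)
        identified = [c for c in identified if c.i_values]
        if not identified:
            raise EmptyInputError(f"species {species}: no valid metaphases")
        ident_tables.append(ranking.identification_table(str(species), identified))
        sp_summaries = quartiles.summarize_karyotype(
            identified, config.whisker_coef, config.quantile_method
        )
        summaries[str(species)] = sp_summaries
        medians = [s.stats.q2 for s in sp_summaries]
        karyotypes[str(species)] = build_karyotype(
            str(species), medians, config.scheme, config.ploidy_factor
        )
        logger.info(
            "%s: %d metaphases, %d identified chromosomes, formula %s",
            species, len(metas), len(sp_summaries), karyotypes[str(species)].formula,
        )

    summary_df = pd.concat(
        [quartiles.summary_table(sp, summaries[sp]) for sp in sorted(summaries)],
        ignore_index=True,
    )
    return StandardizeResult(
        metrics=metrics_df,
        identification=pd.concat(ident_tables, ignore_index=True),
        summary=summary_df,
        karyotypes=karyotypes,
        summaries=summaries,
    )


def karyotype_report_table(karyotypes: dict[str, StandardKaryotype]) -> pd.DataFrame:
    """Wide per-chromosome report: median i (2 dp display) and category per species."""
    species = sorted(karyotypes)
    n = len(karyotypes[species[0]].entries)
    data: dict[str, list] = {"chromosome": list(range(1, n + 1))}
    for sp in species:
        data[f"{sp}_median_i"] = [round(e.median_i, 2) for e in karyotypes[sp].entries]
    for sp in species:
        data[f"{sp}_category"] = [e.category for e in karyotypes[sp].entries]
    return pd.DataFrame(data)


def run_standardize(
    measurements_csv: Union[str, Path],
    out_dir: Union[str, Path],
    config: Optional[PipelineConfig] = None,
) -> StandardizeResult:
    """Read a measurement CSV, standardize, and write the report bundle."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("karyostd")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(config.log_level)
    try:
        df = measurement.read_measurements(measurements_csv)
        logger.info("read %d measurement rows from %s", len(df), measurements_csv)
        logger.info("config: %s", config.model_dump(exclude={"scheme"}))
        result = standardize_frame(df, config)

        measurement.write_metrics_table(result.metrics, out / "metrics.tsv")
        result.identification.to_csv(out / "identification.tsv", sep="\t", index=False)
        result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        karyotype_report_table(result.karyotypes).to_csv(
            out / "karyotype.tsv", sep="\t", index=False
        )
        with open(out / "formulas.txt", "w") as fh:
            for sp in sorted(result.karyotypes):
                k = result.karyotypes[sp]
                fh.write(f"{sp}: {k.formula} (shortened: {k.shortened_formula})\n")
        for sp, k in result.karyotypes.items():
            k.to_json(out / f"{sp}.karyotype.json")
        logger.info("bundle written to %s", out)
        return result
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
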