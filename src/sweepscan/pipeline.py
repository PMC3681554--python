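"""End-to-end pipeline: filter -> scan -> group -> validate -> annotate.

A :class:`PipelineConfig` (usually loaded from YAML) names the inputs and the
per-population scan parameters; :func:`run_pipeline` executes the stages in
order, writes every report to the output directory and records a JSON
manifest echoing all parameters, so a run is reproducible from its manifest
alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import io as sio
from .annotate import annotation_report, read_bed, read_gff3
from .genotype_model import (
    GenotypeMatrix,
    call_rate_filter,
    exclude_chromosomes,
    low_maf_fraction,
)
from .sweep_compare import (
    group_overlapping_regions,
    groups_to_frame,
    validate_across_assays,
    validation_to_frame,
)
from .sweep_scan import (
    HighDensityScanParams,
    LowDensityScanParams,
    SweepRegion,
    scan_high_density,
    scan_low_density,
)

logger = logging.getLogger("sweepscan")

ASSAY_PRESETS = {
    "50k-like": {"scan": "low", "params": LowDensityScanParams()},
    "hd-like": {"scan": "high", "params": HighDensityScanParams()},
}


class PipelineConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    genotypes: Path
    map_file: Optional[Path] = None  # required for PED input
    populations: Path
    assay_profile: Literal["50k-like", "hd-like"] = "50k-like"
    n_min: Optional[int] = None  # overrides the preset run length
    per_population_n_min: dict[str, int] = Field(default_factory=dict)
    span_min: Optional[int] = None
    maf_max: Optional[float] = None
    variable_fraction_max: Optional[float] = None
    max_contiguous_variable: Optional[int] = None
    call_rate_min: float = 0.85
    within_population_call_rate_min: Optional[float] = None
    exclude_chroms: list[str] = Field(default_factory=lambda: ["X"])
    x_removal_first: bool = True
    validation_regions: Optional[Path] = None
    annotation: Optional[Path] = None
    outdir: Path = Path("sweepscan_out")
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("genotypes", "populations")
    @classmethod
    def _must_exist(cls, v: Path) -> Path:
        if not Path(v).exists():
            raise ValueError(f"input file does not exist: {v}")
        return v

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def scan_params(self, population: str):
        preset = ASSAY_PRESETS[self.assay_profile]
        params = preset["params"]
        overrides = {}
        n = self.per_population_n_min.get(population, self.n_min)
        if n is not None:
            overrides["n_min"] = n
        if self.span_min is not None:
            overrides["span_min"] = self.span_min
        if preset["scan"] == "low" and self.maf_max is not None:
            overrides["maf_max"] = self.maf_max
        if preset["scan"] == "high":
            if self.variable_fraction_max is not None:
                overrides["variable_fraction_max"] = self.variable_fraction_max
            if self.max_contiguous_variable is not None:
                overrides["max_contiguous_variable"] = self.max_contiguous_variable
        from dataclasses import replace

        return preset["scan"], replace(params, **overrides)


class PipelineResult(BaseModel, arbitrary_types_allowed=True):
    manifest: dict
    regions: dict[str, list[SweepRegion]]
    outdir: Path


def _load_genotypes(config: PipelineConfig) -> GenotypeMatrix:
    suffix = Path(config.genotypes).suffix.lower()
    if suffix == ".vcf":
        return sio.read_vcf(config.genotypes)
    if suffix == ".ped":
        if config.map_file is None:
            raise ValueError("PED input requires map_file")
        return sio.read_ped_map(config.genotypes, config.map_file)
    raise ValueError(f"unrecognised genotype format: {config.genotypes}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write reports + manifest under ``config.outdir``."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        logger.info("parameters: %s", config.model_dump())
        matrix = _load_genotypes(config)
        panel = sio.read_population_tsv(config.populations)
        panel.validate_against(matrix)
        n_input = matrix.n_loci

        def drop_chroms(m: GenotypeMatrix) -> GenotypeMatrix:
            return exclude_chromosomes(m, config.exclude_chroms)

        if config.x_removal_first:
            matrix = drop_chroms(matrix)
        filt = call_rate_filter(
            matrix, panel, config.call_rate_min, config.within_population_call_rate_min
        )
        matrix = filt.matrix
        if not config.x_removal_first:
            matrix = drop_chroms(matrix)
        filt.report.to_csv(outdir / "removal_report.tsv", sep="\t", index=False)
        logger.info("loci: %d in, %d retained", n_input, matrix.n_loci)

        summary_rows = []
        regions: dict[str, list[SweepRegion]] = {}
        all_regions: list[SweepRegion] = []
        for pop in panel.populations:
            kind, params = config.scan_params(pop)
            mono = low_maf_fraction(matrix, panel, pop)
            scan = scan_low_density if kind == "low" else scan_high_density
            regs = scan(matrix, panel, pop, params)
            regions[pop] = regs
            all_regions.extend(regs)
            summary_rows.append(
                {
                    "population": pop,
                    "n_samples": len(panel.samples_for(pop)),
                    "monomorphic_fraction": mono.n_monomorphic / mono.n_loci,
                    "n_regions": len(regs),
                    "scan": kind,
                    "n_min": params.n_min,
                    "span_min": params.span_min,
                }
            )
            logger.info("%s: %d region(s)", pop, len(regs))
        import pandas as pd

        pd.DataFrame(summary_rows).to_csv(outdir / "panel_summary.tsv", sep="\t", index=False)
        sio.write_regions_tsv(all_regions, outdir / "regions.tsv")
        sio.write_regions_bed(all_regions, outdir / "regions.bed")

        groups = group_overlapping_regions(all_regions)
        groups_to_frame(groups).to_csv(outdir / "groups.tsv", sep="\t", index=False)

        outputs = [
            "removal_report.tsv", "panel_summary.tsv", "regions.tsv",
            "regions.bed", "groups.tsv",
        ]
        if config.validation_regions is not None:
            validation = sio.read_regions_tsv(config.validation_regions)
            results = validate_across_assays(all_regions, validation)
            validation_to_frame(results).to_csv(
                outdir / "validation.tsv", sep="\t", index=False
            )
            outputs.append("validation.tsv")
        if config.annotation is not None:
            apath = Path(config.annotation)
            features = (
                read_bed(apath) if apath.suffix.lower() == ".bed" else read_gff3(apath)
            )
            annotation_report(all_regions, features).to_csv(
                outdir / "annotation.tsv", sep="\t", index=False
            )
            outputs.append("annotation.tsv")

        manifest = {
            "parameters": json.loads(config.model_dump_json()),
            "n_loci_input": n_input,
            "n_loci_retained": matrix.n_loci,
            "n_samples": matrix.n_samples,
            "n_regions": {pop: len(r) for pop, r in regions.items()},
            "n_groups": len(groups),
            "outputs": outputs,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return PipelineResult(manifest=manifest, regions=regions, outdir=outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()
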