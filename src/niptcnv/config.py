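"""Structured run configuration, validated before any pipeline stage runs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from . import fragments, genome as genome_mod
from .detection import CallerParams
from .qc import QcConfig
from .simulate import CohortSpec


class GenomeConfig(BaseModel):
    preset: str = "mini"  # mini | hg19 | recovery, or explicit lengths
    chrom_lengths: dict[str, int] | None = None
    bin_size: int = Field(default=20_000, gt=0)
    gc_mean: float = 0.415
    gc_sd: float = Field(default=0.015, ge=0)
    seed: int = 0

    @field_validator("preset")
    @classmethod
    def _known_preset(cls, v: str) -> str:
        if v not in ("mini", "hg19", "recovery", "custom"):
            raise ValueError(f"unknown genome preset {v!r}")
        return v

    def build(self) -> genome_mod.GenomeModel:
        lengths = {
            "mini": genome_mod.MINI_GENOME_LENGTHS,
            "hg19": genome_mod.HG19_CHROM_LENGTHS,
            "recovery": genome_mod.RECOVERY_GENOME_LENGTHS,
            "custom": self.chrom_lengths,
        }[self.preset]
        if lengths is None:
            raise ValueError("custom genome preset requires chrom_lengths")
        return genome_mod.build_genome(lengths, bin_size=self.bin_size,
                                       gc_mean=self.gc_mean, gc_sd=self.gc_sd,
                                       seed=self.seed)


class CohortConfig(BaseModel):
    n_samples: int = Field(default=200, ge=0)
    cnv_prevalence: float = Field(default=0.005, ge=0, le=1)
    era_pre_fraction: float = Field(default=12_885 / 68_588, ge=0, le=1)
    placental_discordance: float = Field(default=0.40, ge=0, le=1)
    maternal_origin: float = Field(default=0.025, ge=0, le=1)
    ff_mode: str = "raw"  # the pipeline enriches post-era samples explicitly
    reads_mean: float = Field(default=3.9e6, gt=0)
    reads_sd: float = Field(default=2.5e5, ge=0)
    gc_bias_amplitude: float = 0.05

    def spec(self, seed: int) -> CohortSpec:
        return CohortSpec(n_samples=self.n_samples, seed=seed,
                          cnv_prevalence=self.cnv_prevalence,
                          era_pre_fraction=self.era_pre_fraction,
                          placental_discordance=self.placental_discordance,
                          maternal_origin=self.maternal_origin,
                          ff_mode=self.ff_mode,  # type: ignore[arg-type]
                          reads_mean=self.reads_mean, reads_sd=self.reads_sd,
                          gc_bias_amplitude=self.gc_bias_amplitude)


class EnrichmentConfig(BaseModel):
    threshold_bp: float = Field(default=230.0, gt=0)
    logistic_width: float = Field(default=0.0, ge=0)
    fetal_mono_mean: float = 143.0
    fetal_mono_sd: float = 20.0
    maternal_mono_mean: float = 166.0
    maternal_mono_sd: float = 20.0
    di_mean: float = 332.0
    di_sd: float = 30.0
    fetal_di_weight: float = Field(default=0.05, ge=0, le=1)
    maternal_di_weight: float = Field(default=0.33, ge=0, le=1)

    def model(self) -> fragments.FragmentLengthModel:
        return fragments.FragmentLengthModel(
            fetal=fragments.NucleosomeMixture(
                self.fetal_mono_mean, self.fetal_mono_sd, self.di_mean,
                self.di_sd, self.fetal_di_weight),
            maternal=fragments.NucleosomeMixture(
                self.maternal_mono_mean, self.maternal_mono_sd, self.di_mean,
                self.di_sd, self.maternal_di_weight))


class QcSection(BaseModel):
    min_read_length: float = 100.0
    min_q20: float = 0.50
    gc_low: float = 0.38
    gc_high: float = 0.45
    min_fetal_fraction: float = 0.04
    min_unique_reads: float = 3.5e6
    max_attempts: int = Field(default=3, ge=1)

    def qc_config(self) -> QcConfig:
        return QcConfig(self.min_read_length, self.min_q20,
                        (self.gc_low, self.gc_high), self.min_fetal_fraction,
                        self.min_unique_reads, self.max_attempts)


class CallerSection(BaseModel):
    min_bins: int = Field(default=25, ge=1)
    z_region: float = Field(default=5.0, gt=0)
    max_bins: int | None = None
    refine: bool = True
    refine_window: int = Field(default=50, ge=1)

    def params(self) -> CallerParams:
        return CallerParams(self.min_bins, self.z_region, self.max_bins,
                            self.refine, self.refine_window)


class EvalConfig(BaseModel):
    around_1mb_lo: float = 0.5  # "around 1 Mb" stratum, Mb
    around_1mb_hi: float = 1.5
    panel_size: int = Field(default=100, ge=2)


class RunConfig(BaseModel):
    """Top-level pipeline configuration; one global seed fans out to stages."""

    seed: int = Field(default=0, ge=0, lt=2**31)
    genome: GenomeConfig = GenomeConfig()
    cohort: CohortConfig = CohortConfig()
    enrichment: EnrichmentConfig = EnrichmentConfig()
    qc: QcSection = QcSection()
    caller: CallerSection = CallerSection()
    evaluation: EvalConfig = EvalConfig()

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def digest(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
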