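"""Run configuration: every tunable threshold of every pipeline stage.

All thresholds carry the study defaults and are overridable only through a
:class:`RunConfig` (loaded from YAML or built in code) — never hard-coded at
call sites.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is outside its documented domain."""


@dataclass
class RunConfig:
    """All tunable thresholds of the scat-DNA pipeline.

    Defaults reproduce the published protocol: 100%-identity species
    assignment with 2-of-3 replicate consensus and a 0.5% within-sample
    abundance floor for metabarcoding; read-count genotype calls with
    het-in-2-of-3 / hom-in-3-of-3 consensus, 20% per-sample missingness QC;
    PLINK-style locus filters (geno 0.1, maf 0.3, hwe 0.001, r^2 0.5,
    sample missingness 0.3); and the >=10-scats rule for individual diets.
    """

    # -- taxonomy assignment ------------------------------------------------
    species_identity: float = 100.0   # % identity required for species rank
    genus_identity: float = 99.0      # lower bound of the genus band
    family_identity: float = 90.0     # lower bound of the family band
    min_taxon_replicates: int = 2     # taxon must appear in >= this many PCR replicates
    abundance_threshold: float = 0.005  # drop taxa below this fraction of sample reads
    predator_taxa: tuple[str, ...] = ("Canis lupus", "Canis latrans")
    focal_predator: str = "Canis lupus"
    contaminant_taxa: tuple[str, ...] = ("Homo sapiens", "Bos taurus")

    # -- diet analysis ------------------------------------------------------
    min_scats: int = 10               # individual-diet inclusion rule
    items_mode: str = "categories"    # "categories" | "species": per-scat item multiplicity
    n_permutations: int = 999         # PERMANOVA label permutations

    # -- genotype calling ---------------------------------------------------
    min_depth: int = 10               # minimum reads to call a replicate
    hom_ratio: float = 0.9            # allele-read fraction >= this -> homozygote
    het_low: float = 0.3              # heterozygote band on the allele-1 fraction
    het_high: float = 0.7
    max_missing_fraction: float = 0.20  # sample QC: fail if missing loci fraction exceeds
    sex_min_depth: int = 10           # Y-marker depth to count a replicate as male-positive
    sex_min_replicates: int = 2       # Y-positive replicates needed to call male

    # -- individual matching ------------------------------------------------
    # min_shared_loci is the co-called floor implied by the 20% missingness QC
    # on a 35-locus panel: two passing samples always share >= 35 - 2*7 = 21
    max_mismatch: int = 1             # loci allowed to differ between matching samples
    min_shared_loci: int = 21         # co-called loci required to compare two samples

    # -- SNP-matrix filters -------------------------------------------------
    max_locus_missing: float = 0.1
    min_maf: float = 0.3
    hwe_alpha: float = 0.001
    ld_r2: float = 0.5
    max_sample_missing: float = 0.3

    # -- pedigree screening -------------------------------------------------
    max_oh: int = 1                   # opposing-homozygosity tolerance per candidate
    max_trio: int = 1                 # trio-incompatibility tolerance per parent pair

    # -- bookkeeping --------------------------------------------------------
    year_mode: str = "calendar"       # "calendar" | "biological" (year starts 1 May)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fractions = {
            "abundance_threshold": self.abundance_threshold,
            "max_missing_fraction": self.max_missing_fraction,
            "max_locus_missing": self.max_locus_missing,
            "min_maf": self.min_maf,
            "hwe_alpha": self.hwe_alpha,
            "ld_r2": self.ld_r2,
            "max_sample_missing": self.max_sample_missing,
            "hom_ratio": self.hom_ratio,
            "het_low": self.het_low,
            "het_high": self.het_high,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value!r} outside [0, 1]")
        for name, value in {
            "species_identity": self.species_identity,
            "genus_identity": self.genus_identity,
            "family_identity": self.family_identity,
        }.items():
            if not 0.0 <= value <= 100.0:
                raise ConfigError(f"{name}={value!r} outside [0, 100]")
        if not self.family_identity <= self.genus_identity <= self.species_identity:
            raise ConfigError("identity bands must be ordered family <= genus <= species")
        if self.het_low > self.het_high:
            raise ConfigError("het_low must not exceed het_high")
        if self.min_taxon_replicates not in (1, 2, 3):
            raise ConfigError("min_taxon_replicates must be in {1, 2, 3}")
        for name, value in {
            "min_scats": self.min_scats,
            "n_permutations": self.n_permutations,
            "min_depth": self.min_depth,
            "sex_min_depth": self.sex_min_depth,
            "sex_min_replicates": self.sex_min_replicates,
            "min_shared_loci": self.min_shared_loci,
        }.items():
            if int(value) != value or value < 1:
                raise ConfigError(f"{name}={value!r} must be a positive integer")
        for name, value in {"max_mismatch": self.max_mismatch,
                            "max_oh": self.max_oh,
                            "max_trio": self.max_trio,
                            "seed": self.seed}.items():
            if int(value) != value or value < 0:
                raise ConfigError(f"{name}={value!r} must be a non-negative integer")
        if self.items_mode not in ("categories", "species"):
            raise ConfigError("items_mode must be 'categories' or 'species'")
        if self.year_mode not in ("calendar", "biological"):
            raise ConfigError("year_mode must be 'calendar' or 'biological'")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["predator_taxa"] = list(self.predator_taxa)
        d["contaminant_taxa"] = list(self.contaminant_taxa)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("predator_taxa", "contaminant_taxa"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for run provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **changes: Any) -> "RunConfig":
        return dataclasses.replace(self, **changes)
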