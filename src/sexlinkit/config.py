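"""Simulation configuration and ground-truth records.

The :class:`SimConfig` defaults define the study conditions the rest of the
package assumes: a six-chromosome proxy genome (stand-ins for Ssa02, Ssa03,
Ssa05, Ssa06, Ssa12 and Ssa25), a 20 kb sdY-bearing contig whose male-specific
region (MSR) ends at base 13,333, three segregating male-heterogametic sex
lineages, and three populations (TAS/NA/EU) drifted apart under a
Balding-Nichols model.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

DEFAULT_CHROMS = ("Ssa02", "Ssa03", "Ssa05", "Ssa06", "Ssa12", "Ssa25")
SDY_CONTIG = "sdY_contig"
LINEAGES = ("SL-02", "SL-03", "SL-06")


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class HomeologPair:
    """A pair of non-syntenic duplicated intervals with residual correlation.

    Coordinates are 1-based inclusive.  ``rho`` is the per-individual
    probability that a mirrored site on the B side carries a copy of its
    partner's genotype rather than an independent draw.
    """

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    rho: float = 0.9

    def __post_init__(self) -> None:
        if self.chrom_a == self.chrom_b:
            raise ConfigError("homeolog intervals must lie on different chromosomes")
        if self.start_a < 1 or self.start_b < 1:
            raise ConfigError("homeolog interval coordinates are 1-based (>= 1)")
        if self.end_a < self.start_a or self.end_b < self.start_b:
            raise ConfigError("malformed homeolog interval")
        if (self.end_a - self.start_a) != (self.end_b - self.start_b):
            raise ConfigError("homeolog intervals must have equal length")
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigError("rho must lie in [0, 1]")

    def partner_position(self, pos: int) -> int:
        """Map a position in interval A to its mirror position in interval B."""
        if not self.start_a <= pos <= self.end_a:
            raise ValueError(f"position {pos} outside interval A")
        return self.start_b + (pos - self.start_a)


@dataclass(frozen=True)
class SdLocus:
    """A sex-determination anchor: the insertion site of the sdY cassette."""

    chrom: str
    pos: int
    proportion: float
    lineage: str


def _default_homeolog_pairs() -> list[HomeologPair]:
    # Ssa02 partners with both Ssa05 (its 2p half) and Ssa12 (its 2q half);
    # Ssa03 partners with Ssa06, matching the known duplicated-block layout.
    return [
        HomeologPair("Ssa02", 1, 250_000, "Ssa05", 250_001, 500_000),
        HomeologPair("Ssa02", 250_001, 500_000, "Ssa12", 1, 250_000),
        HomeologPair("Ssa03", 250_001, 500_000, "Ssa06", 1, 250_000),
    ]


def _default_sd_loci() -> list[SdLocus]:
    # The Ssa02 anchor sits at the boundary between its two homeolog blocks so
    # an association block around it straddles both and can leak to Ssa05 and
    # Ssa12.  The Ssa03/Ssa06 anchors sit outside any retained-tetrasomy block.
    return [
        SdLocus("Ssa02", 250_000, 0.50, "SL-02"),
        SdLocus("Ssa03", 100_000, 0.25, "SL-03"),
        SdLocus("Ssa06", 400_000, 0.25, "SL-06"),
    ]


@dataclass
class SimConfig:
    """All knobs of the synthetic-cohort generator (defaults = study conditions)."""

    # --- genome geometry -------------------------------------------------
    n_chromosomes: int = 6
    chrom_names: tuple[str, ...] = DEFAULT_CHROMS
    chrom_length_bp: int = 500_000
    sdy_contig_length_bp: int = 20_000
    msr_start: int = 2_001
    msr_end: int = 13_333  # MSR-MFCR junction on the sdY contig
    homeolog_pairs: list[HomeologPair] = field(default_factory=_default_homeolog_pairs)
    homeolog_mirror_fraction: float = 0.5

    # --- population model ------------------------------------------------
    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {"TAS": 20, "NA": 7, "EU": 13}
    )
    fst_drift: dict[str, float] = field(
        default_factory=lambda: {"TAS": 0.04, "NA": 0.04, "EU": 0.17}
    )
    snps_per_chrom: int = 2_200
    sd_loci: list[SdLocus] = field(default_factory=_default_sd_loci)
    sd_block_snps: int = 20
    sd_block_span_bp: int = 20_000
    sd_marker_freq_range: tuple[float, float] = (0.02, 0.10)
    psex_discordance_rate: float = 0.02
    n_dh_females: int = 4
    n_artifact_sites: int = 50

    # --- sequencing model ------------------------------------------------
    coverage_mean: float = 40.0
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    read_len: int = 150
    seq_error_rate: float = 0.003
    low_mq_fraction: float = 0.02
    n_seq_males: int = 6
    n_seq_females: int = 6
    background_window_bp: int = 20_000
    orphan_minority_fraction: float = 1.0 / 3.0
    female_msr_noise: float = 0.0

    # --- sdY-contig variation --------------------------------------------
    n_msr_snps: int = 22
    n_mfcr_snps: int = 20
    msr_divergent_fraction: float = 0.8
    msr_within_flip: float = 0.03
    n_outgroup_sites: int = 8
    n_outgroup_informative: int = 4

    # --- array model ------------------------------------------------------
    array_error_rate: float = 0.01
    n_array_sites: int = 3_000

    seed: int = 2018

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.chrom_names = tuple(self.chrom_names)
        self.homeolog_pairs = [
            hp if isinstance(hp, HomeologPair) else HomeologPair(**hp)
            for hp in self.homeolog_pairs
        ]
        self.sd_loci = [
            sl if isinstance(sl, SdLocus) else SdLocus(**sl) for sl in self.sd_loci
        ]
        self.validate()

    def validate(self) -> None:
        if self.n_chromosomes != len(self.chrom_names):
            raise ConfigError("n_chromosomes must match chrom_names")
        if len(set(self.chrom_names)) != self.n_chromosomes:
            raise ConfigError("duplicate chromosome names")
        if not (1 <= self.msr_start <= self.msr_end <= self.sdy_contig_length_bp):
            raise ConfigError("msr interval must fit within the sdY contig")
        if not self.sd_loci:
            raise ConfigError("at least one sex-determination locus is required")
        if self.sd_loci:
            total = sum(sl.proportion for sl in self.sd_loci)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError("sex-lineage proportions must sum to 1")
            for sl in self.sd_loci:
                if sl.chrom not in self.chrom_names:
                    raise ConfigError(f"sd locus on unknown chromosome {sl.chrom}")
                if not 1 <= sl.pos <= self.chrom_length_bp:
                    raise ConfigError("sd locus position outside chromosome")
        for name, rate in [
            ("psex_discordance_rate", self.psex_discordance_rate),
            ("seq_error_rate", self.seq_error_rate),
            ("array_error_rate", self.array_error_rate),
            ("homeolog_mirror_fraction", self.homeolog_mirror_fraction),
            ("low_mq_fraction", self.low_mq_fraction),
            ("msr_divergent_fraction", self.msr_divergent_fraction),
            ("msr_within_flip", self.msr_within_flip),
            ("orphan_minority_fraction", self.orphan_minority_fraction),
            ("female_msr_noise", self.female_msr_noise),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for hp in self.homeolog_pairs:
            for chrom in (hp.chrom_a, hp.chrom_b):
                if chrom not in self.chrom_names:
                    raise ConfigError(f"homeolog interval on unknown chromosome {chrom}")
        if self.coverage_mean <= 0 or self.insert_mean <= 0 or self.read_len <= 0:
            raise ConfigError("coverage, insert length and read length must be positive")
        if self.n_outgroup_informative > self.n_outgroup_sites:
            raise ConfigError("informative outgroup sites cannot exceed total")
        if self.n_outgroup_sites > self.n_msr_snps:
            raise ConfigError("outgroup sites cannot exceed MSR SNP count")

    # ------------------------------------------------------------------
    @property
    def msr_interval(self) -> tuple[int, int]:
        return (self.msr_start, self.msr_end)

    @property
    def contig_lengths(self) -> dict[str, int]:
        lengths = {name: self.chrom_length_bp for name in self.chrom_names}
        lengths[SDY_CONTIG] = self.sdy_contig_length_bp
        return lengths

    def homeolog_partner(self, chrom: str) -> str | None:
        """First homeolog partner chromosome of ``chrom``, if any."""
        for hp in self.homeolog_pairs:
            if hp.chrom_a == chrom:
                return hp.chrom_b
            if hp.chrom_b == chrom:
                return hp.chrom_a
        return None

    # --- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chrom_names"] = list(self.chrom_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "chrom_names" in d:
            d["chrom_names"] = tuple(d["chrom_names"])
        if "sd_marker_freq_range" in d:
            d["sd_marker_freq_range"] = tuple(d["sd_marker_freq_range"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ----------------------------------------------------------------------
_TRUTH_REQUIRED = (
    "junction_pos",
    "lineage_by_male",
    "true_sd_loci",
    "artifact_sites",
    "homeolog_pairs",
    "gsex",
    "psex",
)


@dataclass
class TruthRecord:
    """Generator ground truth used by parameter-recovery tests."""

    junction_pos: int
    lineage_by_male: dict[str, str]
    true_sd_loci: list[tuple[str, int]]
    artifact_sites: list[tuple[str, int]]
    homeolog_pairs: list[HomeologPair]
    gsex: dict[str, str]
    psex: dict[str, str]
    dh_samples: list[str] = field(default_factory=list)
    seq_males: list[str] = field(default_factory=list)
    seq_females: list[str] = field(default_factory=list)
    msr_sites: list[int] = field(default_factory=list)
    haplogroup_by_male: dict[str, str] = field(default_factory=dict)
    ancestral_haplogroup: str = ""

    def __post_init__(self) -> None:
        males = {a for a, s in self.gsex.items() if s == "male"}
        missing = males - set(self.lineage_by_male)
        if missing:
            raise ConfigError(f"males without a lineage: {sorted(missing)[:3]}")
        bad = set(self.lineage_by_male.values()) - set(LINEAGES)
        if bad:
            raise ConfigError(f"unknown lineage labels: {sorted(bad)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_sd_loci"] = [list(t) for t in self.true_sd_loci]
        d["artifact_sites"] = [list(t) for t in self.artifact_sites]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        missing = [k for k in _TRUTH_REQUIRED if k not in d]
        if missing:
            raise ConfigError(f"truth record missing fields: {missing}")
        d = dict(d)
        d["true_sd_loci"] = [tuple(t) for t in d["true_sd_loci"]]
        d["artifact_sites"] = [tuple(t) for t in d["artifact_sites"]]
        d["homeolog_pairs"] = [
            hp if isinstance(hp, HomeologPair) else HomeologPair(**hp)
            for hp in d["homeolog_pairs"]
        ]
        return cls(**d)


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    """Serialize a truth record to JSON (lossless round-trip)."""
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_truth(path: str | Path) -> TruthRecord:
    return TruthRecord.from_dict(json.loads(Path(path).read_text()))
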