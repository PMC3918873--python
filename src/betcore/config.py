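"""Configuration dataclasses for the simulation and analysis stages.

Every numeric constant of the analysis (detection threshold, FDR, fold-change
gate, MAPQ cutoff, fragment length, TSS flank, enhancer assignment window)
lives in :class:`PipelineConfig`; the three simulator configs hold the planted
experimental designs. All configs are frozen and hashable so a (config, seed)
pair pins an output bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


class GenerationError(RuntimeError):
    """Raised when a simulator cannot realize a configuration (e.g. regions
    overflowing chromosome bounds)."""


DEFAULT_CELL_LINES = ("OCI-AML3", "MV4-11", "MOLM13", "SKM1")


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of the multi-cell-line treated-vs-vehicle expression experiment.

    A ``core_block_size``-gene block is downregulated by ``core_log2fc`` in the
    treated arm of *every* cell line; each line additionally gets
    ``private_de_per_line`` genes perturbed in that line only (random sign).
    """

    n_cell_lines: int = 4
    replicates_per_arm: int = 3
    n_genes: int = 10_000
    core_block_size: int = 26
    core_log2fc: float = -2.0
    core_sd: float = 0.25
    private_de_per_line: int = 300
    null_sd: float = 0.25
    undetected_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cell_lines": self.n_cell_lines,
            "replicates_per_arm": self.replicates_per_arm,
            "n_genes": self.n_genes,
            "core_block_size": self.core_block_size,
            "private_de_per_line": self.private_de_per_line,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if self.core_block_size > self.n_genes:
            raise ConfigError(
                f"core_block_size ({self.core_block_size}) exceeds n_genes ({self.n_genes})"
            )
        if not 0.0 <= self.undetected_fraction <= 1.0:
            raise ConfigError("undetected_fraction must lie in [0, 1]")
        if self.null_sd < 0 or self.core_sd < 0:
            raise ConfigError("standard deviations must be non-negative")

    @property
    def cell_lines(self) -> tuple[str, ...]:
        names = list(DEFAULT_CELL_LINES[: self.n_cell_lines])
        for i in range(len(names), self.n_cell_lines):
            names.append(f"LINE{i + 1}")
        return tuple(names)


@dataclass(frozen=True)
class ChipConfig:
    """Design of the two-condition ChIP-seq simulation over a toy genome.

    Enhancer signal weights are heavy-tailed (exponential); a ``n_super``
    subset carries ``super_multiplier``-scaled signal, and exactly
    ``core_genes_with_se`` planted core genes get a super-enhancer within the
    assignment window of their TSS. Treated-condition reads at super-enhancers
    are binomially thinned to ``ibet_se_depletion`` of the vehicle rate.
    """

    genome: tuple[tuple[str, int], ...] = (("chr1", 10_000_000), ("chr2", 14_000_000))
    n_enhancers: int = 500
    n_super: int = 30
    core_genes_with_se: int = 12
    typical_rpm_scale: float = 100.0
    super_multiplier: float = 20.0
    library_size_per_condition: int = 2_000_000
    fragment_len: int = 300
    read_len: int = 36
    ibet_se_depletion: float = 0.3
    background_fraction_min: float = 0.05
    n_other_genes: int = 200
    seed: int = 0

    def validate(self) -> None:
        if not self.genome:
            raise ConfigError("genome must contain at least one chromosome")
        for chrom, length in self.genome:
            if length <= 0:
                raise ConfigError(f"chromosome {chrom} has non-positive length")
        if self.n_super > self.n_enhancers:
            raise ConfigError("n_super cannot exceed n_enhancers")
        for name in ("n_enhancers", "n_super", "core_genes_with_se",
                     "library_size_per_condition", "n_other_genes"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 < self.ibet_se_depletion <= 1.0:
            raise ConfigError("ibet_se_depletion must lie in (0, 1]")
        if self.fragment_len < self.read_len:
            raise ConfigError("fragment_len must be >= read_len")

    @property
    def genome_dict(self) -> dict[str, int]:
        return dict(self.genome)


def default_label_schemes(n_archetypes: int) -> dict[str, dict[str, tuple[float, ...]]]:
    """Per-archetype categorical label distributions for the synthetic cohort.

    Mimics clinical annotation of an AML series: a multi-level karyotype class
    plus binary mutation statuses, each skewed by archetype so that
    group-by-factor association tests have planted signal.
    """
    karyo_levels = ["NK", "MLL", "CBF", "+8", "OtherHR", "Other"]
    k = n_archetypes
    schemes: dict[str, dict[str, tuple[float, ...]]] = {"karyotype": {}, "NPM1c": {}, "FLT3_ITD": {}}
    n_lev = len(karyo_levels)
    for a in range(k):
        probs = [0.4 / (n_lev - 1)] * n_lev
        probs[a % n_lev] = 0.6
        schemes["karyotype"][f"A{a}"] = tuple(p / sum(probs) for p in probs)
        p_npm1 = 0.15 + 0.6 * (a % k) / max(k - 1, 1)
        schemes["NPM1c"][f"A{a}"] = (p_npm1, 1.0 - p_npm1)
        p_flt3 = 0.6 - 0.4 * (a % k) / max(k - 1, 1)
        schemes["FLT3_ITD"][f"A{a}"] = (p_flt3, 1.0 - p_flt3)
    return schemes


LABEL_LEVELS = {
    "karyotype": ("NK", "MLL", "CBF", "+8", "OtherHR", "Other"),
    "NPM1c": ("mut", "wt"),
    "FLT3_ITD": ("mut", "wt"),
}


@dataclass(frozen=True)
class CohortConfig:
    """Design of the synthetic patient cohort measured on the signature genes."""

    n_patients: int = 436
    n_signature_genes: int = 18
    n_archetypes: int = 6
    archetype_separation: float = 3.0
    within_sd: float = 1.0
    label_schemes: Any = None  # None -> default_label_schemes(n_archetypes)
    seed: int = 0

    def validate(self) -> None:
        if self.n_archetypes < 1:
            raise ConfigError("n_archetypes must be >= 1")
        if self.n_patients < self.n_archetypes:
            raise ConfigError("n_patients must be >= n_archetypes")
        if self.n_signature_genes < 1:
            raise ConfigError("n_signature_genes must be >= 1")
        if self.within_sd < 0 or self.archetype_separation < 0:
            raise ConfigError("scale parameters must be non-negative")
        for factor, per_arch in self.resolved_label_schemes().items():
            for arch, probs in per_arch.items():
                if abs(sum(probs) - 1.0) > 1e-8:
                    raise ConfigError(
                        f"label probabilities for {factor}/{arch} sum to {sum(probs)}, not 1"
                    )

    def resolved_label_schemes(self) -> dict:
        if self.label_schemes is None:
            return default_label_schemes(self.n_archetypes)
        return self.label_schemes


@dataclass(frozen=True)
class PipelineConfig:
    """Every stated numeric threshold of the analysis, in one place."""

    detection_alpha: float = 0.01
    fdr_threshold: float = 0.05
    fc_threshold: float = 2.0
    cluster_cutoff: float = 10.0
    mapq_min: int = 10
    fragment_len: int = 300
    tss_flank: int = 5_000
    assign_window: int = 50_000
    coverage_binsize: int = 100
    n_patient_groups: int = 6

    def validate(self) -> None:
        for name in ("detection_alpha", "fdr_threshold", "fc_threshold", "cluster_cutoff",
                     "fragment_len", "tss_flank", "assign_window", "coverage_binsize"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.mapq_min < 0:
            raise ConfigError("mapq_min must be >= 0")


_CONFIG_SECTIONS = {
    "expression": ExperimentConfig,
    "chip": ChipConfig,
    "cohort": CohortConfig,
    "pipeline": PipelineConfig,
}


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline run: the three simulator designs, the analysis thresholds,
    a master seed, and the output directory. Round-trips through JSON/YAML."""

    expression: ExperimentConfig = field(default_factory=ExperimentConfig)
    chip: ChipConfig = field(default_factory=ChipConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0
    outdir: str = "betcore_run"

    def validate(self) -> None:
        self.expression.validate()
        self.chip.validate()
        self.cohort.validate()
        self.pipeline.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chip"]["genome"] = [list(pair) for pair in self.chip.genome]
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known_top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known_top
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key in _CONFIG_SECTIONS:
                section_cls = _CONFIG_SECTIONS[key]
                names = {f.name for f in dataclasses.fields(section_cls)}
                bad = set(value) - names
                if bad:
                    raise ConfigError(f"unknown keys in '{key}': {sorted(bad)}")
                value = dict(value)
                if key == "chip" and "genome" in value:
                    value["genome"] = tuple((str(c), int(l)) for c, l in value["genome"])
                kwargs[key] = section_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
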