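"""Simulation configuration: the study conditions of the synthetic experiment."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .models import ALL_CLASSES, ALL_SAMPLES


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _default_class_proportions() -> dict[str, float]:
    # A detected-cytoplasmic minority, sizeable nuclear-specific and
    # undetected majorities, mirroring how sparse cytoplasmic detection is
    # for lncRNAs in a single cell line.
    return {
        "free_cytoplasmic": 0.10,
        "light_polysomal": 0.20,
        "heavy_polysomal": 0.02,
        "nuclear_specific": 0.28,
        "not_present": 0.40,
    }


def _default_mass_factors() -> dict[str, float]:
    # Relative starting RNA masses of the pooled gradient fractions; equal
    # amounts are hybridized, so measured concentrations must be corrected
    # back by these factors.
    return {"free": 5.0, "light": 2.0, "heavy": 1.0, "input": 8.0}


def _default_te_rates() -> dict[str, dict[str, float] | float]:
    # Per-transcript probability of carrying an insertion of each repeat
    # class. ERVL-MaLR is planted twice as often in free cytoplasmic
    # transcripts as elsewhere; Alu and L1 are class-independent.
    ervl = {c: 0.2 for c in ALL_CLASSES}
    ervl["free_cytoplasmic"] = 0.4
    return {"ERVL-MaLR": ervl, "Alu": 0.35, "L1": 0.25}


def _default_capped_probs() -> dict[str, float]:
    # Light-polysomal transcripts are most often capped; capping promotes
    # 40S scanning and hence ribosomal recruitment.
    return {
        "free_cytoplasmic": 0.35,
        "light_polysomal": 0.85,
        "heavy_polysomal": 0.85,
        "nuclear_specific": 0.5,
        "not_present": 0.5,
    }


def _default_spike_levels() -> list[float]:
    # Eight ten-fold dilution levels (linear concentration units).
    return [10.0 ** k for k in range(8)]


def _default_utr_means() -> dict[str, float]:
    # Mean pseudo-5'UTR length (nt) per class: polysomal transcripts carry
    # longer, more mRNA-like 5' leaders.
    return {
        "free_cytoplasmic": 30.0,
        "light_polysomal": 90.0,
        "heavy_polysomal": 90.0,
        "nuclear_specific": 50.0,
        "not_present": 50.0,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic polysome-profiling microarray experiment.

    Defaults describe one realistic study: a few hundred lncRNA genes probed
    at 4 probes per transcript across four samples (free cytoplasmic, light
    polysomal, heavy polysomal, total cytoplasmic input), calibrated against
    an 8-level ten-fold spike-in dilution series, with multiplicative
    lognormal intensity noise and a hard low-intensity floor.
    """

    n_lncrna_genes: int = 300
    n_coding_genes: int = 60
    transcripts_per_gene_max: int = 3
    probes_per_transcript: int = 4
    spike_levels: list[float] = field(default_factory=_default_spike_levels)
    spike_probes_per_level: int = 4
    noise_sd_log10: float = 0.1
    floor_intensity: float = 1e-3
    gain: float = 100.0
    slope: float = 1.0
    mass_factors: dict[str, float] = field(default_factory=_default_mass_factors)
    class_proportions: dict[str, float] = field(default_factory=_default_class_proportions)
    te_insertion_rates: dict = field(default_factory=_default_te_rates)
    seed: int = 0

    # Concentration model: the maximal fraction of a cytoplasmic transcript is
    # drawn lognormally around 10**mean_log10_conc; the other two fractions sit
    # at least class_separation-fold below it.
    mean_log10_conc: float = 2.5
    sd_log10_conc: float = 0.7
    class_separation: float = 2.0

    # Annotation geometry.
    exons_per_transcript_max: int = 5
    mean_exon_length: int = 300
    intergenic_gap: int = 20000
    positional_conflict_rate: float = 0.05
    coding_evidence_rate: float = 0.05

    # 5' features.
    pseudo_utr_mean_by_class: dict[str, float] = field(default_factory=_default_utr_means)
    capped_prob_by_class: dict[str, float] = field(default_factory=_default_capped_probs)
    cage_tags_capped: float = 30.0
    cage_tags_uncapped: float = 2.0

    # qPCR / stability assay.
    n_qpcr_transcripts: int = 14
    qpcr_noise_sd_ct: float = 0.1
    n_stability_genes: int = 8
    n_bio_replicates: int = 3
    n_tech_replicates: int = 2
    base_half_life_h: float = 4.0
    drug_stabilization_factor: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_lncrna_genes < 0 or self.n_coding_genes < 0:
            raise ConfigurationError("gene counts must be nonnegative")
        if self.probes_per_transcript < 1 or self.transcripts_per_gene_max < 1:
            raise ConfigurationError("per-gene/transcript counts must be >= 1")
        if self.noise_sd_log10 < 0:
            raise ConfigurationError("noise_sd_log10 must be nonnegative")
        if self.floor_intensity <= 0:
            raise ConfigurationError("floor_intensity must be positive")
        levels = list(self.spike_levels)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ConfigurationError("spike_levels must be strictly increasing")
        if any(v <= 0 for v in levels):
            raise ConfigurationError("spike_levels must be positive")
        for name, mf in self.mass_factors.items():
            if name not in ALL_SAMPLES:
                raise ConfigurationError(f"unknown sample label {name!r}")
            if mf <= 0:
                raise ConfigurationError("mass factors must be positive")
        missing = set(ALL_SAMPLES) - set(self.mass_factors)
        if missing:
            raise ConfigurationError(f"mass_factors missing samples: {sorted(missing)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_proportions sum to {total}, not 1")
        for cls in self.class_proportions:
            if cls not in ALL_CLASSES:
                raise ConfigurationError(f"unknown localization class {cls!r}")
        for te_class, rates in self.te_insertion_rates.items():
            values = rates.values() if isinstance(rates, dict) else [rates]
            if any(not (0.0 <= r <= 1.0) for r in values):
                raise ConfigurationError(f"te_insertion_rates[{te_class!r}] outside [0,1]")
        if not (0.0 <= self.positional_conflict_rate <= 1.0):
            raise ConfigurationError("positional_conflict_rate outside [0,1]")
        if not (0.0 <= self.coding_evidence_rate <= 1.0):
            raise ConfigurationError("coding_evidence_rate outside [0,1]")

    def te_rate(self, te_class: str, localization_class: str) -> float:
        rates = self.te_insertion_rates[te_class]
        if isinstance(rates, dict):
            return float(rates.get(localization_class, 0.0))
        return float(rates)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
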