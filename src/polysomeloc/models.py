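"""Shared domain containers.

Coordinates are 0-based half-open everywhere in memory; GTF serialization
converts to the 1-based closed convention at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Cytoplasmic polysome-profiling samples, ordered light to heavy, plus the
#: unfractionated cytoplasmic input hybridized alongside them.
CYTOPLASMIC_SAMPLES = ("free", "light", "heavy")
ALL_SAMPLES = CYTOPLASMIC_SAMPLES + ("input",)

#: Localization classes assigned from maximal fraction signal.
CYTOPLASMIC_CLASSES = ("free_cytoplasmic", "light_polysomal", "heavy_polysomal")
ALL_CLASSES = CYTOPLASMIC_CLASSES + ("nuclear_specific", "not_present")

#: Maps each cytoplasmic class to the sample where its signal peaks.
CLASS_TO_SAMPLE = {
    "free_cytoplasmic": "free",
    "light_polysomal": "light",
    "heavy_polysomal": "heavy",
}
SAMPLE_TO_CLASS = {v: k for k, v in CLASS_TO_SAMPLE.items()}


@dataclass(frozen=True)
class TranscriptModel:
    """Genomic structure of one transcript; the unit of all interval analyses.

    ``exons`` are sorted, non-overlapping, half-open ``(start, end)`` intervals
    on the genome. ``biotype`` is one of ``lncRNA``, ``protein_coding``,
    ``pseudogene``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "lncRNA"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"empty exon ({start}, {end}) in {self.transcript_id}")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"exons overlap or unsorted in {self.transcript_id}")
            prev_end = end
        if not self.exons:
            raise ValueError(f"{self.transcript_id} has no exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Mature (spliced) transcript length in nt."""
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware genomic position)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker-style repetitive element annotation."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str
    repeat_family: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("repeat interval is empty")


@dataclass
class ProbePanel:
    """Probe-level intensity matrix with spike-in design and sample metadata.

    ``probes``: DataFrame indexed by probe_id with columns ``target_id``,
    ``is_spike`` (bool) and ``spike_concentration`` (linear units; NaN for
    non-spike probes).
    ``intensities``: DataFrame probe_id x sample of linear intensities.
    ``samples``: DataFrame indexed by sample label with a ``mass_factor``
    column (relative starting RNA mass of the pool each sample came from).
    """

    probes: pd.DataFrame
    intensities: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.probes.index.equals(self.intensities.index):
            raise ValueError("probes and intensities indexed by different probes")
        missing = set(self.intensities.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        spikes = self.probes["is_spike"]
        if (self.probes.loc[spikes, "spike_concentration"] <= 0).any():
            raise ValueError("spike probes must have positive spike_concentration")

    @property
    def spike_probes(self) -> pd.DataFrame:
        return self.probes[self.probes["is_spike"]]

    def copy(self) -> "ProbePanel":
        return ProbePanel(self.probes.copy(), self.intensities.copy(), self.samples.copy())


@dataclass(frozen=True)
class CalibrationModel:
    """Per-sample spike-in calibration: log10(I) = slope * log10(C) + intercept.

    ``detection_threshold`` is the intensity below which the spike signal to
    concentration relation ceases to be linear; probes at or below it are
    treated as undetected. ``r`` is the Pearson correlation of the fit,
    computed on the spike levels above the threshold only.
    """

    sample: str
    slope: float
    intercept: float
    detection_threshold: float
    r: float
    n_levels_used: int

    def to_log10_concentration(self, intensity, mass_factor: float = 1.0):
        """Invert the calibration; caller is responsible for thresholding."""
        import numpy as np

        return (np.log10(intensity) - self.intercept) / self.slope + np.log10(mass_factor)


@dataclass
class TruthTable:
    """Synthetic ground truth enabling recovery tests.

    ``transcripts``: DataFrame indexed by transcript_id with columns gene_id,
    biotype, true_class, conc_free, conc_light, conc_heavy (linear units),
    capped (bool), pseudo_utr_len (nt; -1 when no ORF was planted),
    nuclear_rpkm, nuclear_idr.
    ``te_insertions``: DataFrame with columns transcript_id, te_class, length.
    """

    transcripts: pd.DataFrame
    te_insertions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["transcript_id", "te_class", "length"]))

    def __post_init__(self) -> None:
        conc = self.transcripts[["conc_free", "conc_light", "conc_heavy"]]
        if (conc.to_numpy() < 0).any():
            raise ValueError("true concentrations must be nonnegative")
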