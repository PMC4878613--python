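import numpy as np
import pandas as pd
import pytest

from polysomeloc.config import SimulationConfig
from polysomeloc.models import ProbePanel, TranscriptModel


@pytest.fixture
def tiny_config():
    """Small but complete study configuration for fast end-to-end runs."""
    return SimulationConfig(
        n_lncrna_genes=60,
        n_coding_genes=15,
        transcripts_per_gene_max=2,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_transcript(tid="tx1", gene="g1", chrom="chr1", strand="+",
                    exons=((0, 100),), biotype="lncRNA"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
        exons=tuple(exons), biotype=biotype,
    )


def make_panel(intensities: dict, spike_concentrations: dict | None = None,
               targets: dict | None = None, mass_factors: dict | None = None):
    """Assemble a ProbePanel from plain dicts.

    ``intensities``: probe_id -> {sample: value}; ``spike_concentrations``:
    probe_id -> linear concentration for spike probes.
    """
    spike_concentrations = spike_concentrations or {}
    targets = targets or {}
    probe_ids = list(intensities)
    samples = sorted({s for v in intensities.values() for s in v})
    probes = pd.DataFrame(
        {
            "target_id": [targets.get(p, p) for p in probe_ids],
            "is_spike": [p in spike_concentrations for p in probe_ids],
            "spike_concentration": [spike_concentrations.get(p, np.nan) for p in probe_ids],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    inten = pd.DataFrame(
        [[intensities[p][s] for s in samples] for p in probe_ids],
        index=probes.index,
        columns=samples,
    )
    mass_factors = mass_factors or {s: 1.0 for s in samples}
    meta = pd.DataFrame(
        {"mass_factor": [mass_factors[s] for s in samples]},
        index=pd.Index(samples, name="sample"),
    )
    return ProbePanel(probes=probes, intensities=inten, samples=meta)


def spike_panel(level_intensities: dict[float, dict[str, float]],
                probes_per_level: int = 1, mass_factors=None):
    """Panel holding only spike probes at the given per-level intensities."""
    intensities = {}
    spikes = {}
    for li, (conc, per_sample) in enumerate(sorted(level_intensities.items())):
        for p in range(probes_per_level):
            pid = f"S{li}_{p}"
            intensities[pid] = per_sample
            spikes[pid] = conc
    return make_panel(intensities, spikes, mass_factors=mass_factors)
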