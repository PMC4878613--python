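"""Synthetic polysome-profiling experiment with known ground truth.

Emulates the statistical structure of a spike-in calibrated microarray study
of cytoplasmic lncRNA localization: four samples (free cytoplasmic, light
polysomal, heavy polysomal, total cytoplasmic input) probed at 4 probes per
transcript, a spike-in dilution series sharing the arrays' multiplicative
lognormal noise and hard intensity floor, per-sample starting-RNA mass
factors, planted first ORFs / pseudo-5'UTRs, class-dependent transposable
element insertions, CAGE tags on capped transcripts, and qPCR Ct tables for
pool percentages and drug-block stability time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import ConfigurationError, SimulationConfig
from .models import (
    ALL_SAMPLES,
    CLASS_TO_SAMPLE,
    CYTOPLASMIC_CLASSES,
    ProbePanel,
    RepeatFeature,
    TranscriptModel,
    TruthTable,
)

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

# mRNAs skew to the heavy fraction: they are actively translated.
_CODING_CLASS_PROPORTIONS = {
    "free_cytoplasmic": 0.25,
    "light_polysomal": 0.45,
    "heavy_polysomal": 0.30,
}


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-stream generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Ground truth


def generate_truth(config: SimulationConfig) -> TruthTable:
    """Draw per-transcript localization classes, fraction concentrations and
    planted 5'/TE features."""
    rng = _child_rng(config.seed, 0)
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])

    rows = []
    te_rows = []

    def add_gene(gene_id: str, biotype: str, cls: str, n_tx: int) -> None:
        for t in range(n_tx):
            tid = f"{gene_id}.{t + 1}"
            conc = {"free": 0.0, "light": 0.0, "heavy": 0.0}
            if cls in CYTOPLASMIC_CLASSES:
                peak = CLASS_TO_SAMPLE[cls]
                top = 10.0 ** rng.normal(config.mean_log10_conc, config.sd_log10_conc)
                conc[peak] = top
                for other in ("free", "light", "heavy"):
                    if other != peak:
                        conc[other] = top / (
                            config.class_separation * 10.0 ** rng.uniform(0.0, 0.6)
                        )
            if cls == "nuclear_specific":
                nuclear_rpkm = 10.0 ** rng.normal(0.5, 0.5)
                nuclear_idr = rng.uniform(0.0, 0.1)
            elif cls == "not_present":
                nuclear_rpkm = 0.0
                nuclear_idr = 1.0
            else:
                nuclear_rpkm = 10.0 ** rng.normal(0.0, 0.5)
                nuclear_idr = rng.uniform(0.0, 0.1)
            capped = bool(rng.random() < config.capped_prob_by_class[cls])
            utr_mean = config.pseudo_utr_mean_by_class[cls]
            pseudo_utr = int(rng.exponential(utr_mean))
            rows.append(
                {
                    "transcript_id": tid,
                    "gene_id": gene_id,
                    "biotype": biotype,
                    "true_class": cls,
                    "conc_free": conc["free"],
                    "conc_light": conc["light"],
                    "conc_heavy": conc["heavy"],
                    "capped": capped,
                    "pseudo_utr_len": pseudo_utr,
                    "nuclear_rpkm": nuclear_rpkm,
                    "nuclear_idr": nuclear_idr,
                }
            )
            for te_class in config.te_insertion_rates:
                if rng.random() < config.te_rate(te_class, cls):
                    te_rows.append(
                        {
                            "transcript_id": tid,
                            "te_class": te_class,
                            "length": int(rng.integers(80, 300)),
                        }
                    )

    for g in range(config.n_lncrna_genes):
        cls = classes[rng.choice(len(classes), p=probs)]
        n_tx = int(rng.integers(1, config.transcripts_per_gene_max + 1))
        add_gene(f"LNCG{g + 1:05d}", "lncRNA", cls, n_tx)

    coding_classes = list(_CODING_CLASS_PROPORTIONS)
    coding_probs = np.array(list(_CODING_CLASS_PROPORTIONS.values()))
    for g in range(config.n_coding_genes):
        cls = coding_classes[rng.choice(len(coding_classes), p=coding_probs)]
        add_gene(f"PCG{g + 1:05d}", "protein_coding", cls, 1)

    transcripts = pd.DataFrame(rows).set_index("transcript_id")
    te = pd.DataFrame(te_rows, columns=["transcript_id", "te_class", "length"])
    return TruthTable(transcripts=transcripts, te_insertions=te)


# ---------------------------------------------------------------------------
# Annotation + sequences + repeats + CAGE


@dataclass
class AnnotationBundle:
    """Everything the pipeline reads, plus the truth it was generated from."""

    transcripts: list[TranscriptModel]
    sequences: dict[str, str]
    repeats: list[RepeatFeature]
    cage_tags: pd.DataFrame
    coding_evidence: pd.DataFrame
    truth: TruthTable

    def transcript_map(self) -> dict[str, TranscriptModel]:
        return {tx.transcript_id: tx for tx in self.transcripts}

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": outdir / "annotation.gtf",
            "fasta": outdir / "transcripts.fa",
            "repeats": outdir / "repeats.bed",
            "cage": outdir / "cage_tags.bed",
            "evidence": outdir / "coding_evidence.tsv",
            "truth": outdir / "truth.tsv",
            "truth_te": outdir / "truth_te.tsv",
        }
        io.write_gtf(self.transcripts, paths["gtf"])
        io.write_fasta(self.sequences, paths["fasta"])
        io.write_repeats_bed(self.repeats, paths["repeats"])
        io.write_cage_bed(self.cage_tags, paths["cage"])
        self.coding_evidence.to_csv(paths["evidence"], sep="\t", index=False, float_format="%.6g")
        self.truth.transcripts.reset_index().to_csv(
            paths["truth"], sep="\t", index=False, float_format="%.10g"
        )
        self.truth.te_insertions.to_csv(paths["truth_te"], sep="\t", index=False)
        return {k: str(v) for k, v in paths.items()}


def _plant_first_orf(seq: np.ndarray, offset: int, rng: np.random.Generator) -> int:
    """Make ``offset`` the start of the transcript's 5'-most forward ORF.

    Erases every upstream AUG (so no upstream ORF can exist), writes AUG at
    the offset and an in-frame stop downstream with no intervening in-frame
    stop. Returns the offset actually used (clipped to leave room).
    """
    n = len(seq)
    offset = max(0, min(offset, n - 6))
    s = seq  # mutate in place
    # Remove AUGs upstream of the planted start. Replacing G with C can never
    # create a new AUG, so one left-to-right pass suffices.
    for i in range(0, min(offset, n - 2)):
        if s[i] == "A" and s[i + 1] == "T" and s[i + 2] == "G":
            s[i + 2] = "C"
    s[offset], s[offset + 1], s[offset + 2] = "A", "T", "G"
    max_codons = (n - offset - 6) // 3
    n_codons = min(int(rng.integers(5, 41)), max_codons)
    stop_at = offset + 3 + 3 * n_codons
    # Clear in-frame stops inside the ORF body, then write the terminator.
    for i in range(offset + 3, stop_at, 3):
        if "".join(s[i : i + 3]) in _STOPS:
            s[i] = "C"
    s[stop_at], s[stop_at + 1], s[stop_at + 2] = "T", "A", "A"
    return offset


def _gene_structure(
    rng: np.random.Generator, config: SimulationConfig, start: int
) -> tuple[tuple[int, int], ...]:
    n_exons = int(rng.integers(1, config.exons_per_transcript_max + 1))
    exons = []
    pos = start
    for _ in range(n_exons):
        length = int(rng.integers(max(60, config.mean_exon_length // 2),
                                  2 * config.mean_exon_length))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(200, 2000))
    return tuple(exons)


def generate_annotation(config: SimulationConfig, truth: TruthTable | None = None) -> AnnotationBundle:
    """Generate transcript models, sequences, TE intervals, CAGE tags and a
    coding-evidence table consistent with ``truth`` (drawn here if absent).

    Protein-coding genes live on ``chr1`` at regular >5 kb spacing; lncRNA
    genes live on ``chr2`` except for a planted fraction placed within 5 kb
    of (and on the same strand as) a coding gene, which a positional filter
    must discard.
    """
    config.validate()
    if truth is None:
        truth = generate_truth(config)
    rng = _child_rng(config.seed, 1)

    tx_truth = truth.transcripts
    gene_ids = list(dict.fromkeys(tx_truth["gene_id"]))
    coding_genes = [g for g in gene_ids if g.startswith("PCG")]
    lnc_genes = [g for g in gene_ids if not g.startswith("PCG")]

    transcripts: list[TranscriptModel] = []
    gene_spans: dict[str, tuple[str, str, int, int]] = {}

    # Coding genes: chr1, sequential.
    cursor = 10_000
    coding_layout = []
    for gid in coding_genes:
        strand = "+" if rng.random() < 0.5 else "-"
        coding_layout.append((gid, cursor, strand))
        cursor += config.intergenic_gap
    # lncRNA genes: a planted fraction sits 1 kb downstream of a coding gene
    # on the same strand (positional conflict); the rest go to chr2.
    conflict = {
        gid: bool(rng.random() < config.positional_conflict_rate) and bool(coding_genes)
        for gid in lnc_genes
    }

    def build_gene(gid: str, chrom: str, start: int, strand: str, biotype: str) -> int:
        tids = tx_truth.index[tx_truth["gene_id"] == gid]
        end = start
        for tid in tids:
            exons = _gene_structure(rng, config, start + int(rng.integers(0, 200)))
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    biotype=biotype,
                )
            )
            end = max(end, exons[-1][1])
        gene_spans[gid] = (chrom, strand, start, end)
        return end

    for gid, start, strand in coding_layout:
        build_gene(gid, "chr1", start, strand, "protein_coding")

    cursor2 = 10_000
    conflict_slot = 0
    for gid in lnc_genes:
        if conflict[gid]:
            host = coding_layout[conflict_slot % len(coding_layout)]
            conflict_slot += 1
            host_end = gene_spans[host[0]][3]
            build_gene(gid, "chr1", host_end + 1000, host[2], "lncRNA")
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            cursor2 = build_gene(gid, "chr2", cursor2, strand, "lncRNA") + config.intergenic_gap

    # Sequences with planted first ORFs.
    sequences: dict[str, str] = {}
    planted_utr = {}
    for tx in transcripts:
        n = tx.length
        seq = _BASES[rng.integers(0, 4, size=n)].copy()
        offset = int(tx_truth.loc[tx.transcript_id, "pseudo_utr_len"])
        offset = _plant_first_orf(seq, offset, rng)
        planted_utr[tx.transcript_id] = offset
        sequences[tx.transcript_id] = "".join(seq)
    tx_truth = tx_truth.copy()
    tx_truth["pseudo_utr_len"] = [planted_utr[t] for t in tx_truth.index]

    # TE intervals overlapping exons of their host transcript.
    tx_map = {t.transcript_id: t for t in transcripts}
    repeats: list[RepeatFeature] = []
    for i, row in enumerate(truth.te_insertions.itertuples(index=False)):
        tx = tx_map[row.transcript_id]
        exon = tx.exons[int(rng.integers(0, len(tx.exons)))]
        pos = int(rng.integers(exon[0], exon[1]))
        repeats.append(
            RepeatFeature(
                chrom=tx.chrom,
                start=pos,
                end=pos + int(row.length),
                strand="+" if rng.random() < 0.5 else "-",
                repeat_name=f"{row.te_class}_ins{i + 1}",
                repeat_class=row.te_class,
                repeat_family=row.te_class,
            )
        )

    # CAGE tag clusters at the TSS of capped transcripts (within +/-100 nt).
    cage_rows = []
    for tx in transcripts:
        info = tx_truth.loc[tx.transcript_id]
        mean_tags = config.cage_tags_capped if info["capped"] else config.cage_tags_uncapped
        count = int(rng.poisson(mean_tags))
        if count == 0:
            continue
        pos = max(0, tx.tss + int(rng.integers(-100, 101)))
        cage_rows.append(
            {
                "chrom": tx.chrom,
                "start": pos,
                "end": pos + 1,
                "transcript_id": tx.transcript_id,
                "count": count,
                "strand": tx.strand,
            }
        )
    cage = pd.DataFrame(
        cage_rows, columns=["chrom", "start", "end", "transcript_id", "count", "strand"]
    )

    # Coding-potential evidence: lncRNA transcripts score as noncoding except
    # a planted contaminating fraction pushed over one randomly chosen cutoff.
    ev_rows = []
    for tx in transcripts:
        if tx.biotype != "lncRNA":
            continue
        row = {
            "transcript_id": tx.transcript_id,
            "phylocsf_score": float(rng.normal(-20.0, 10.0)),
            "cpat_prob": float(rng.uniform(0.0, 0.2)),
            "cpc_score": float(rng.normal(-3.0, 1.0)),
            "peptide_hits": 0,
        }
        if rng.random() < config.coding_evidence_rate:
            which = int(rng.integers(0, 4))
            if which == 0:
                row["phylocsf_score"] = float(rng.uniform(96.0, 300.0))
            elif which == 1:
                row["cpat_prob"] = float(rng.uniform(0.364, 1.0))
            elif which == 2:
                row["cpc_score"] = float(rng.uniform(1.0, 5.0))
            else:
                row["peptide_hits"] = int(rng.integers(1, 5))
        ev_rows.append(row)
    evidence = pd.DataFrame(
        ev_rows,
        columns=["transcript_id", "phylocsf_score", "cpat_prob", "cpc_score", "peptide_hits"],
    )

    return AnnotationBundle(
        transcripts=transcripts,
        sequences=sequences,
        repeats=repeats,
        cage_tags=cage,
        coding_evidence=evidence,
        truth=TruthTable(transcripts=tx_truth, te_insertions=truth.te_insertions),
    )


# ---------------------------------------------------------------------------
# Microarray


def simulate_array(truth: TruthTable, config: SimulationConfig) -> ProbePanel:
    """Probe intensities I = max(floor, gain * C_hyb^slope * 10^eps).

    ``C_hyb`` is the hybridized concentration: the fraction concentration
    divided by the pool's mass factor (equal RNA masses are hybridized, so
    abundant pools are diluted). The input sample sees the sum of the three
    fraction concentrations. Spike-ins are added at hybridization at known
    concentrations, identical across samples, with the same noise model.
    """
    config.validate()
    rng = _child_rng(config.seed, 2)
    tx = truth.transcripts
    samples = list(ALL_SAMPLES)
    for s in samples:
        if s not in config.mass_factors:
            raise ConfigurationError(f"unknown sample label {s!r}")

    probe_ids, target_ids, is_spike, spike_conc = [], [], [], []
    conc_rows = []
    for tid, row in tx.iterrows():
        total = row["conc_free"] + row["conc_light"] + row["conc_heavy"]
        by_sample = {
            "free": row["conc_free"],
            "light": row["conc_light"],
            "heavy": row["conc_heavy"],
            "input": total,
        }
        for p in range(config.probes_per_transcript):
            probe_ids.append(f"{tid}_p{p + 1}")
            target_ids.append(tid)
            is_spike.append(False)
            spike_conc.append(np.nan)
            conc_rows.append(
                [by_sample[s] / config.mass_factors[s] for s in samples]
            )
    for li, level in enumerate(config.spike_levels):
        for p in range(config.spike_probes_per_level):
            probe_ids.append(f"SPIKE_L{li + 1}_p{p + 1}")
            target_ids.append(f"SPIKE_L{li + 1}")
            is_spike.append(True)
            spike_conc.append(level)
            conc_rows.append([level] * len(samples))

    hyb = np.asarray(conc_rows, dtype=float)
    if (hyb < 0).any():
        raise ValueError("truth concentrations must be nonnegative")
    eps = rng.normal(0.0, config.noise_sd_log10, size=hyb.shape) if config.noise_sd_log10 > 0 else 0.0
    signal = config.gain * hyb**config.slope * 10.0**eps
    signal[hyb == 0] = 0.0
    intensities = np.maximum(config.floor_intensity, signal)

    probes = pd.DataFrame(
        {"target_id": target_ids, "is_spike": is_spike, "spike_concentration": spike_conc},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    inten = pd.DataFrame(intensities, index=probes.index, columns=samples)
    meta = pd.DataFrame(
        {"mass_factor": [config.mass_factors[s] for s in samples]},
        index=pd.Index(samples, name="sample"),
    )
    return ProbePanel(probes=probes, intensities=inten, samples=meta)


# ---------------------------------------------------------------------------
# qPCR pool percentages


def simulate_qpcr(truth: TruthTable, config: SimulationConfig) -> pd.DataFrame:
    """Ct table for candidate transcripts across the FM/LP/HP pools.

    Ct = offset - log2(amount) + noise; the Dap and Thr bacterial spike-ins
    are present at equal amounts in every pool.
    """
    config.validate()
    rng = _child_rng(config.seed, 3)
    tx = truth.transcripts
    cyt = tx[tx["true_class"].isin(CYTOPLASMIC_CLASSES)].copy()
    cyt["total"] = cyt[["conc_free", "conc_light", "conc_heavy"]].sum(axis=1)
    candidates = cyt.sort_values("total", ascending=False).head(config.n_qpcr_transcripts)

    pools = {"FM": "conc_free", "LP": "conc_light", "HP": "conc_heavy"}
    sd = config.qpcr_noise_sd_ct
    rows = []
    for tid, row in candidates.iterrows():
        for pool, col in pools.items():
            rows.append(
                {
                    "transcript_id": tid,
                    "pool": pool,
                    "ct_target": 30.0 - np.log2(row[col]) + rng.normal(0.0, sd),
                    "ct_spike_dap": 20.0 + rng.normal(0.0, sd),
                    "ct_spike_thr": 21.0 + rng.normal(0.0, sd),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stability time course


def simulate_stability(
    truth: TruthTable, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct time course under transcription block, with and without a
    ribosome-stalling drug.

    Returns ``(ct_table, gene_truth)``. Decay follows first-order kinetics:
    Ct rises by one per half-life elapsed. For planted "stabilized" genes the
    drug multiplies the half-life by ``drug_stabilization_factor``; other
    genes decay identically with and without drug. The reference gene is
    constant. Noise is additive on each measured Ct.
    """
    config.validate()
    rng = _child_rng(config.seed, 4)
    tx = truth.transcripts
    poly = tx[tx["true_class"].isin(("light_polysomal", "heavy_polysomal"))]
    genes = list(poly.index[: config.n_stability_genes])
    if len(genes) < config.n_stability_genes:
        extra = [g for g in tx.index if g not in genes]
        genes += extra[: config.n_stability_genes - len(genes)]
    stabilized = {g: (i % 2 == 0) for i, g in enumerate(genes)}

    sd = config.qpcr_noise_sd_ct
    rows = []
    for gene in genes:
        base_ct = float(rng.uniform(18.0, 24.0))
        for treatment in ("control", "CHX", "EMT"):
            half_life = config.base_half_life_h
            if treatment != "control" and stabilized[gene]:
                half_life *= config.drug_stabilization_factor
            for bio in range(1, config.n_bio_replicates + 1):
                rep_offset = float(rng.uniform(-0.5, 0.5))
                for tech in range(1, config.n_tech_replicates + 1):
                    for tp_h in (0.0, 6.0):
                        ct0 = base_ct + rep_offset
                        ct = ct0 + tp_h / half_life
                        rows.append(
                            {
                                "gene": gene,
                                "treatment": treatment,
                                "bio_rep": bio,
                                "tech_rep": tech,
                                "timepoint": f"{int(tp_h)}h",
                                "ct_target": ct + rng.normal(0.0, sd),
                                "ct_reference": 15.0 + rng.normal(0.0, sd),
                            }
                        )
    gene_truth = pd.DataFrame(
        {"gene": genes, "stabilized": [stabilized[g] for g in genes]}
    )
    return pd.DataFrame(rows), gene_truth


def nuclear_evidence(truth: TruthTable) -> pd.DataFrame:
    """Nuclear RNA-seq detection evidence (mean RPKM and IDR) per transcript."""
    tx = truth.transcripts
    return pd.DataFrame(
        {
            "transcript_id": tx.index,
            "nuclear_rpkm": tx["nuclear_rpkm"].to_numpy(),
            "idr": tx["nuclear_idr"].to_numpy(),
        }
    )
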