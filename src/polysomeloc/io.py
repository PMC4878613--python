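"""Readers and writers for the pipeline's file formats.

GTF carries transcript/exon features (1-based closed on disk, 0-based
half-open in memory), FASTA the transcript sequences, BED6 the repeat and
CAGE-tag intervals, TSV the probe panel and every tabular result.
"""

from __future__ import annotations

import math
from collections import defaultdict

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import ProbePanel, RepeatFeature, TranscriptModel

# ---------------------------------------------------------------------------
# GTF


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    """Write transcript and exon features for each model, in input order."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_biotype "{tx.biotype}";'
            )
            rows = [("transcript", tx.start, tx.end)]
            rows += [("exon", s, e) for s, e in tx.exons]
            for feature, start, end in rows:
                fh.write(
                    f"{tx.chrom}\tpolysomeloc\t{feature}\t{start + 1}\t{end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """Read transcript models from a GTF; exon features define the structure."""
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _source, feature, start, end, _score, strand, _frame, attr = (
                line.rstrip("\n").split("\t")
            )
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr)
            tid = attrs["transcript_id"]
            if tid not in meta:
                meta[tid] = (
                    attrs.get("gene_id", tid),
                    chrom,
                    strand,
                    attrs.get("gene_biotype", attrs.get("transcript_biotype", "lncRNA")),
                )
                order.append(tid)
            exons[tid].append((int(start) - 1, int(end)))
    return [
        TranscriptModel(
            transcript_id=tid,
            gene_id=meta[tid][0],
            chrom=meta[tid][1],
            strand=meta[tid][2],
            exons=tuple(sorted(exons[tid])),
            biotype=meta[tid][3],
        )
        for tid in order
    ]


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# BED6


def write_repeats_bed(repeats: list[RepeatFeature], path) -> None:
    """BED6 with name = repeat_name|repeat_class|repeat_family."""
    with open(path, "w") as fh:
        for rep in repeats:
            name = f"{rep.repeat_name}|{rep.repeat_class}|{rep.repeat_family}"
            fh.write(f"{rep.chrom}\t{rep.start}\t{rep.end}\t{name}\t0\t{rep.strand}\n")


def read_repeats_bed(path) -> list[RepeatFeature]:
    repeats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            parts = name.split("|")
            repeats.append(
                RepeatFeature(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    repeat_name=parts[0],
                    repeat_class=parts[1] if len(parts) > 1 else parts[0],
                    repeat_family=parts[2] if len(parts) > 2 else "",
                )
            )
    return repeats


def write_cage_bed(tags: pd.DataFrame, path) -> None:
    """CAGE tag clusters as BED6: score column holds the tag count."""
    cols = ["chrom", "start", "end", "transcript_id", "count", "strand"]
    tags[cols].to_csv(path, sep="\t", header=False, index=False)


def read_cage_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "transcript_id", "count", "strand"],
    )
    return df


# ---------------------------------------------------------------------------
# Probe panel TSV

_PROBE_COLS = ["probe_id", "target_id", "is_spike", "spike_concentration"]


def write_probe_panel(panel: ProbePanel, panel_path, design_path) -> None:
    """Panel TSV: probe metadata + one intensity column per sample.

    The sample design (label, mass_factor) goes to a second TSV.
    """
    table = panel.probes.copy()
    for sample in panel.intensities.columns:
        table[sample] = panel.intensities[sample]
    table.index.name = "probe_id"
    table.reset_index().to_csv(panel_path, sep="\t", index=False, float_format="%.10g")
    design = panel.samples.copy()
    design.index.name = "sample"
    design.reset_index().to_csv(design_path, sep="\t", index=False, float_format="%.10g")


def read_probe_panel(panel_path, design_path) -> ProbePanel:
    table = pd.read_csv(panel_path, sep="\t")
    design = pd.read_csv(design_path, sep="\t").set_index("sample")
    probes = table.set_index("probe_id")[_PROBE_COLS[1:]]
    probes["is_spike"] = probes["is_spike"].astype(bool)
    sample_cols = [c for c in table.columns if c not in _PROBE_COLS]
    intensities = table.set_index("probe_id")[sample_cols].astype(float)
    return ProbePanel(probes=probes, intensities=intensities, samples=design)


# ---------------------------------------------------------------------------
# Per-base score tracks (bedGraph)


def read_bedgraph(path) -> dict[str, dict[int, float]]:
    """Read a bedGraph into per-chromosome sparse {position: score} maps.

    Suits the small promoter/exon windows queried here; bases absent from the
    file count as missing data.
    """
    track: dict[str, dict[int, float]] = defaultdict(dict)
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, value = line.split()[:4]
            score = float(value)
            if math.isnan(score):
                continue
            for pos in range(int(start), int(end)):
                track[chrom][pos] = score
    return dict(track)
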