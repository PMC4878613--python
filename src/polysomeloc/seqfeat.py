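"""Sequence-derived transcript features.

Six-frame canonical ORF catalog (AUG starts, UAA/UAG/UGA stops; per stop
codon only the longest ORF, i.e. the 5'-most in-frame start with no
intervening stop, is kept), pseudo-5'UTR length (distance from the 5' end
to the first AUG of the 5'-most forward ORF), GC content, per-base mean
conservation over intervals, and promoter deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import TranscriptModel

_STOPS = frozenset({"TAA", "TAG", "TGA"})
_START = "ATG"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class OrfRecord:
    """One canonical ORF. Frames 0-2 are forward; 3-5 are scanned on the
    reverse complement, with offsets in reverse-complement coordinates.
    ``end`` is half-open and includes the stop codon."""

    frame: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _normalize(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


def _reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _scan_one_frame(seq: str, frame: int) -> list[tuple[int, int]]:
    """ORFs in one reading frame of one strand.

    Tracking the first AUG since the last stop yields, for each stop codon,
    exactly the longest ORF ending at it. Codons containing N are neither
    starts nor stops.
    """
    orfs = []
    start = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _STOPS:
            if start is not None:
                orfs.append((start, i + 3))
                start = None
        elif codon == _START and start is None:
            start = i
    return orfs


def scan_orfs(sequence: str) -> list[OrfRecord]:
    """All canonical ORFs in the six frames of ``sequence``."""
    seq = _normalize(sequence)
    if not seq:
        return []
    records = []
    for frame in range(3):
        for start, end in _scan_one_frame(seq, frame):
            records.append(OrfRecord(frame=frame, start=start, end=end))
    rc = _reverse_complement(seq)
    for frame in range(3):
        for start, end in _scan_one_frame(rc, frame):
            records.append(OrfRecord(frame=frame + 3, start=start, end=end))
    return records


def pseudo_five_utr(sequence: str) -> int | None:
    """Distance (nt) from the 5' end to the first AUG of the 5'-most
    forward-strand ORF; None when no forward ORF exists."""
    starts = [o.start for o in scan_orfs(sequence) if o.frame < 3]
    return min(starts) if starts else None


def total_orf_coverage(sequence: str) -> float:
    """Fraction of transcript bases covered by the union of all six-frame
    ORFs (reverse-frame ORFs mapped back to forward coordinates)."""
    seq = _normalize(sequence)
    n = len(seq)
    if n == 0:
        return 0.0
    covered = np.zeros(n, dtype=bool)
    for orf in scan_orfs(seq):
        if orf.frame < 3:
            covered[orf.start : orf.end] = True
        else:
            covered[n - orf.end : n - orf.start] = True
    return float(covered.sum()) / n


def longest_orf_length(sequence: str) -> int:
    orfs = scan_orfs(sequence)
    return max((o.length for o in orfs), default=0)


def gc_content(sequence: str) -> float:
    """(#G + #C) / (length - #N); undefined (raises) for all-N input."""
    seq = _normalize(sequence)
    if not seq:
        raise ValueError("gc_content of empty sequence is undefined")
    n_count = seq.count("N")
    informative = len(seq) - n_count
    if informative == 0:
        raise ValueError("gc_content undefined: sequence is all N")
    return (seq.count("G") + seq.count("C")) / informative


def interval_mean_score(
    intervals: list[tuple[str, int, int]],
    track: dict[str, dict[int, float]],
) -> tuple[float, int]:
    """Mean per-base score over all covered bases of all intervals.

    Bases are weighted equally across intervals; bases missing from the
    track are skipped and counted. Returns ``(mean, n_missing)``; raises
    when no base is covered.
    """
    total = 0.0
    n = 0
    missing = 0
    for chrom, start, end in intervals:
        chrom_track = track.get(chrom, {})
        for pos in range(start, end):
            score = chrom_track.get(pos)
            if score is None:
                missing += 1
            else:
                total += score
                n += 1
    if n == 0:
        raise ValueError("no scored base covered by the queried intervals")
    return total / n, missing


def promoter_window(
    tx: TranscriptModel, upstream: int = 1000, downstream: int = 500
) -> tuple[str, int, int, str]:
    """Strand-aware promoter interval around the TSS (half-open, clipped at 0)."""
    if tx.strand == "+":
        start, end = tx.tss - upstream, tx.tss + downstream
    else:
        start, end = tx.tss + 1 - downstream, tx.tss + 1 + upstream
    return (tx.chrom, max(0, start), max(0, end), tx.strand)


def dedup_promoters(
    transcripts: list[TranscriptModel], upstream: int = 1000, downstream: int = 500
) -> dict[tuple[str, int, int, str], list[str]]:
    """Group transcripts by identical promoter window; each shared promoter
    contributes a single record downstream."""
    promoters: dict[tuple[str, int, int, str], list[str]] = {}
    for tx in transcripts:
        promoters.setdefault(promoter_window(tx, upstream, downstream), []).append(
            tx.transcript_id
        )
    return promoters


def feature_table(
    transcripts: list[TranscriptModel],
    sequences: dict[str, str],
    track: dict[str, dict[int, float]] | None = None,
    upstream: int = 1000,
    downstream: int = 500,
) -> pd.DataFrame:
    """Per-transcript feature vector: pseudo-5'UTR length, longest ORF,
    total ORF coverage, GC, and (when a track is given) mean exonic and
    promoter conservation."""
    rows = []
    for tx in transcripts:
        seq = sequences[tx.transcript_id]
        utr = pseudo_five_utr(seq)
        row = {
            "transcript_id": tx.transcript_id,
            "pseudo_five_utr_len": np.nan if utr is None else utr,
            "longest_orf_len": longest_orf_length(seq),
            "total_orf_coverage": total_orf_coverage(seq),
            "gc": gc_content(seq),
        }
        if track is not None:
            exon_iv = [(tx.chrom, s, e) for s, e in tx.exons]
            chrom, ps, pe, _ = promoter_window(tx, upstream, downstream)
            try:
                row["mean_exon_conservation"] = interval_mean_score(exon_iv, track)[0]
            except ValueError:
                row["mean_exon_conservation"] = np.nan
            try:
                row["mean_promoter_conservation"] = interval_mean_score(
                    [(chrom, ps, pe)], track
                )[0]
            except ValueError:
                row["mean_promoter_conservation"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
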