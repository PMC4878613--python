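"""High-confidence lncRNA catalog filtering.

Two stages. The positional filter discards a gene when any of its
transcripts overlaps a same-strand pseudogene, overlaps a same-strand
protein-coding exon, or lies within 5 kb (same strand) of a protein-coding
transcript or pseudogene — such lncRNAs may be unannotated extensions of
those genes. The coding-potential vote then flags a gene as potential
protein-coding when at least one transcript crosses at least one of four
evidence cutoffs (PhyloCSF > 95, CPAT >= 0.364, CPC >= 1, >= 1 exonic
same-strand peptide hit); the remainder are the filtered lncRNAs. Scores
come from external tools and are consumed, never computed.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .models import TranscriptModel

logger = logging.getLogger(__name__)

PHYLOCSF_CUTOFF = 95.0  # strictly greater
CPAT_CUTOFF = 0.364  # >=
CPC_CUTOFF = 1.0  # >=
PROXIMITY_BP = 5000  # gap <= 5 kb counts as "within"

VERDICTS = ("filtered_lncRNA", "potential_protein_coding", "positionally_discarded")


@dataclass
class FilterReport:
    """Per-gene verdicts plus per-transcript triggering rules."""

    gene_verdicts: dict[str, str]
    transcript_rules: dict[str, list[str]] = field(default_factory=dict)

    def genes_with(self, verdict: str) -> list[str]:
        return sorted(g for g, v in self.gene_verdicts.items() if v == verdict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.gene_verdicts),
                "verdict": list(self.gene_verdicts.values()),
            }
        )


def _span_tree(items: list[TranscriptModel]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for tx in items:
        trees[(tx.chrom, tx.strand)].addi(tx.start, tx.end, tx)
    return trees


def positional_filter(
    lncrnas: list[TranscriptModel],
    reference: list[TranscriptModel],
    proximity_bp: int = PROXIMITY_BP,
) -> FilterReport:
    """Discard lncRNA genes positionally entangled with coding/pseudogene
    annotation; every transcript of a discarded gene inherits the verdict.
    """
    coding = [t for t in reference if t.biotype == "protein_coding"]
    pseudo = [t for t in reference if t.biotype == "pseudogene"]
    coding_span = _span_tree(coding)
    pseudo_span = _span_tree(pseudo)
    coding_exons: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for tx in coding:
        for s, e in tx.exons:
            coding_exons[(tx.chrom, tx.strand)].addi(s, e, tx.transcript_id)

    ref_chroms = {t.chrom for t in reference}
    unknown_chroms: dict[str, int] = defaultdict(int)
    rules: dict[str, list[str]] = {}
    gene_hit: dict[str, bool] = {}
    gene_of: dict[str, str] = {}
    for tx in lncrnas:
        gene_of[tx.transcript_id] = tx.gene_id
        gene_hit.setdefault(tx.gene_id, False)
        if tx.chrom not in ref_chroms:
            unknown_chroms[tx.chrom] += 1
            continue
        key = (tx.chrom, tx.strand)
        hits = []
        if pseudo_span.get(key) and pseudo_span[key].overlap(tx.start, tx.end):
            hits.append("overlaps_pseudogene")
        exon_tree = coding_exons.get(key)
        if exon_tree and any(exon_tree.overlap(s, e) for s, e in tx.exons):
            hits.append("overlaps_coding_exon")
        # Proximity: gap between transcript spans <= proximity_bp, same strand;
        # overlap counts as within. Query an envelope widened by the gap (+1:
        # half-open trees treat touching intervals as non-overlapping, while a
        # gap of exactly proximity_bp must count).
        lo, hi = tx.start - proximity_bp - 1, tx.end + proximity_bp + 1
        near = []
        for tree in (coding_span.get(key), pseudo_span.get(key)):
            if tree:
                near.extend(tree.overlap(lo, hi))
        for other in near:
            gap = max(other.begin - tx.end, tx.start - other.end, 0)
            if gap <= proximity_bp:
                hits.append("within_5kb")
                break
        if hits:
            rules[tx.transcript_id] = hits
            gene_hit[tx.gene_id] = True

    if unknown_chroms:
        detail = ", ".join(f"{c}: {n}" for c, n in sorted(unknown_chroms.items()))
        logger.info(
            "transcripts on chromosomes without reference annotation retained "
            "untested (%s)",
            detail,
        )
    verdicts = {
        g: ("positionally_discarded" if hit else "filtered_lncRNA")
        for g, hit in gene_hit.items()
    }
    return FilterReport(gene_verdicts=verdicts, transcript_rules=rules)


def transcript_flagged(
    phylocsf_score: float, cpat_prob: float, cpc_score: float, peptide_hits: int
) -> bool:
    """Evidence vote for one transcript: any single method crossing its
    cutoff flags the transcript as potentially coding."""
    return (
        phylocsf_score > PHYLOCSF_CUTOFF
        or cpat_prob >= CPAT_CUTOFF
        or cpc_score >= CPC_CUTOFF
        or peptide_hits >= 1
    )


def coding_vote(
    evidence: pd.DataFrame,
    gene_map: dict[str, str],
    positional: FilterReport | None = None,
) -> FilterReport:
    """Combine evidence into final gene verdicts.

    ``evidence`` columns: transcript_id, phylocsf_score, cpat_prob,
    cpc_score, peptide_hits. ``gene_map`` maps every surviving transcript to
    its gene. A gene is potential_protein_coding iff >= 1 transcript is
    flagged. Transcripts with no evidence record count as noncoding (scores
    of -inf / 0 hits), logged. Evidence for unknown transcripts is an error.
    Verdicts from a prior positional report are carried through unchanged.
    """
    unknown = set(evidence["transcript_id"]) - set(gene_map)
    if unknown:
        raise KeyError(f"evidence for unknown transcripts: {sorted(unknown)[:5]}")
    discarded_genes = set()
    if positional is not None:
        discarded_genes = {
            g for g, v in positional.gene_verdicts.items() if v == "positionally_discarded"
        }

    by_tx = evidence.set_index("transcript_id")
    rules: dict[str, list[str]] = dict(positional.transcript_rules) if positional else {}
    gene_flagged: dict[str, bool] = {}
    n_missing = 0
    for tid, gene in gene_map.items():
        if gene in discarded_genes:
            continue
        gene_flagged.setdefault(gene, False)
        if tid not in by_tx.index:
            n_missing += 1
            continue
        row = by_tx.loc[tid]
        tx_rules = []
        if row["phylocsf_score"] > PHYLOCSF_CUTOFF:
            tx_rules.append("phylocsf")
        if row["cpat_prob"] >= CPAT_CUTOFF:
            tx_rules.append("cpat")
        if row["cpc_score"] >= CPC_CUTOFF:
            tx_rules.append("cpc")
        if row["peptide_hits"] >= 1:
            tx_rules.append("peptides")
        if tx_rules:
            rules[tid] = tx_rules
            gene_flagged[gene] = True
    if n_missing:
        logger.info("%d transcripts had no evidence record; treated as noncoding", n_missing)

    verdicts = {g: "positionally_discarded" for g in discarded_genes}
    verdicts.update(
        {
            g: ("potential_protein_coding" if flagged else "filtered_lncRNA")
            for g, flagged in gene_flagged.items()
        }
    )
    return FilterReport(gene_verdicts=verdicts, transcript_rules=rules)


def filter_catalog(
    lncrnas: list[TranscriptModel],
    reference: list[TranscriptModel],
    evidence: pd.DataFrame,
    proximity_bp: int = PROXIMITY_BP,
) -> FilterReport:
    """Run both filtering stages and return the final report."""
    positional = positional_filter(lncrnas, reference, proximity_bp=proximity_bp)
    gene_map = {t.transcript_id: t.gene_id for t in lncrnas}
    return coding_vote(evidence, gene_map, positional=positional)
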