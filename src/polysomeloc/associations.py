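"""Cross-evidence statistics linking localization to other data types.

Translation index (peptide vs mRNA abundance), CAGE-capping vs occupancy
regressions, cytoplasmic/nuclear expression ratios, and tissue expression
dispersion.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats


def translation_index(
    peptide_log10: float, mrna_concentration: float, min_peptide_log10: float = 0.5
) -> float | None:
    """TI = log10(peptide / mRNA) for one gene.

    ``peptide_log10`` is the log10 mean normalized peptide intensity; records
    at or below ``min_peptide_log10`` are excluded (returns None). mRNA
    concentration is linear (the sum over the three cytoplasmic fractions).
    """
    if mrna_concentration <= 0:
        raise ValueError("translation index undefined for zero mRNA concentration")
    if peptide_log10 <= min_peptide_log10:
        return None
    return peptide_log10 - math.log10(mrna_concentration)


def translation_index_table(
    peptides: pd.DataFrame,
    mrna: pd.DataFrame,
    min_peptide_log10: float = 0.5,
) -> pd.DataFrame:
    """Vectorized TI over genes. ``peptides``: gene_id, peptide_expression
    (log10). ``mrna``: gene_id, mrna_concentration (linear). Returns
    gene_id, translation_index, excluded (peptide below cutoff)."""
    merged = peptides.merge(mrna, on="gene_id", how="inner")
    merged = merged[merged["mrna_concentration"] > 0]
    excluded = merged["peptide_expression"] <= min_peptide_log10
    ti = merged["peptide_expression"] - np.log10(merged["mrna_concentration"])
    return pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "translation_index": ti.where(~excluded),
            "excluded": excluded,
        }
    )


def capping_regression(
    cage_normalized: pd.Series, occupancy_by_fraction: pd.DataFrame
) -> pd.DataFrame:
    """Per-fraction OLS of fraction log-occupancy on normalized CAGE signal.

    ``cage_normalized``: transcript-indexed CAGE tag counts in the TSS
    +/-100 nt window divided by cytoplasmic expression. ``occupancy_by_fraction``:
    transcript-indexed columns free/light/heavy holding
    log10(C_f) - log10(C_F + C_L + C_H). Returns slope, intercept, r and the
    two-sided p for slope = 0, one row per fraction.
    """
    rows = []
    for fraction in occupancy_by_fraction.columns:
        merged = pd.concat(
            [cage_normalized.rename("x"), occupancy_by_fraction[fraction].rename("y")],
            axis=1,
            join="inner",
        ).replace([np.inf, -np.inf], np.nan).dropna()
        if len(merged) < 3:
            raise ValueError(f"fraction {fraction!r}: need >=3 points for regression")
        fit = stats.linregress(merged["x"], merged["y"])
        rows.append(
            {
                "fraction": fraction,
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r": float(fit.rvalue),
                "p_value": float(fit.pvalue),
                "n": len(merged),
            }
        )
    return pd.DataFrame(rows)


def cyt_nuc_ratio(cyt_rpkm: float, nuc_rpkm: float) -> float:
    """log2(cytoplasmic / nuclear) RPKM for a transcript present in both."""
    if cyt_rpkm <= 0 or nuc_rpkm <= 0:
        raise ValueError("transcript must be present in both compartments")
    return math.log2(cyt_rpkm / nuc_rpkm)


def cyt_nuc_ratio_table(expression: pd.DataFrame) -> tuple[pd.Series, int]:
    """log2 cytoplasmic/nuclear ratios over a table with columns
    transcript_id, cyt_rpkm, nuc_rpkm; transcripts absent from either
    compartment are skipped and counted. Returns (ratios, n_skipped)."""
    present = (expression["cyt_rpkm"] > 0) & (expression["nuc_rpkm"] > 0)
    kept = expression[present]
    ratios = pd.Series(
        np.log2(kept["cyt_rpkm"].to_numpy() / kept["nuc_rpkm"].to_numpy()),
        index=kept["transcript_id"],
        name="log2_cyt_nuc",
    )
    return ratios, int((~present).sum())


def tissue_stats(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript dispersion across a transcripts x tissues RPKM matrix.

    CV = sd/mean over tissues (NaN for all-zero rows), variance, and
    detection breadth = fraction of tissues with RPKM > 0.
    """
    if expression.shape[1] < 2:
        raise ValueError("need >=2 tissues")
    values = expression.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame(
        {
            "cv": cv,
            "variance": values.var(axis=1, ddof=1),
            "breadth": (values > 0).mean(axis=1),
        },
        index=expression.index,
    )
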