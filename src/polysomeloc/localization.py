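"""Classification of transcripts by fraction of maximal signal.

A transcript detected in at least one cytoplasmic fraction is assigned to
the fraction where its absolute concentration peaks (free cytoplasmic,
light polysomal or heavy polysomal; light + heavy pool into "polysomal").
Transcripts detected in no cytoplasmic fraction fall back on nuclear
RNA-seq evidence (mean RPKM > 0 and IDR < 0.1 -> nuclear specific) or are
called not present. Polysomal occupancy is the linear-scale share of a
transcript's cytoplasmic copies found in the two polysomal fractions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import CYTOPLASMIC_CLASSES, CYTOPLASMIC_SAMPLES, SAMPLE_TO_CLASS

#: Argmax ties break toward the lighter fraction: free < light < heavy.
_FRACTION_ORDER = {"free": 0, "light": 1, "heavy": 2}


def _linear_concentrations(quant: pd.DataFrame) -> pd.DataFrame:
    """Wide per-transcript linear concentrations; undetected or
    variance-excluded entries are 0."""
    cyt = quant[quant["sample"].isin(CYTOPLASMIC_SAMPLES)].copy()
    usable = cyt["detected"] & ~cyt["variance_excluded"]
    cyt["linear"] = np.where(usable, 10.0 ** cyt["log10_concentration"], 0.0)
    wide = cyt.pivot(index="transcript_id", columns="sample", values="linear")
    for s in CYTOPLASMIC_SAMPLES:
        if s not in wide:
            wide[s] = 0.0
    return wide[list(CYTOPLASMIC_SAMPLES)].fillna(0.0)


def classify(
    quant: pd.DataFrame,
    nuclear: pd.DataFrame | None = None,
    idr_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Assign localization classes from a transcript quantification table.

    ``quant`` is the long table from :func:`polysomeloc.quant.aggregate_transcripts`;
    ``nuclear`` has columns transcript_id, nuclear_rpkm, idr (a boolean
    ``detected`` column is accepted in place of idr).

    Returns a DataFrame: transcript_id, loc_class, pooled_class, occupancy.
    """
    if quant.duplicated(subset=["transcript_id", "sample"]).any():
        raise ValueError("duplicate transcript/sample rows in quantification table")
    wide = _linear_concentrations(quant)

    nuc_detected: dict[str, bool] = {}
    if nuclear is not None:
        if nuclear["transcript_id"].duplicated().any():
            raise ValueError("duplicate transcript ids in nuclear evidence")
        for row in nuclear.itertuples(index=False):
            if hasattr(row, "idr"):
                ok = row.nuclear_rpkm > 0 and row.idr < idr_cutoff
            else:
                ok = row.nuclear_rpkm > 0 and bool(getattr(row, "detected", False))
            nuc_detected[row.transcript_id] = bool(ok)

    rows = []
    for tid, conc in wide.iterrows():
        values = conc.to_numpy()
        if values.sum() > 0:
            best = max(
                CYTOPLASMIC_SAMPLES,
                key=lambda s: (conc[s], -_FRACTION_ORDER[s]),
            )
            cls = SAMPLE_TO_CLASS[best]
            occ = float((conc["light"] + conc["heavy"]) / values.sum())
        elif nuc_detected.get(tid, False):
            cls, occ = "nuclear_specific", np.nan
        else:
            cls, occ = "not_present", np.nan
        pooled = (
            "polysomal"
            if cls in ("light_polysomal", "heavy_polysomal")
            else cls
        )
        rows.append(
            {"transcript_id": tid, "loc_class": cls, "pooled_class": pooled, "occupancy": occ}
        )
    return pd.DataFrame(rows)


def occupancy(conc_free: float, conc_light: float, conc_heavy: float) -> float:
    """Polysomal occupancy O = (C_L + C_H) / (C_F + C_L + C_H), linear scale.

    Undetected fractions enter as 0. Raises on an all-zero triple.
    """
    total = conc_free + conc_light + conc_heavy
    if total <= 0:
        raise ValueError("occupancy undefined: no cytoplasmic signal")
    return (conc_light + conc_heavy) / total


def fraction_log_occupancy(
    conc_free: float, conc_light: float, conc_heavy: float
) -> dict[str, float]:
    """Per-fraction log10 share: log10(C_f) - log10(C_F + C_L + C_H).

    The three exponentials sum to 1; each value is <= 0.
    """
    total = conc_free + conc_light + conc_heavy
    if total <= 0:
        raise ValueError("fraction log occupancy undefined: zero total")
    with np.errstate(divide="ignore"):
        return {
            "free": float(np.log10(conc_free) - np.log10(total)),
            "light": float(np.log10(conc_light) - np.log10(total)),
            "heavy": float(np.log10(conc_heavy) - np.log10(total)),
        }


def summarize_classes(calls: pd.DataFrame, decimals: int = 1) -> dict:
    """Counts and percentages per class, plus occupancy decile bins.

    Percentages of the three cytoplasmic classes are computed over
    cytoplasmic transcripts only and sum to 100 up to rounding. Occupancy
    bins are half-open [0, 0.1), ..., [0.9, 1.0].
    """
    if calls.empty:
        raise ValueError("no localization calls to summarize")
    counts = calls["loc_class"].value_counts().to_dict()
    cyt = calls[calls["loc_class"].isin(CYTOPLASMIC_CLASSES)]
    n_cyt = len(cyt)
    percentages = {
        cls: round(100.0 * counts.get(cls, 0) / n_cyt, decimals) if n_cyt else np.nan
        for cls in CYTOPLASMIC_CLASSES
    }
    pooled_pct = (
        round(
            100.0
            * (counts.get("light_polysomal", 0) + counts.get("heavy_polysomal", 0))
            / n_cyt,
            decimals,
        )
        if n_cyt
        else np.nan
    )
    occ = cyt["occupancy"].dropna().to_numpy()
    bin_edges = np.linspace(0.0, 1.0, 11)
    hist, _ = np.histogram(occ, bins=bin_edges)
    return {
        "counts": {cls: int(counts.get(cls, 0)) for cls in calls["loc_class"].unique()},
        "n_cytoplasmic": n_cyt,
        "percent_cytoplasmic": percentages,
        "percent_polysomal": pooled_pct,
        "occupancy_bins": {
            f"[{bin_edges[i]:.1f},{bin_edges[i + 1]:.1f})": int(hist[i])
            for i in range(10)
        },
    }


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Printed-style percentage of a numerator/denominator pair."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)
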