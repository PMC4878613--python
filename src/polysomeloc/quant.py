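"""Spike-in anchored absolute quantification of array intensities.

The chain is: background correction -> between-array normalization on the
spike-in probes -> per-sample calibration regression of log10 intensity on
log10 spike concentration, with a detection threshold where the relation
leaves linearity -> inversion of the regression (plus mass-factor
correction) to per-probe absolute log10 concentrations -> aggregation to
transcripts with a strict-majority detection rule and per-sample exclusion
of the highest-variance probesets.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .models import CalibrationModel, ProbePanel


class CalibrationError(RuntimeError):
    """Raised when a sample's spike-in series cannot anchor a regression."""


def background_correct(panel: ProbePanel, offset: float) -> ProbePanel:
    """Offset-based background correction.

    Subtracts the per-sample minimum intensity (the additive background
    estimate) and adds ``offset``, guaranteeing strictly positive output
    while preserving probe ordering and pairwise intensity differences
    within each sample.
    """
    if offset <= 0:
        raise ValueError("background offset must be positive")
    out = panel.copy()
    mins = out.intensities.min(axis=0)
    out.intensities = out.intensities.sub(mins, axis=1) + offset
    return out


def normalize_between_arrays(
    panel: ProbePanel, cycles: int = 3, frac: float = 0.7
) -> ProbePanel:
    """Cyclic loess normalization anchored on spike-in probes.

    For every sample pair a loess curve of the log-intensity difference (M)
    against the mean (A) is fitted on spike probes only, then applied to all
    probes of the pair, half to each sample; cycling over pairs a few times
    converges to agreement on the spike series. Non-spike probes are moved by
    the curves fit on spikes, never by their own values.
    """
    spikes = panel.probes["is_spike"].to_numpy()
    n_levels = panel.probes.loc[spikes, "spike_concentration"].nunique()
    if n_levels < 5:
        raise ValueError(f"need >=5 spike levels for normalization, got {n_levels}")
    samples = list(panel.intensities.columns)
    if len(samples) < 2:
        raise ValueError("need >=2 samples to normalize between arrays")

    X = np.log10(panel.intensities.to_numpy(dtype=float).clip(min=1e-300))
    for _ in range(cycles):
        for i in range(len(samples) - 1):
            for j in range(i + 1, len(samples)):
                A = 0.5 * (X[:, i] + X[:, j])
                M = X[:, i] - X[:, j]
                fit = lowess(M[spikes], A[spikes], frac=frac, return_sorted=True)
                # Interpolate the spike curve at every probe's A value;
                # constant extrapolation beyond the spike range.
                curve = np.interp(A, fit[:, 0], fit[:, 1])
                X[:, i] -= curve / 2.0
                X[:, j] += curve / 2.0
    out = panel.copy()
    out.intensities = pd.DataFrame(
        10.0**X, index=panel.intensities.index, columns=panel.intensities.columns
    )
    return out


def fit_calibration(
    spike_intensities: np.ndarray,
    spike_concentrations: np.ndarray,
    deviation_tolerance: float = 2.0,
    sample: str = "",
) -> CalibrationModel:
    """Fit log10(I) = a*log10(C) + b on the spike series and locate the
    detection threshold where the relation leaves linearity.

    Probe-level observations are collapsed to a median intensity per spike
    level. Scanning levels from low to high concentration, the lowest
    remaining level is dropped while its intensity deviates from a
    regression over the remaining levels by more than
    ``deviation_tolerance``-fold (the low-intensity floor bends the curve at
    the bottom, so departures from linearity accumulate there). The
    threshold is the observed intensity of the highest level dropped; if no
    level deviates it is the lowest level's intensity. The returned
    slope/intercept/r are fit on the levels strictly above the threshold.
    """
    intensities = np.asarray(spike_intensities, dtype=float)
    concentrations = np.asarray(spike_concentrations, dtype=float)
    if intensities.shape != concentrations.shape:
        raise ValueError("spike intensities and concentrations differ in shape")
    levels = np.unique(concentrations)
    if levels.size < 5:
        raise CalibrationError(f"need >=5 spike levels, got {levels.size}")

    level_int = np.array(
        [np.median(intensities[concentrations == c]) for c in levels]
    )
    log_c = np.log10(levels)
    log_i = np.log10(level_int)

    log_tol = math.log10(deviation_tolerance)
    keep_from = 0
    while levels.size - keep_from >= 2:
        a0, b0 = np.polyfit(log_c[keep_from:], log_i[keep_from:], 1)
        if abs(log_i[keep_from] - (a0 * log_c[keep_from] + b0)) > log_tol:
            keep_from += 1
        else:
            break
    threshold = float(level_int[max(keep_from - 1, 0)])
    keep = level_int > threshold
    if keep.sum() < 3:
        raise CalibrationError(
            f"only {int(keep.sum())} spike levels above the detection threshold"
        )
    a, b = np.polyfit(log_c[keep], log_i[keep], 1)
    r = float(np.corrcoef(log_c[keep], log_i[keep])[0, 1])
    if a <= 0:
        raise CalibrationError(f"nonpositive calibration slope {a:.3g}")
    return CalibrationModel(
        sample=sample,
        slope=float(a),
        intercept=float(b),
        detection_threshold=threshold,
        r=r,
        n_levels_used=int(keep.sum()),
    )


def calibrate_panel(
    panel: ProbePanel, deviation_tolerance: float = 2.0
) -> dict[str, CalibrationModel]:
    """Fit one calibration per sample from the panel's spike probes."""
    spikes = panel.spike_probes
    conc = spikes["spike_concentration"].to_numpy(dtype=float)
    return {
        sample: fit_calibration(
            panel.intensities.loc[spikes.index, sample].to_numpy(dtype=float),
            conc,
            deviation_tolerance=deviation_tolerance,
            sample=sample,
        )
        for sample in panel.intensities.columns
    }


def intensity_to_concentration(
    panel: ProbePanel,
    calibrations: dict[str, CalibrationModel],
    mass_factors: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-probe absolute log10 concentration; NaN below the threshold.

    log10(C) = (log10(I) - b)/a + log10(mass_factor): inverting the spike
    regression recovers the hybridized concentration, and the mass factor
    undoes the dilution to equal starting RNA amounts.
    """
    if mass_factors is None:
        mass_factors = panel.samples["mass_factor"].to_dict()
    out = {}
    for sample in panel.intensities.columns:
        if sample not in calibrations:
            raise KeyError(f"no calibration for sample {sample!r}")
        cal = calibrations[sample]
        inten = panel.intensities[sample].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            conc = cal.to_log10_concentration(inten, mass_factors.get(sample, 1.0))
        conc[~(inten > cal.detection_threshold)] = np.nan
        out[sample] = conc
    return pd.DataFrame(out, index=panel.intensities.index)


def aggregate_transcripts(
    panel: ProbePanel,
    calibrations: dict[str, CalibrationModel],
    mass_factors: dict[str, float] | None = None,
    variance_quantile: float = 0.05,
) -> pd.DataFrame:
    """Collapse probes to transcript-level quantifications.

    A target is detected in a sample when strictly more than half of its
    probes lie above the detection threshold (a single-probe target needs
    its one probe detected); its value is the mean log10 concentration of
    the detected probes. Probeset variance is computed over the raw
    (unthresholded) log10 conversions of all the target's probes; within
    each sample the top ``variance_quantile`` of detected targets by that
    variance are flagged ``variance_excluded``.

    Returns a long DataFrame: transcript_id, sample, detected,
    log10_concentration, probeset_variance, variance_excluded.
    """
    if mass_factors is None:
        mass_factors = panel.samples["mass_factor"].to_dict()
    probes = panel.probes[~panel.probes["is_spike"]]
    conc = intensity_to_concentration(panel, calibrations, mass_factors)

    rows = []
    for sample in panel.intensities.columns:
        cal = calibrations[sample]
        inten = panel.intensities.loc[probes.index, sample]
        with np.errstate(divide="ignore"):
            raw = cal.to_log10_concentration(
                inten.to_numpy(dtype=float), mass_factors.get(sample, 1.0)
            )
        raw = pd.Series(raw, index=probes.index).replace([np.inf, -np.inf], np.nan)
        sample_conc = conc.loc[probes.index, sample]
        frame = pd.DataFrame(
            {
                "target_id": probes["target_id"],
                "conc": sample_conc,
                "raw": raw,
                "above": sample_conc.notna(),
            }
        )
        grouped = frame.groupby("target_id", sort=True)
        n_probes = grouped.size()
        n_above = grouped["above"].sum()
        detected = n_above > n_probes / 2
        value = grouped.apply(
            lambda g: g.loc[g["above"], "conc"].mean(), include_groups=False
        )
        variance = grouped["raw"].apply(
            lambda v: float(np.var(v.dropna(), ddof=1)) if v.notna().sum() >= 2 else 0.0
        )
        det_ids = detected.index[detected]
        n_excl = int(np.floor(variance_quantile * len(det_ids)))
        excluded: set = set()
        if n_excl > 0:
            excluded = set(variance.loc[det_ids].nlargest(n_excl).index)
        for tid in n_probes.index:
            is_det = bool(detected.loc[tid])
            rows.append(
                {
                    "transcript_id": tid,
                    "sample": sample,
                    "detected": is_det,
                    "log10_concentration": float(value.loc[tid]) if is_det else np.nan,
                    "probeset_variance": float(variance.loc[tid]),
                    "variance_excluded": tid in excluded,
                }
            )
    return pd.DataFrame(rows)


def quantify(
    panel: ProbePanel,
    deviation_tolerance: float = 2.0,
    variance_quantile: float = 0.05,
    background_offset: float | None = None,
    normalize: bool = True,
) -> tuple[pd.DataFrame, dict[str, CalibrationModel]]:
    """Full quantification chain on one panel; returns (quant table, calibrations)."""
    work = panel
    if background_offset is not None:
        work = background_correct(work, background_offset)
    if normalize and len(work.intensities.columns) >= 2:
        work = normalize_between_arrays(work)
    calibrations = calibrate_panel(work, deviation_tolerance=deviation_tolerance)
    quant = aggregate_transcripts(work, calibrations, variance_quantile=variance_quantile)
    return quant, calibrations
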