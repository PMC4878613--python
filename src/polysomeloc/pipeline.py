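"""End-to-end orchestration: simulate -> filter -> quantify -> localize ->
features/repeats/associations -> stability, with a machine-readable summary
and a run manifest.

Every stage reads the files the previous stage wrote through the package's
own readers, so a run exercises the full file round trip. Given a seed the
whole run is deterministic.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, associations, catalog, io, localization, qpcr, quant, simulate
from .config import SimulationConfig
from .models import CYTOPLASMIC_CLASSES, CYTOPLASMIC_SAMPLES

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_all(config: SimulationConfig | str | Path, outdir: str | Path) -> dict:
    """Run the full synthetic study; returns the manifest dictionary.

    Writes stage outputs, ``summary.json`` (deterministic given the seed)
    and ``manifest.json`` under ``outdir``.
    """
    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_yaml(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    summary: dict = {}

    def run_stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineError(name, exc) from exc

    # -- synthetic_data ----------------------------------------------------
    def _simulate():
        if config.n_lncrna_genes == 0:
            raise ValueError("n_lncrna_genes must be positive to run the study")
        bundle = simulate.generate_annotation(config)
        paths = bundle.write(outdir / "inputs")
        panel = simulate.simulate_array(bundle.truth, config)
        io.write_probe_panel(
            panel, outdir / "inputs" / "probe_panel.tsv", outdir / "inputs" / "sample_design.tsv"
        )
        paths["panel"] = str(outdir / "inputs" / "probe_panel.tsv")
        paths["design"] = str(outdir / "inputs" / "sample_design.tsv")
        qpcr_table = simulate.simulate_qpcr(bundle.truth, config)
        qpcr_table.to_csv(outdir / "inputs" / "pool_qpcr.tsv", sep="\t", index=False)
        stab_table, stab_truth = simulate.simulate_stability(bundle.truth, config)
        stab_table.to_csv(outdir / "inputs" / "stability_ct.tsv", sep="\t", index=False)
        stab_truth.to_csv(outdir / "inputs" / "stability_truth.tsv", sep="\t", index=False)
        simulate.nuclear_evidence(bundle.truth).to_csv(
            outdir / "inputs" / "nuclear_evidence.tsv", sep="\t", index=False
        )
        manifest["stages"]["synthetic_data"] = {
            "paths": paths,
            "n_transcripts": len(bundle.transcripts),
            "n_repeats": len(bundle.repeats),
        }
        return bundle

    bundle = run_stage("synthetic_data", _simulate)

    # -- catalog_filter ----------------------------------------------------
    def _filter():
        transcripts = io.read_gtf(outdir / "inputs" / "annotation.gtf")
        lncrnas = [t for t in transcripts if t.biotype == "lncRNA"]
        reference = [t for t in transcripts if t.biotype != "lncRNA"]
        evidence = pd.read_csv(outdir / "inputs" / "coding_evidence.tsv", sep="\t")
        report = catalog.filter_catalog(lncrnas, reference, evidence)
        frame = report.to_frame()
        frame.to_csv(outdir / "catalog_verdicts.tsv", sep="\t", index=False)
        manifest["stages"]["catalog_filter"] = {
            "paths": {"verdicts": str(outdir / "catalog_verdicts.tsv")},
            "n_genes": len(report.gene_verdicts),
        }
        counts = frame["verdict"].value_counts().to_dict()
        summary["catalog"] = {v: int(counts.get(v, 0)) for v in catalog.VERDICTS}
        return transcripts, lncrnas, report

    transcripts, lncrnas, filter_report = run_stage("catalog_filter", _filter)
    filtered_genes = set(filter_report.genes_with("filtered_lncRNA"))

    # -- array_quant -------------------------------------------------------
    def _quantify():
        panel = io.read_probe_panel(
            outdir / "inputs" / "probe_panel.tsv", outdir / "inputs" / "sample_design.tsv"
        )
        table, calibrations = quant.quantify(panel)
        table.to_csv(outdir / "transcript_quant.tsv", sep="\t", index=False, float_format="%.10g")
        cal_frame = pd.DataFrame(
            [
                {
                    "sample": c.sample,
                    "slope": c.slope,
                    "intercept": c.intercept,
                    "detection_threshold": c.detection_threshold,
                    "r": c.r,
                    "n_levels_used": c.n_levels_used,
                }
                for c in calibrations.values()
            ]
        )
        cal_frame.to_csv(outdir / "calibration.tsv", sep="\t", index=False, float_format="%.10g")
        manifest["stages"]["array_quant"] = {
            "paths": {
                "quant": str(outdir / "transcript_quant.tsv"),
                "calibration": str(outdir / "calibration.tsv"),
            },
            "n_rows": len(table),
        }
        summary["calibration"] = {
            c.sample: {"slope": c.slope, "intercept": c.intercept, "r": c.r}
            for c in calibrations.values()
        }
        return table

    quant_table = run_stage("array_quant", _quantify)

    # -- localization ------------------------------------------------------
    def _localize():
        nuclear = pd.read_csv(outdir / "inputs" / "nuclear_evidence.tsv", sep="\t")
        calls = localization.classify(quant_table, nuclear)
        calls.to_csv(outdir / "localization_calls.tsv", sep="\t", index=False, float_format="%.10g")
        biotype = {t.transcript_id: t.biotype for t in transcripts}
        gene = {t.transcript_id: t.gene_id for t in transcripts}
        calls["biotype"] = calls["transcript_id"].map(biotype)
        lnc_calls = calls[
            (calls["biotype"] == "lncRNA")
            & calls["transcript_id"].map(gene).isin(filtered_genes)
        ]
        mrna_calls = calls[calls["biotype"] == "protein_coding"]
        summary["lncrna_classes"] = localization.summarize_classes(lnc_calls)
        if (mrna_calls["loc_class"].isin(CYTOPLASMIC_CLASSES)).any():
            summary["mrna_classes"] = localization.summarize_classes(mrna_calls)
        manifest["stages"]["localization"] = {
            "paths": {"calls": str(outdir / "localization_calls.tsv")},
            "n_calls": len(calls),
        }
        return calls

    calls = run_stage("localization", _localize)

    # -- recovery vs truth -------------------------------------------------
    def _recovery():
        truth = bundle.truth.transcripts
        merged = calls.merge(
            truth.reset_index()[["transcript_id", "true_class"]], on="transcript_id"
        )
        cyt = merged[merged["true_class"].isin(CYTOPLASMIC_CLASSES)]
        detected = cyt[cyt["loc_class"].isin(CYTOPLASMIC_CLASSES)]
        recovery = (
            float((detected["loc_class"] == detected["true_class"]).mean())
            if len(detected)
            else np.nan
        )
        # Concentration recovery, per fraction sample.
        truth_cols = {"free": "conc_free", "light": "conc_light", "heavy": "conc_heavy"}
        errors = []
        for sample, col in truth_cols.items():
            sub = quant_table[
                (quant_table["sample"] == sample)
                & quant_table["detected"]
                & ~quant_table["variance_excluded"]
            ]
            sub = sub[sub["transcript_id"].isin(truth.index)]
            true_conc = truth.loc[sub["transcript_id"], col].to_numpy()
            ok = true_conc > 0
            errors.append(
                sub["log10_concentration"].to_numpy()[ok] - np.log10(true_conc[ok])
            )
        err = np.concatenate(errors) if errors else np.array([])
        rmse = float(np.sqrt(np.mean(err**2))) if err.size else np.nan
        # Sum of fractions vs input hybridization.
        wide = quant_table.pivot(
            index="transcript_id", columns="sample", values="log10_concentration"
        )
        have = wide.dropna(subset=[*CYTOPLASMIC_SAMPLES, "input"], how="any")
        if len(have) >= 3:
            total = np.log10(
                sum(10.0 ** have[s] for s in CYTOPLASMIC_SAMPLES)
            )
            r = float(np.corrcoef(total, have["input"])[0, 1])
        else:
            r = np.nan
        summary["recovery"] = {
            "class_recovery_rate": recovery,
            "n_classified_cytoplasmic": int(len(detected)),
            "log10_concentration_rmse": rmse,
            "sum_vs_input_pearson_r": r,
        }

    run_stage("recovery", _recovery)

    # -- repeats -----------------------------------------------------------
    def _repeats():
        from . import repeats as rep

        repeat_features = io.read_repeats_bed(outdir / "inputs" / "repeats.bed")
        lnc_models = [t for t in lncrnas if t.gene_id in filtered_genes]
        profiles = rep.te_profiles(lnc_models, repeat_features)
        profiles.to_csv(outdir / "te_profiles.tsv", sep="\t", index=False, float_format="%.10g")
        cls = calls[["transcript_id", "loc_class"]]
        matrix = rep.class_te_matrix(profiles, cls, lnc_models)
        matrix.to_csv(outdir / "te_class_matrix.tsv", sep="\t", float_format="%.10g")
        summary["te_matrix"] = {
            str(loc): {str(c): (None if pd.isna(v) else float(v)) for c, v in row.items()}
            for loc, row in matrix.iterrows()
        }
        # Planted contrast: ERVL-MaLR coverage, free cytoplasmic vs polysomal.
        cls_map = cls.set_index("transcript_id")["loc_class"]
        reps_ids = [t.transcript_id for t in rep.representative_transcripts(lnc_models)]
        cov = (
            profiles[profiles["repeat_class"] == "ERVL-MaLR"]
            .set_index("transcript_id")["coverage"]
            .reindex(reps_ids)
            .fillna(0.0)
        )
        loc = cls_map.reindex(reps_ids)
        free_cov = cov[loc == "free_cytoplasmic"].to_numpy()
        poly_cov = cov[loc.isin(["light_polysomal", "heavy_polysomal"])].to_numpy()
        if free_cov.size and poly_cov.size:
            test = rep.coverage_rank_test(free_cov, poly_cov)
            carriers = set(cov.index[cov > 0])
            fg = set(loc.index[loc == "free_cytoplasmic"])
            bg = set(loc.index[loc.isin(CYTOPLASMIC_CLASSES)])
            summary["ervl_malr"] = {
                "mean_coverage_free": test["mean_a"],
                "mean_coverage_polysomal": test["mean_b"],
                "rank_test_p": test["p_value"],
                "presence_enrichment_p": rep.presence_enrichment(fg & bg, bg, carriers),
            }
        manifest["stages"]["repeat_analysis"] = {
            "paths": {
                "profiles": str(outdir / "te_profiles.tsv"),
                "matrix": str(outdir / "te_class_matrix.tsv"),
            },
            "n_profiles": len(profiles),
        }

    run_stage("repeat_analysis", _repeats)

    # -- associations (capping vs occupancy) --------------------------------
    def _associate():
        cage = io.read_cage_bed(outdir / "inputs" / "cage_tags.bed")
        wide = localization._linear_concentrations(quant_table)
        total = wide.sum(axis=1)
        expressed = total[total > 0]
        tags = cage.set_index("transcript_id")["count"]
        cage_norm = (tags.reindex(expressed.index).fillna(0.0)) / expressed
        with np.errstate(divide="ignore"):
            occ = pd.DataFrame(
                {
                    s: np.log10(wide.loc[expressed.index, s]) - np.log10(expressed)
                    for s in CYTOPLASMIC_SAMPLES
                }
            )
        fits = associations.capping_regression(cage_norm, occ)
        fits.to_csv(outdir / "capping_regression.tsv", sep="\t", index=False, float_format="%.10g")
        summary["capping_regression"] = {
            row["fraction"]: {"slope": row["slope"], "p_value": row["p_value"], "n": int(row["n"])}
            for _, row in fits.iterrows()
        }
        manifest["stages"]["association_stats"] = {
            "paths": {"capping": str(outdir / "capping_regression.tsv")},
            "n_transcripts": int(len(expressed)),
        }

    run_stage("association_stats", _associate)

    # -- stability + pool qPCR ----------------------------------------------
    def _stability():
        ct = pd.read_csv(outdir / "inputs" / "stability_ct.tsv", sep="\t")
        stab = qpcr.stability_table(ct)
        stab.to_csv(outdir / "stability.tsv", sep="\t", index=False, float_format="%.10g")
        pool_ct = pd.read_csv(outdir / "inputs" / "pool_qpcr.tsv", sep="\t")
        pools = qpcr.pool_percentage_table(pool_ct)
        pools.to_csv(outdir / "pool_percentages.tsv", sep="\t", index=False, float_format="%.10g")
        # Concordance of qPCR pool percentages with the array-side shares.
        truth = bundle.truth.transcripts
        paired_q, paired_a = [], []
        for _, row in pools.iterrows():
            t = truth.loc[row["transcript_id"]]
            tot = t["conc_free"] + t["conc_light"] + t["conc_heavy"]
            if tot <= 0:
                continue
            for pool, col in (("FM", "conc_free"), ("LP", "conc_light"), ("HP", "conc_heavy")):
                paired_q.append(row[pool])
                paired_a.append(100.0 * t[col] / tot)
        r, p = qpcr.concordance(np.array(paired_q), np.array(paired_a))
        stab_truth = pd.read_csv(outdir / "inputs" / "stability_truth.tsv", sep="\t")
        stabilized = set(stab_truth.loc[stab_truth["stabilized"], "gene"])
        hits = stab[(stab["gene"].isin(stabilized)) & (stab["mean_ratio"] > 1) & (stab["p_value"] < 0.05)]
        summary["stability"] = {
            "qpcr_array_concordance_r": r,
            "qpcr_array_concordance_p": p,
            "n_stabilized_planted": len(stabilized),
            "n_stabilized_detected": int(hits["gene"].nunique()),
        }
        manifest["stages"]["stability_qpcr"] = {
            "paths": {
                "stability": str(outdir / "stability.tsv"),
                "pools": str(outdir / "pool_percentages.tsv"),
            },
            "n_pool_transcripts": len(pools),
        }

    run_stage("stability_qpcr", _stability)

    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(_round_floats(summary), fh, sort_keys=True, indent=1)
        fh.write("\n")
    manifest["summary"] = str(summary_path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_round_floats(manifest), fh, sort_keys=True, indent=1)
        fh.write("\n")
    return manifest
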