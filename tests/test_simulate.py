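"""Synthetic-data generator: planted structure, noise model, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from polysomeloc import io, simulate
from polysomeloc.config import ConfigurationError, SimulationConfig
from polysomeloc.models import CYTOPLASMIC_CLASSES
from polysomeloc.repeats import build_repeat_index


def _uniform_classes(**kw):
    kw.setdefault("class_proportions", {
        "free_cytoplasmic": 0.3, "light_polysomal": 0.3, "heavy_polysomal": 0.1,
        "nuclear_specific": 0.15, "not_present": 0.15,
    })
    return SimulationConfig(**kw)


class TestConfig:
    def test_rejects_negative_counts(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_lncrna_genes=-1)

    def test_rejects_unsorted_spike_levels(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(spike_levels=[10.0, 1.0, 100.0])

    def test_rejects_probability_outside_unit_interval(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(te_insertion_rates={"Alu": 1.5})

    def test_rejects_unnormalized_class_proportions(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(class_proportions={"free_cytoplasmic": 0.5})

    def test_yaml_round_trip(self, tmp_path, tiny_config):
        path = tmp_path / "config.yaml"
        tiny_config.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == tiny_config


class TestTruth:
    def test_cytoplasmic_class_matches_argmax_of_concentrations(self, tiny_config):
        truth = simulate.generate_truth(tiny_config).transcripts
        cyt = truth[truth["true_class"].isin(CYTOPLASMIC_CLASSES)]
        argmax = cyt[["conc_free", "conc_light", "conc_heavy"]].idxmax(axis=1)
        expected = cyt["true_class"].map({
            "free_cytoplasmic": "conc_free",
            "light_polysomal": "conc_light",
            "heavy_polysomal": "conc_heavy",
        })
        assert (argmax == expected).all()

    def test_class_proportions_within_binomial_error(self):
        config = _uniform_classes(n_lncrna_genes=600, n_coding_genes=0, seed=3)
        truth = simulate.generate_truth(config).transcripts
        genes = truth.groupby("gene_id")["true_class"].first()
        n = len(genes)
        for cls, p in config.class_proportions.items():
            observed = (genes == cls).sum()
            tol = 4 * math.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) <= tol, cls


class TestAnnotation:
    def test_zero_te_rates_give_no_exonic_te_overlap(self):
        config = SimulationConfig(
            n_lncrna_genes=30, n_coding_genes=5, seed=2,
            te_insertion_rates={"Alu": 0.0, "ERVL-MaLR": 0.0},
        )
        bundle = simulate.generate_annotation(config)
        assert bundle.repeats == []

    def test_zero_utr_offset_puts_aug_at_sequence_start(self):
        config = SimulationConfig(
            n_lncrna_genes=20, n_coding_genes=0, seed=2,
            pseudo_utr_mean_by_class={c: 0.0 for c in
                                      ["free_cytoplasmic", "light_polysomal",
                                       "heavy_polysomal", "nuclear_specific",
                                       "not_present"]},
        )
        bundle = simulate.generate_annotation(config)
        assert all(seq.startswith("ATG") for seq in bundle.sequences.values())

    def test_planted_utr_is_first_forward_orf_start(self, tiny_config):
        from polysomeloc.seqfeat import pseudo_five_utr

        bundle = simulate.generate_annotation(tiny_config)
        truth = bundle.truth.transcripts
        for tid, seq in list(bundle.sequences.items())[:40]:
            assert pseudo_five_utr(seq) == truth.loc[tid, "pseudo_utr_len"]

    def test_te_insertions_overlap_host_exons(self, tiny_config):
        bundle = simulate.generate_annotation(tiny_config)
        index = build_repeat_index(bundle.repeats)
        tx_map = bundle.transcript_map()
        for row in bundle.truth.te_insertions.itertuples(index=False):
            tx = tx_map[row.transcript_id]
            tree = index[tx.chrom]
            assert any(tree.overlap(s, e) for s, e in tx.exons)

    def test_capped_transcript_cage_tags_within_window(self, tiny_config):
        bundle = simulate.generate_annotation(tiny_config)
        tx_map = bundle.transcript_map()
        for row in bundle.cage_tags.itertuples(index=False):
            tss = tx_map[row.transcript_id].tss
            assert abs(row.start - tss) <= 100

    def test_deterministic_byte_identical_outputs(self, tmp_path, tiny_config):
        paths1 = simulate.generate_annotation(tiny_config).write(tmp_path / "a")
        paths2 = simulate.generate_annotation(tiny_config).write(tmp_path / "b")
        for key in ("gtf", "fasta", "repeats", "cage"):
            assert open(paths1[key], "rb").read() == open(paths2[key], "rb").read()

    def test_files_round_trip_through_package_readers(self, tmp_path, tiny_config):
        bundle = simulate.generate_annotation(tiny_config)
        paths = bundle.write(tmp_path)
        assert io.read_gtf(paths["gtf"]) == bundle.transcripts
        assert io.read_fasta(paths["fasta"]) == bundle.sequences
        assert io.read_repeats_bed(paths["repeats"]) == bundle.repeats
        cage = io.read_cage_bed(paths["cage"])
        pd.testing.assert_frame_equal(cage, bundle.cage_tags)


class TestArray:
    def test_noise_free_intensities_linear_in_concentration(self):
        config = SimulationConfig(
            n_lncrna_genes=20, n_coding_genes=0, noise_sd_log10=0.0,
            floor_intensity=1e-12, slope=1.0, seed=5,
        )
        truth = simulate.generate_truth(config)
        panel = simulate.simulate_array(truth, config)
        tx = truth.transcripts
        for sample, col in (("free", "conc_free"), ("light", "conc_light")):
            offsets = []
            for tid, row in tx.iterrows():
                conc = row[col] / config.mass_factors[sample]
                if conc <= 1e-6:
                    continue
                inten = panel.intensities.loc[f"{tid}_p1", sample]
                offsets.append(np.log10(inten) - np.log10(conc))
            assert np.ptp(offsets) < 1e-9
            assert offsets[0] == pytest.approx(np.log10(config.gain))

    def test_concentration_below_floor_clamps_to_floor(self):
        config = SimulationConfig(
            n_lncrna_genes=10, n_coding_genes=0, noise_sd_log10=0.0,
            floor_intensity=50.0, mean_log10_conc=-6.0, sd_log10_conc=0.01, seed=5,
        )
        truth = simulate.generate_truth(config)
        panel = simulate.simulate_array(truth, config)
        non_spike = panel.probes.index[~panel.probes["is_spike"]]
        assert (panel.intensities.loc[non_spike] == 50.0).all().all()

    def test_noise_sd_matches_stated_model(self):
        config = SimulationConfig(
            n_lncrna_genes=300, n_coding_genes=0, transcripts_per_gene_max=1,
            noise_sd_log10=0.1, floor_intensity=1e-12, seed=11,
            class_proportions={"free_cytoplasmic": 1.0, "light_polysomal": 0.0,
                               "heavy_polysomal": 0.0, "nuclear_specific": 0.0,
                               "not_present": 0.0},
        )
        truth = simulate.generate_truth(config)
        panel = simulate.simulate_array(truth, config)
        tx = truth.transcripts
        resid = []
        for tid, row in tx.iterrows():
            expected = config.gain * row["conc_free"] / config.mass_factors["free"]
            for p in range(1, config.probes_per_transcript + 1):
                inten = panel.intensities.loc[f"{tid}_p{p}", "free"]
                resid.append(np.log10(inten) - np.log10(expected))
        assert len(resid) >= 1000
        assert np.std(resid) == pytest.approx(0.1, abs=0.01)

    def test_panel_round_trips_through_tsv(self, tmp_path, tiny_config):
        truth = simulate.generate_truth(tiny_config)
        panel = simulate.simulate_array(truth, tiny_config)
        io.write_probe_panel(panel, tmp_path / "p.tsv", tmp_path / "d.tsv")
        back = io.read_probe_panel(tmp_path / "p.tsv", tmp_path / "d.tsv")
        assert np.allclose(back.intensities, panel.intensities, rtol=1e-9)
        assert (back.probes["target_id"] == panel.probes["target_id"]).all()
        assert (back.probes["is_spike"] == panel.probes["is_spike"]).all()


class TestQpcr:
    def _noise_free(self, **kw):
        kw.setdefault("qpcr_noise_sd_ct", 0.0)
        kw.setdefault("n_lncrna_genes", 20)
        kw.setdefault("n_coding_genes", 0)
        kw.setdefault("seed", 9)
        return SimulationConfig(**kw)

    def test_spike_cts_equal_across_pools_at_zero_noise(self):
        config = self._noise_free()
        truth = simulate.generate_truth(config)
        table = simulate.simulate_qpcr(truth, config)
        assert table["ct_spike_dap"].nunique() == 1
        assert table["ct_spike_thr"].nunique() == 1

    def test_doubling_amount_lowers_ct_by_one(self):
        config = self._noise_free()
        truth = simulate.generate_truth(config)
        doubled = truth.transcripts.copy()
        doubled[["conc_free", "conc_light", "conc_heavy"]] *= 2
        t1 = simulate.simulate_qpcr(truth, config)
        t2 = simulate.simulate_qpcr(
            simulate.TruthTable(transcripts=doubled, te_insertions=truth.te_insertions),
            config,
        )
        merged = t1.merge(t2, on=["transcript_id", "pool"], suffixes=("_1", "_2"))
        assert np.allclose(merged["ct_target_1"] - merged["ct_target_2"], 1.0)

    def test_seeded_run_is_reproducible(self, tiny_config):
        truth = simulate.generate_truth(tiny_config)
        t1 = simulate.simulate_qpcr(truth, tiny_config)
        t2 = simulate.simulate_qpcr(truth, tiny_config)
        pd.testing.assert_frame_equal(t1, t2)


class TestStability:
    def test_no_decay_means_equal_cts(self):
        config = SimulationConfig(
            n_lncrna_genes=20, n_coding_genes=0, qpcr_noise_sd_ct=0.0,
            base_half_life_h=float("inf"), drug_stabilization_factor=1.0, seed=9,
        )
        truth = simulate.generate_truth(config)
        table, _ = simulate.simulate_stability(truth, config)
        wide = table.pivot_table(
            index=["gene", "treatment", "bio_rep", "tech_rep"],
            columns="timepoint", values="ct_target",
        )
        assert np.allclose(wide["0h"], wide["6h"])

    def test_six_hour_half_life_raises_ct_by_one(self):
        config = SimulationConfig(
            n_lncrna_genes=20, n_coding_genes=0, qpcr_noise_sd_ct=0.0,
            base_half_life_h=6.0, drug_stabilization_factor=1.0, seed=9,
        )
        truth = simulate.generate_truth(config)
        table, _ = simulate.simulate_stability(truth, config)
        wide = table.pivot_table(
            index=["gene", "treatment", "bio_rep", "tech_rep"],
            columns="timepoint", values="ct_target",
        )
        assert np.allclose(wide["6h"] - wide["0h"], 1.0)

    def test_seeded_run_is_reproducible(self, tiny_config):
        truth = simulate.generate_truth(tiny_config)
        t1, _ = simulate.simulate_stability(truth, tiny_config)
        t2, _ = simulate.simulate_stability(truth, tiny_config)
        pd.testing.assert_frame_equal(t1, t2)
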