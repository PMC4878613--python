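"""Spike-in calibration and absolute quantification."""

import numpy as np
import pandas as pd
import pytest

from polysomeloc import quant, simulate
from polysomeloc.config import SimulationConfig
from polysomeloc.quant import CalibrationError
from tests.conftest import make_panel, spike_panel


def _spike_series(gain=100.0, levels=None, samples=("s1",)):
    levels = levels or [10.0**k for k in range(8)]
    return spike_panel(
        {c: {s: gain * c for s in samples} for c in levels}
    )


class TestBackgroundCorrect:
    def test_constant_shift_restores_pairwise_differences(self, rng):
        base = rng.uniform(10, 1000, size=50)
        panel0 = make_panel({f"p{i}": {"s1": v} for i, v in enumerate(base)})
        shifted = make_panel({f"p{i}": {"s1": v + 37.5} for i, v in enumerate(base)})
        c0 = quant.background_correct(panel0, offset=1.0).intensities["s1"]
        c1 = quant.background_correct(shifted, offset=1.0).intensities["s1"]
        assert np.allclose(c0, c1, atol=1e-6)
        assert (c0.rank() == pd.Series(base, index=c0.index).rank()).all()

    def test_all_zero_becomes_constant_positive(self):
        panel = make_panel({f"p{i}": {"s1": 0.0} for i in range(5)})
        out = quant.background_correct(panel, offset=0.5).intensities["s1"]
        assert (out == 0.5).all()

    def test_idempotent_application_stays_positive(self, rng):
        panel = make_panel({f"p{i}": {"s1": v} for i, v in
                            enumerate(rng.uniform(0, 100, size=20))})
        once = quant.background_correct(panel, offset=1.0)
        twice = quant.background_correct(once, offset=1.0)
        assert (twice.intensities["s1"] > 0).all()

    def test_nonpositive_offset_rejected(self):
        panel = make_panel({"p1": {"s1": 1.0}})
        with pytest.raises(ValueError):
            quant.background_correct(panel, offset=0.0)


class TestNormalizeBetweenArrays:
    def _panel(self, distort, n_probes=40, rng=None):
        rng = rng or np.random.default_rng(0)
        levels = [10.0**k for k in range(8)]
        intensities, spikes = {}, {}
        for li, c in enumerate(levels):
            pid = f"S{li}"
            intensities[pid] = {"s1": 100 * c, "s2": distort(100 * c)}
            spikes[pid] = c
        for i in range(n_probes):
            v = float(10 ** rng.uniform(2, 8))
            intensities[f"p{i}"] = {"s1": v, "s2": distort(v)}
        return make_panel(intensities, spikes)

    def test_identical_samples_are_left_alone(self):
        panel = self._panel(lambda v: v)
        out = quant.normalize_between_arrays(panel)
        assert np.allclose(out.intensities, panel.intensities, rtol=1e-9)

    def test_twofold_scaling_is_removed_from_spikes(self):
        panel = self._panel(lambda v: 2.0 * v)
        out = quant.normalize_between_arrays(panel)
        spikes = out.probes.index[out.probes["is_spike"]]
        s1 = out.intensities.loc[spikes, "s1"]
        s2 = out.intensities.loc[spikes, "s2"]
        assert np.allclose(s1, s2, rtol=0.01)

    def test_monotone_nonlinear_distortion_spread_halved(self):
        panel = self._panel(lambda v: 3.0 * v**0.9)
        out = quant.normalize_between_arrays(panel)
        spikes = panel.probes.index[panel.probes["is_spike"]]

        def spread(p):
            X = np.log10(p.intensities.loc[spikes])
            return np.abs(X["s1"] - X["s2"]).mean()

        assert spread(out) <= 0.5 * spread(panel)

    def test_too_few_spike_levels_rejected(self):
        levels = [1.0, 10.0, 100.0, 1000.0]
        intensities = {f"S{i}": {"s1": c, "s2": c} for i, c in enumerate(levels)}
        spikes = {f"S{i}": c for i, c in enumerate(levels)}
        with pytest.raises(ValueError):
            quant.normalize_between_arrays(make_panel(intensities, spikes))


class TestFitCalibration:
    def test_noise_free_power_law_recovered_exactly(self):
        levels = np.array([10.0**k for k in range(8)])
        cal = quant.fit_calibration(100.0 * levels, levels)
        assert cal.slope == pytest.approx(1.0, abs=1e-12)
        assert cal.intercept == pytest.approx(2.0, abs=1e-12)
        assert cal.detection_threshold == pytest.approx(100.0)
        assert cal.r == pytest.approx(1.0)

    def test_floored_levels_excluded_exactly(self):
        levels = np.array([10.0**k for k in range(8)])
        intensities = np.maximum(5e3, 100.0 * levels)  # bottom 2 of 8 at floor
        cal = quant.fit_calibration(intensities, levels, deviation_tolerance=2.0)
        assert cal.detection_threshold == pytest.approx(5e3)
        assert cal.n_levels_used == 6
        assert cal.slope == pytest.approx(1.0, abs=1e-9)
        assert cal.intercept == pytest.approx(2.0, abs=1e-9)

    def test_deep_floor_still_isolated(self):
        # Half the ladder clamped: the scan must still find the clean top.
        levels = np.array([10.0**k for k in range(8)])
        intensities = np.maximum(5e4, 10.0 * levels)  # bottom 4 of 8 at floor
        cal = quant.fit_calibration(intensities, levels, deviation_tolerance=2.0)
        assert cal.detection_threshold == pytest.approx(5e4)
        assert cal.n_levels_used == 4
        assert cal.slope == pytest.approx(1.0, abs=1e-9)

    def test_refit_above_threshold_is_a_fixed_point(self, rng):
        levels = np.array([10.0**k for k in range(8)])
        noisy = 100.0 * levels * 10 ** rng.normal(0, 0.02, size=8)
        cal = quant.fit_calibration(noisy, levels)
        keep = noisy > cal.detection_threshold
        a, b = np.polyfit(np.log10(levels[keep]), np.log10(noisy[keep]), 1)
        assert a == pytest.approx(cal.slope, abs=1e-9)
        assert b == pytest.approx(cal.intercept, abs=1e-9)

    def test_too_few_usable_levels_is_an_error(self):
        levels = np.array([1.0, 10.0, 100.0, 1e3, 1e4])
        intensities = np.maximum(1e4, 10.0 * levels)  # only the top level clears
        with pytest.raises(CalibrationError):
            quant.fit_calibration(intensities, levels)

    def test_fewer_than_five_levels_is_an_error(self):
        levels = np.array([1.0, 10.0, 100.0, 1e3])
        with pytest.raises(CalibrationError):
            quant.fit_calibration(100 * levels, levels)


class TestIntensityToConcentration:
    def test_identity_calibration(self):
        panel = _spike_series()
        cals = quant.calibrate_panel(panel)
        cals["s1"] = quant.CalibrationModel(
            sample="s1", slope=1.0, intercept=0.0, detection_threshold=0.0,
            r=1.0, n_levels_used=8,
        )
        conc = quant.intensity_to_concentration(panel, cals, {"s1": 1.0})
        probe = panel.intensities.index[panel.intensities["s1"] == 100.0][0]
        assert conc.loc[probe, "s1"] == pytest.approx(2.0)

    def test_mass_factor_shifts_by_its_log(self):
        panel = _spike_series()
        cal = quant.CalibrationModel("s1", 1.0, 0.0, 0.0, 1.0, 8)
        c1 = quant.intensity_to_concentration(panel, {"s1": cal}, {"s1": 1.0})
        c10 = quant.intensity_to_concentration(panel, {"s1": cal}, {"s1": 10.0})
        assert np.allclose(c10 - c1, 1.0)

    def test_missing_calibration_is_an_error(self):
        panel = _spike_series()
        with pytest.raises(KeyError):
            quant.intensity_to_concentration(panel, {}, {"s1": 1.0})

    def test_below_threshold_is_absent(self):
        panel = _spike_series()
        cal = quant.CalibrationModel("s1", 1.0, 0.0, 500.0, 1.0, 8)
        conc = quant.intensity_to_concentration(panel, {"s1": cal}, {"s1": 1.0})
        below = panel.intensities["s1"] <= 500.0
        assert conc.loc[below, "s1"].isna().all()
        assert conc.loc[~below, "s1"].notna().all()

    def test_monotone_in_intensity(self):
        panel = _spike_series()
        cals = quant.calibrate_panel(panel)
        conc = quant.intensity_to_concentration(panel, cals)
        ordered = panel.intensities["s1"].sort_values()
        assert conc.loc[ordered.index, "s1"].dropna().is_monotonic_increasing


def _target_panel(probe_values: dict[str, list[float]], threshold=10.0):
    """Panel of multi-probe targets plus a trivially perfect spike ladder."""
    intensities, spikes, targets = {}, {}, {}
    for tid, values in probe_values.items():
        for i, v in enumerate(values):
            pid = f"{tid}_p{i}"
            intensities[pid] = {"s1": v}
            targets[pid] = tid
    for li, c in enumerate([10.0**k for k in range(8)]):
        pid = f"S{li}"
        intensities[pid] = {"s1": c}
        spikes[pid] = c
    panel = make_panel(intensities, spikes, targets)
    cal = quant.CalibrationModel("s1", 1.0, 0.0, threshold, 1.0, 8)
    return panel, {"s1": cal}


class TestAggregateTranscripts:
    def test_strict_majority_detection(self):
        panel, cals = _target_panel({
            "t3of4": [100.0, 100.0, 100.0, 1.0],
            "t2of4": [100.0, 100.0, 1.0, 1.0],
        })
        out = quant.aggregate_transcripts(panel, cals).set_index("transcript_id")
        assert bool(out.loc["t3of4", "detected"])
        assert out.loc["t3of4", "log10_concentration"] == pytest.approx(2.0)
        assert not bool(out.loc["t2of4", "detected"])
        assert np.isnan(out.loc["t2of4", "log10_concentration"])

    def test_single_probe_target_follows_its_probe(self):
        panel, cals = _target_panel({"one": [100.0], "dim": [1.0]})
        out = quant.aggregate_transcripts(panel, cals).set_index("transcript_id")
        assert bool(out.loc["one", "detected"])
        assert not bool(out.loc["dim", "detected"])

    def test_variance_exclusion_flags_top_quantile_exactly(self, rng):
        values = {}
        spread = np.linspace(0.01, 0.5, 100)
        for i in range(100):
            base = 3.0  # log10
            probes = 10 ** (base + np.array([-1, 1, -0.5, 0.5]) * spread[i])
            values[f"t{i:03d}"] = list(probes)
        panel, cals = _target_panel(values, threshold=0.5)
        out = quant.aggregate_transcripts(panel, cals, variance_quantile=0.05)
        flagged = set(out.loc[out["variance_excluded"], "transcript_id"])
        expected = {f"t{i:03d}" for i in range(95, 100)}  # 5 widest probesets
        assert flagged == expected

    def test_unknown_sample_label_missing_calibration_errors(self):
        panel, cals = _target_panel({"t": [100.0] * 4})
        with pytest.raises(KeyError):
            quant.aggregate_transcripts(panel, {})


class TestEndToEnd:
    def test_noise_free_recovery_to_1e6(self):
        config = SimulationConfig(
            n_lncrna_genes=40, n_coding_genes=0, noise_sd_log10=0.0,
            floor_intensity=1e-9, mean_log10_conc=3.5, sd_log10_conc=0.5, seed=21,
        )
        truth = simulate.generate_truth(config)
        panel = simulate.simulate_array(truth, config)
        table, cals = quant.quantify(panel, variance_quantile=0.0)
        tx = truth.transcripts
        checked = 0
        for sample, col in (("free", "conc_free"), ("light", "conc_light"),
                            ("heavy", "conc_heavy")):
            sub = table[(table["sample"] == sample) & table["detected"]]
            for _, row in sub.iterrows():
                true_c = tx.loc[row["transcript_id"], col]
                if true_c <= 0:
                    continue
                assert row["log10_concentration"] == pytest.approx(
                    np.log10(true_c), abs=1e-6
                )
                checked += 1
        assert checked > 50

    def test_sum_of_fractions_tracks_input_sample(self):
        config = SimulationConfig(
            n_lncrna_genes=150, n_coding_genes=0, noise_sd_log10=0.05,
            mean_log10_conc=3.5, seed=22,
        )
        truth = simulate.generate_truth(config)
        panel = simulate.simulate_array(truth, config)
        table, _ = quant.quantify(panel)
        wide = table.pivot(index="transcript_id", columns="sample",
                           values="log10_concentration")
        have = wide.dropna()
        total = np.log10(10 ** have["free"] + 10 ** have["light"] + 10 ** have["heavy"])
        r = np.corrcoef(total, have["input"])[0, 1]
        assert len(have) >= 50
        assert r >= 0.95
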