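"""Peak quantification, calibration, level classification, and bead decoding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ramancode as rc
from ramancode.decode import classify_level, decoded_to_frame
from ramancode.errors import CalibrationError, LowSignalError, RangeError
from ramancode.simulate import diagonal_codes, lorentzian


def _single_peak(height=50.0, center=1400.0, fwhm=10.0):
    w = 600.0 + 2.0 * np.arange(1301)
    return rc.Spectrum(w, height * lorentzian(w, center, fwhm))


class TestQuantifyPeak:
    def test_flat_zero_is_zero(self):
        w = 600.0 + 2.0 * np.arange(100)
        assert rc.quantify_peak(rc.Spectrum(w, np.zeros(100)), 700.0) == 0.0

    def test_known_lorentzian_height(self):
        sp = _single_peak(height=50.0)
        assert rc.quantify_peak(sp, 1400.0) == pytest.approx(50.0, rel=0.02)

    def test_linearity_under_scaling(self):
        sp = _single_peak(height=50.0)
        h1 = rc.quantify_peak(sp, 1400.0)
        h3 = rc.quantify_peak(sp.scaled(3.0), 1400.0)
        assert h3 == pytest.approx(3.0 * h1, rel=1e-12)

    def test_window_outside_grid_rejected(self):
        sp = _single_peak()
        with pytest.raises(RangeError):
            rc.quantify_peak(sp, 599.0)

    def test_negative_dips_clip_to_zero(self):
        w = 600.0 + 2.0 * np.arange(100)
        assert rc.quantify_peak(rc.Spectrum(w, np.full(100, -3.0)), 700.0) == 0.0


class TestRegionRatio:
    def test_noise_free_ratio_matches_level(self, cfg, scheme):
        for level in (0, 3, 9):
            sp = rc.simulate_spectrum(rc.Code(level, level, level), cfg, noise=False)
            for region in "XYZ":
                assert rc.region_ratio(sp, scheme.pair(region)) == pytest.approx(
                    scheme.level_ratios[level], abs=0.02
                )

    def test_invariant_to_global_scaling(self, cfg, scheme):
        sp = rc.simulate_spectrum(rc.Code(2, 5, 8), cfg, noise=False)
        for region in "XYZ":
            r1 = rc.region_ratio(sp, scheme.pair(region))
            r2 = rc.region_ratio(sp.scaled(2.0), scheme.pair(region))
            assert r2 == pytest.approx(r1, rel=1e-9)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scaling_invariance_property(self, factor):
        cfg = rc.SimulationConfig()
        sp = rc.simulate_spectrum(rc.Code(3, 3, 3), cfg, noise=False)
        pair = cfg.scheme.pair("X")
        assert rc.region_ratio(sp.scaled(factor), pair) == pytest.approx(
            rc.region_ratio(sp, pair), rel=1e-9
        )

    def test_dead_reference_is_low_signal(self, cfg, scheme):
        w = 600.0 + 2.0 * np.arange(1301)
        sp = rc.Spectrum(w, np.zeros(1301))
        with pytest.raises(LowSignalError):
            rc.region_ratio(sp, scheme.pair("X"))


class TestCalibration:
    def test_noise_free_centroids_track_level_map(
        self, scheme, noise_free_calibration
    ):
        for region in "XYZ":
            mu = noise_free_calibration.centroids[region]
            assert len(mu) == 10
            assert np.all(np.diff(mu) > 0)
            # centroids carry the (shared) smoothing/baseline bias of the
            # pipeline; they track the dosage ladder, they need not equal it
            assert np.allclose(mu, scheme.level_ratios, atol=0.06)

    def test_noisy_centroids_near_noise_free_truth(
        self, scheme, noisy_calibration, noise_free_calibration
    ):
        """5 replicates/level: noisy centroid within ~3 sd/sqrt(5) of the
        noise-free centroid of the same pipeline (CLT check)."""
        for region in "XYZ":
            mu = noisy_calibration.centroids[region]
            sd = noisy_calibration.dispersions[region]
            truth = noise_free_calibration.centroids[region]
            for level in range(10):
                # floor covers the ~0.01 systematic shift the random baseline
                # leaves after ALS correction (absent from the replicate sd)
                tol = max(4.0 * sd[level] / np.sqrt(5), 0.015)
                assert abs(mu[level] - truth[level]) < tol

    def test_missing_level_reported(self, cfg, scheme):
        standards = rc.simulate_standards(
            cfg, 1, codes=[rc.Code(l, l, l) for l in range(9)], noise=False
        )
        with pytest.raises(CalibrationError, match="missing"):
            rc.calibrate_levels(standards, scheme)

    def test_save_load_round_trip(self, noise_free_calibration, tmp_path):
        prefix = tmp_path / "cal"
        noise_free_calibration.save(prefix)
        back = rc.CalibrationSet.load(prefix)
        for region in "XYZ":
            assert np.allclose(
                back.centroids[region], noise_free_calibration.centroids[region]
            )

    def test_non_monotone_centroids_rejected(self):
        mu = np.linspace(0, 1.5, 10)
        bad = mu.copy()
        bad[4], bad[5] = bad[5], bad[4]
        with pytest.raises(CalibrationError, match="replicates"):
            rc.CalibrationSet(
                centroids={"X": bad, "Y": mu, "Z": mu},
                dispersions={r: np.full(10, 0.01) for r in "XYZ"},
                n_replicates={r: np.ones(10) for r in "XYZ"},
                n_levels=10,
            )


class TestClassifyLevel:
    @pytest.fixture()
    def centroids(self):
        return np.linspace(0.0, 1.5, 10), np.full(10, 0.02)

    def test_exact_centroid(self, centroids):
        mu, sd = centroids
        level, margin, flags = classify_level(float(mu[3]), mu, sd)
        assert level == 3 and margin > 0 and not flags

    def test_midpoint_tie_takes_lower_level(self, centroids):
        mu, sd = centroids
        midpoint = 0.5 * (mu[2] + mu[3])
        level, margin, _ = classify_level(float(midpoint), mu, sd)
        assert level == 2
        assert margin == pytest.approx(0.0, abs=1e-9)

    def test_out_of_range_clamps_with_flag(self, centroids):
        mu, sd = centroids
        level, _, flags = classify_level(2.5, mu, sd)
        assert level == 9 and "out_of_range" in flags
        level, _, flags = classify_level(-0.5, mu, sd)
        assert level == 0 and "out_of_range" in flags

    def test_equals_brute_force_argmin(self, centroids, rng):
        """Nearest-centroid equals exhaustive distance minimization (10^4 draws)."""
        mu, sd = centroids
        ratios = rng.uniform(-0.2, 1.7, size=10_000)
        for ratio in ratios:
            level, _, _ = classify_level(float(ratio), mu, sd)
            brute = min(range(10), key=lambda l: (abs(ratio - mu[l]), l))
            assert level == brute


class TestDecodeBead:
    def test_noise_free_ligand_code(self, cfg, scheme, noise_free_calibration):
        sp = rc.simulate_spectrum(rc.Code(5, 7, 5), cfg, noise=False)
        decoded = rc.decode_bead(sp, scheme, noise_free_calibration)
        assert decoded.code.code_number == 575
        assert decoded.sequence == "cGRGDdvc"
        assert decoded.confidence > 0.99

    def test_exhaustive_zero_noise_round_trip(self, cfg, scheme, noise_free_calibration):
        for code in rc.enumerate_codes(scheme):
            sp = rc.simulate_spectrum(code, cfg, noise=False)
            assert rc.decode_bead(sp, scheme, noise_free_calibration).code == code

    def test_global_scaling_does_not_change_code(self, cfg, scheme, noise_free_calibration):
        sp = rc.simulate_spectrum(rc.Code(2, 8, 4), cfg, noise=False)
        a = rc.decode_bead(sp, scheme, noise_free_calibration)
        b = rc.decode_bead(sp.scaled(0.5), scheme, noise_free_calibration)
        assert a.code == b.code

    def test_low_signal_spectrum_is_undecodable(self, scheme, noise_free_calibration):
        w = 600.0 + 2.0 * np.arange(1301)
        sp = rc.Spectrum(w, np.full(1301, 0.01))
        with pytest.raises(LowSignalError):
            rc.decode_bead(sp, scheme, noise_free_calibration)


class TestDecodeBatch:
    def test_empty_batch_warns(self, scheme, noise_free_calibration):
        with pytest.warns(UserWarning, match="no spectra"):
            decoded, summary = rc.decode_batch([], scheme, noise_free_calibration)
        assert decoded == [] and summary["n_total"] == 0

    def test_accuracy_and_confusion_with_truth(self, cfg, scheme, noisy_calibration):
        library = rc.simulate_library(300, cfg, seed=77)
        items = [(t.bead_id, s, t.code) for t, s in library]
        decoded, summary = rc.decode_batch(items, scheme, noisy_calibration)
        assert summary["accuracy"] >= 0.95
        assert set(summary["region_errors"]) == {"X", "Y", "Z"}

    def test_undecodable_beads_collected_not_fatal(self, cfg, scheme, noise_free_calibration):
        good = rc.simulate_spectrum(rc.Code(1, 1, 1), cfg, noise=False)
        dead = rc.Spectrum(cfg.grid(), np.zeros(cfg.grid().size))
        items = [("ok", good), ("dead", dead)]
        decoded, summary = rc.decode_batch(items, scheme, noise_free_calibration)
        assert summary["n_decoded"] == 1
        assert "dead" in summary["errors"]

    def test_accuracy_monotone_in_noise(self, scheme, noise_free_calibration):
        """Decoding accuracy never improves as additive noise grows.

        Calibration is held fixed (noise-free) and per-bead seeds are shared
        across noise levels, isolating the measurement-noise effect.
        """
        accuracies = []
        codes = rc.enumerate_codes(scheme)
        rng = np.random.default_rng(55)
        picks = rng.integers(0, 1000, size=120)
        for sd in (0.0, 2.0, 6.0, 12.0, 24.0):
            cfg = rc.SimulationConfig(scheme=scheme, noise=rc.NoiseModel(additive_sd=sd))
            ok = 0
            for i, pick in enumerate(picks):
                sp = rc.simulate_spectrum(codes[pick], cfg, rng=9000 + i)
                try:
                    ok += rc.decode_bead(sp, scheme, noise_free_calibration).code == codes[pick]
                except LowSignalError:
                    pass
            accuracies.append(ok / len(picks))
        assert all(b <= a + 1e-9 for a, b in zip(accuracies, accuracies[1:]))

    def test_confident_beads_are_more_accurate(self, scheme):
        """Among beads with confidence >= 0.9, accuracy is at least that of the rest."""
        cfg = rc.SimulationConfig(scheme=scheme, noise=rc.NoiseModel(additive_sd=8.0))
        standards = rc.simulate_standards(cfg, 5, codes=diagonal_codes(scheme), rng=600)
        calibration = rc.calibrate_levels(standards, scheme)
        codes = rc.enumerate_codes(scheme)
        rng = np.random.default_rng(66)
        picks = rng.integers(0, 1000, size=250)
        hits_hi, hits_lo = [], []
        for i, pick in enumerate(picks):
            sp = rc.simulate_spectrum(codes[pick], cfg, rng=7000 + i)
            try:
                d = rc.decode_bead(sp, scheme, calibration)
            except LowSignalError:
                continue
            (hits_hi if d.confidence >= 0.9 else hits_lo).append(d.code == codes[pick])
        assert hits_hi and hits_lo  # both confidence strata populated at this noise
        assert np.mean(hits_hi) >= np.mean(hits_lo)

    def test_output_table_columns(self, cfg, scheme, noise_free_calibration):
        sp = rc.simulate_spectrum(rc.Code(5, 7, 5), cfg, noise=False)
        decoded = [rc.decode_bead(sp, scheme, noise_free_calibration, bead_id="b1")]
        frame = decoded_to_frame(decoded)
        assert list(frame.columns) == [
            "bead_id", "R_X", "R_Y", "R_Z", "x", "y", "z",
            "code_number", "sequence", "confidence", "flags",
        ]
        assert frame.loc[0, "code_number"] == 575
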