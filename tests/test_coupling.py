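"""Phase extraction, modulation index, surrogates, inhalation peaks, PTA."""

import numpy as np
import pytest

from breathmod import coupling, spectral, synth
from breathmod.coupling import EmptyPhaseBinError

from conftest import brute_force_peaks


class TestExtractPhase:
    def test_cosine_phase_zero_at_peaks(self):
        rate = 100.0
        t = np.arange(int(60 * rate)) / rate
        tr = synth.RespirationTrace(np.cos(2 * np.pi * 0.25 * t), rate)
        ph = coupling.extract_phase(tr)
        peaks = brute_force_peaks(tr.samples)
        assert np.max(np.abs(ph.phase_rad[peaks])) < 0.05
        assert ph.phase_rad.min() >= -np.pi and ph.phase_rad.max() < np.pi

    def test_unwrapped_slope_is_two_pi_f(self):
        rate, f = 100.0, 0.5
        t = np.arange(int(120 * rate)) / rate
        tr = synth.RespirationTrace(np.sin(2 * np.pi * f * t), rate)
        ph = coupling.extract_phase(tr)
        unwrapped = np.unwrap(ph.phase_rad)
        slope = np.polyfit(t[500:-500], unwrapped[500:-500], 1)[0]
        assert slope == pytest.approx(2 * np.pi * f, rel=1e-3)

    def test_constant_trace_rejected(self):
        tr = synth.RespirationTrace(np.ones(100), 10.0)
        with pytest.raises(ValueError, match="constant"):
            coupling.extract_phase(tr)

    def test_jittered_breath_phase_near_zero_at_peaks(
        self, breath_trace, breath_phase
    ):
        peaks = brute_force_peaks(breath_trace.samples, min_gap=300)
        assert np.max(np.abs(breath_phase.phase_rad[peaks])) < 0.1


class TestBinAmplitudeByPhase:
    def test_constant_amplitude_gives_equal_bins(self, breath_phase):
        bm = coupling.bin_amplitude_by_phase(
            breath_phase.phase_rad, np.full(breath_phase.phase_rad.size, 2.5)
        )
        np.testing.assert_allclose(bm, 2.5)

    def test_cosine_amplitude_recovers_bin_centres(self):
        """amplitude = 1 + cos(phase) on dense uniform phase: each bin's
        mean equals the analytic integral over its own interval."""
        phase = np.linspace(-np.pi, np.pi, 2_000_001)[:-1]
        amp = 1.0 + np.cos(phase)
        bm = coupling.bin_amplitude_by_phase(phase, amp, n_bins=20)
        width = 2 * np.pi / 20
        edges = -np.pi + width * np.arange(21)
        analytic = 1.0 + (np.sin(edges[1:]) - np.sin(edges[:-1])) / width
        np.testing.assert_allclose(bm, analytic, atol=1e-5)
        centres = edges[:-1] + width / 2
        np.testing.assert_allclose(bm, 1.0 + np.cos(centres), atol=5e-3)

    def test_long_recording_yields_20_finite_means(self, breath_phase):
        rng = np.random.default_rng(0)
        bm = coupling.bin_amplitude_by_phase(
            breath_phase.phase_rad, rng.random(breath_phase.phase_rad.size)
        )
        assert bm.shape == (20,) and np.all(np.isfinite(bm))

    def test_empty_bin_error_carries_index(self):
        phase = np.linspace(0.0, np.pi - 0.2, 500)  # negative half missing
        with pytest.raises(EmptyPhaseBinError) as exc:
            coupling.bin_amplitude_by_phase(phase, np.ones(500))
        assert exc.value.bin_index == 0


class TestModulationIndex:
    def test_uniform_zero_and_delta_one(self):
        assert coupling.modulation_index(np.full(20, 3.7)) == pytest.approx(0.0)
        delta = np.zeros(20)
        delta[7] = 5.0
        assert coupling.modulation_index(delta) == pytest.approx(1.0)

    def test_cosine_bins_match_entropy_arithmetic_oracle(self):
        centres = -np.pi + (2 * np.pi / 20) * (np.arange(20) + 0.5)
        means = 1.0 + np.cos(centres)
        p = means / means.sum()
        h = -np.sum(p[p > 0] * np.log(p[p > 0]))
        expected = (np.log(20) - h) / np.log(20)
        assert coupling.modulation_index(means) == pytest.approx(
            expected, abs=1e-12
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        means = rng.random(20) + 0.1
        base = coupling.modulation_index(means)
        for c in (1e-6, 0.5, 3.0, 1e6):
            assert coupling.modulation_index(c * means) == pytest.approx(
                base, abs=1e-12
            )

    def test_rotation_invariance_by_whole_bins(self, breath_phase):
        """MI is unchanged when the phase is rotated by a multiple of
        the bin width (the binned distribution merely permutes)."""
        rng = np.random.default_rng(6)
        amp = rng.random(breath_phase.phase_rad.size)
        width = 2 * np.pi / 20
        base = coupling.modulation_index(
            coupling.bin_amplitude_by_phase(breath_phase.phase_rad, amp)
        )
        for k in (1, 5, 13):
            rotated = np.angle(np.exp(1j * (breath_phase.phase_rad + k * width)))
            mi = coupling.modulation_index(
                coupling.bin_amplitude_by_phase(rotated, amp)
            )
            assert mi == pytest.approx(base, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            coupling.modulation_index(np.zeros(20))


class TestSurrogateNormalize:
    def test_normalised_mi_definition_holds(self, breath_phase):
        rng = np.random.default_rng(7)
        amp = rng.random(breath_phase.phase_rad.size)
        res = coupling.surrogate_normalize(breath_phase.phase_rad, amp, seed=1)
        assert res.mi_norm == pytest.approx(
            (res.mi_raw - res.surrogate_mean) / res.surrogate_sd
        )
        assert res.n_surrogates == 200

    def test_zero_surrogate_sd_flagged_missing(self):
        # phase uniform over bins, amplitude constant: every surrogate MI
        # equals the observed MI equals 0
        phase = np.tile(np.linspace(-np.pi, np.pi, 200, endpoint=False), 10)
        amp = np.ones(2000)
        with pytest.warns(UserWarning, match="zero surrogate SD"):
            res = coupling.surrogate_normalize(phase, amp, seed=2)
        assert np.isnan(res.mi_norm)

    def test_planted_coupling_detected_strongly(self, breath_phase):
        """Depth-1 coupling at 10 Hz on a 5-min trace: normalised MI
        well above the significance range, across seeds."""
        ph = breath_phase.phase_rad
        grid = spectral.FrequencyGrid(np.array([10.0]))
        for seed in (1, 2, 3):
            x = synth.gen_coupled_signal(ph, 10.0, 1.0, 0.0, 1.0, seed=seed)
            env = spectral.amplitude_envelope(
                spectral.morlet_cwt(x, 300.0, grid), 300.0, grid
            )
            res = coupling.surrogate_normalize(ph, env.values[0, 0], seed=seed)
            assert res.mi_norm > 5.0


class TestDetectInhalationPeaks:
    def test_constant_phase_yields_empty_list(self):
        ph = coupling.PhaseSeries(np.zeros(1000), 100.0)
        with pytest.warns(UserWarning, match="no inhalation peaks"):
            events = coupling.detect_inhalation_peaks(ph)
        assert events.size == 0

    def test_zero_jitter_count_matches_brute_force_scan(self):
        tr = synth.gen_respiration(60.0, 300.0, 4.0, 0.0, seed=5)
        ph = coupling.extract_phase(tr)
        events = coupling.detect_inhalation_peaks(ph)
        oracle = brute_force_peaks(tr.samples, min_gap=600)
        assert events.size == oracle.size
        # events sit at the respiration peaks, not half a cycle away
        assert np.max(np.abs(ph.phase_rad[events])) < 0.1

    def test_refractory_rule_absorbs_small_phase_noise(self, breath_trace):
        ph = coupling.extract_phase(breath_trace)
        clean = coupling.detect_inhalation_peaks(ph, min_period_s=2.0)
        noisy = coupling.PhaseSeries(
            ph.phase_rad
            + 0.01 * np.random.default_rng(8).standard_normal(ph.phase_rad.size),
            ph.rate_hz,
        )
        assert coupling.detect_inhalation_peaks(noisy, 2.0).size == clean.size


class TestPhaseTriggeredAverage:
    def test_output_is_2000_samples_with_zscored_rows(self):
        rng = np.random.default_rng(9)
        env = rng.random((36, 12000)) + 1.0
        events = np.arange(1500, 10500, 900)
        pta = coupling.phase_triggered_average(env, events, halfwin=1000)
        assert pta.values.shape == (36, 2000)
        np.testing.assert_allclose(pta.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(pta.values.std(axis=1), 1.0, atol=1e-9)

    def test_incomplete_windows_dropped_and_counted(self):
        env = np.random.default_rng(10).random((3, 5000))
        events = np.array([100, 2500, 4900])  # first and last incomplete
        pta = coupling.phase_triggered_average(env, events, halfwin=1000)
        assert pta.n_events == 1 and pta.n_dropped_events == 2

    def test_constant_rows_reported_missing(self):
        env = np.ones((2, 6000))
        with pytest.warns(UserWarning, match="constant PTA rows"):
            pta = coupling.phase_triggered_average(
                env, np.array([3000]), halfwin=1000
            )
        assert np.all(np.isnan(pta.values))

    def test_planted_preferred_phase_zero_peaks_at_window_centre(
        self, breath_trace, breath_phase
    ):
        """Noiseless depth-1 coupling with preferred phase 0: the PTA of
        the carrier row is maximal at the inhalation-peak centre."""
        ph = breath_phase.phase_rad
        grid = spectral.FrequencyGrid(np.array([10.0]))
        x = synth.gen_coupled_signal(ph, 10.0, 1.0, 0.0, np.inf, seed=11)
        env = spectral.amplitude_envelope(
            spectral.morlet_cwt(x, 300.0, grid), 300.0, grid
        ).values[0]
        events = coupling.detect_inhalation_peaks(breath_phase)
        pta = coupling.phase_triggered_average(env, events, halfwin=1000)
        peak_offset = abs(int(np.argmax(pta.values[0])) - 1000)
        assert peak_offset < 60  # within 0.2 s of the centre

    def test_zero_retained_events_is_an_error(self):
        env = np.random.default_rng(12).random((2, 1500))
        with pytest.raises(ValueError, match="no events"):
            coupling.phase_triggered_average(env, np.array([10]), halfwin=1000)


@pytest.fixture(scope="module")
def planted_dataset():
    gt = synth.SyntheticGroundTruth(
        couplings=[synth.Coupling(10.0, 1.0, 0.0, (5,))],
        snr=1.5,
        seed=13,
    )
    return synth.gen_subject_dataset(gt, 1, 8, duration_s=120.0, rate_hz=300.0)


class TestMIMap:
    def test_argmax_at_planted_entity_and_frequency(self, planted_dataset,
                                                    grid36):
        """The map's argmax lands on the coupled entity at the carrier
        frequency. The Morlet bandwidth at 10 Hz (~1.7 Hz at omega0=6)
        exceeds the 2-Hz grid spacing, so adjacent rows carry nearly
        the same modulation; the frequency is asserted to within one
        grid step."""
        res = coupling.mi_map(planted_dataset.subjects[0], grid36, seed=14)
        assert res.mi_norm.shape == (8, 36)
        ent, fidx = np.unravel_index(np.argmax(res.mi_norm), res.mi_norm.shape)
        assert ent == 5
        assert abs(grid36.freqs_hz[fidx] - 10.0) <= 2.0
        # the coupled entity's spectrum is overwhelmingly significant at
        # the carrier itself
        assert res.mi_norm[5, np.flatnonzero(grid36.freqs_hz == 10.0)[0]] > 5.0

    def test_map_deterministic_in_master_seed(self, planted_dataset, grid36):
        small = spectral.FrequencyGrid(np.array([8.0, 10.0]))
        a = coupling.mi_map(planted_dataset.subjects[0], small, seed=15,
                            n_surrogates=50)
        b = coupling.mi_map(planted_dataset.subjects[0], small, seed=15,
                            n_surrogates=50)
        np.testing.assert_array_equal(a.mi_norm, b.mi_norm)
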