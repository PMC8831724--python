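"""Clipping detection, context spectra, colored-noise synthesis, and repair."""

import numpy as np
import pytest
from scipy.signal import periodogram

from somnoscore.core import BandScheme, Recording
from somnoscore.repair import (
    ArtifactReport,
    FaultyInterval,
    RepairParams,
    context_spectrum,
    detect_clipped_intervals,
    repair_recording,
    synthesize_colored_noise,
)
from somnoscore.synth import GenConfig, synthesize_recording

RAIL = 500.0
FS = 128.0


def _signal_with_pinned(runs, n=2000, level=RAIL):
    x = np.zeros(n)
    for s, e in runs:
        x[s:e] = level
    return x


class TestDetect:
    def test_single_pinned_run(self):
        x = _signal_with_pinned([(100, 120)])
        out = detect_clipped_intervals(x, RAIL, min_run=8, merge_gap_samples=0, pad_samples=0)
        assert [(iv.start_sample, iv.end_sample) for iv in out] == [(100, 120)]

    def test_nearby_runs_merge(self):
        x = _signal_with_pinned([(100, 110), (114, 124)])
        out = detect_clipped_intervals(x, RAIL, min_run=4, merge_gap_samples=8, pad_samples=0)
        assert [(iv.start_sample, iv.end_sample) for iv in out] == [(100, 124)]

    def test_subthreshold_sinusoid_clean(self):
        t = np.arange(4096) / FS
        x = 0.5 * RAIL * np.sin(2 * np.pi * 2 * t)
        assert detect_clipped_intervals(x, RAIL) == []

    def test_short_runs_ignored(self):
        x = _signal_with_pinned([(100, 102)])
        assert detect_clipped_intervals(x, RAIL, min_run=4) == []

    def test_padding_clamped_to_recording(self):
        x = _signal_with_pinned([(0, 10)], n=100)
        out = detect_clipped_intervals(x, RAIL, pad_samples=16)
        assert out[0].start_sample == 0
        assert out[0].end_sample == 26

    def test_empty_signal(self):
        assert detect_clipped_intervals(np.array([]), RAIL) == []

    def test_bad_rail_fraction_rejected(self):
        with pytest.raises(ValueError):
            detect_clipped_intervals(np.zeros(10), RAIL, rail_fraction=0.0)

    def test_output_disjoint_and_sorted(self, rng):
        x = rng.normal(0, 50, 20000)
        for _ in range(30):
            s = rng.integers(0, 19000)
            x[s : s + rng.integers(4, 200)] = RAIL
        out = detect_clipped_intervals(x, RAIL)
        for a, b in zip(out, out[1:]):
            assert a.end_sample < b.start_sample


class TestContextSpectrum:
    def test_sinusoid_concentrates_at_tone(self):
        t = np.arange(8192) / FS
        x = 30 * np.sin(2 * np.pi * 4 * t)
        iv = FaultyInterval(4000, 4200)
        freqs, psd = context_spectrum(x, iv, FS, context_len_samples=512)
        near = np.abs(freqs - 4.0) <= FS / 512 + 1e-9  # +-1 bin of the flank grid
        assert psd[near].sum() / psd.sum() >= 0.95

    def test_white_noise_total_power_matches_variance(self, rng):
        # Parseval: integrating the flank PSD recovers sigma^2 (Monte Carlo)
        sigma = 20.0
        totals = []
        for _ in range(100):
            x = rng.normal(0, sigma, 3000)
            freqs, psd = context_spectrum(x, FaultyInterval(1400, 1600), FS)
            totals.append(np.trapezoid(psd, freqs))
        assert np.mean(totals) == pytest.approx(sigma**2, rel=0.1)

    def test_interval_at_start_uses_right_flank_only(self, rng):
        x = rng.normal(0, 10, 2000)
        iv = FaultyInterval(0, 100)
        freqs, psd = context_spectrum(x, iv, FS, context_len_samples=512)
        f2, p2 = periodogram(x[100:612], fs=FS, window="hann", scaling="density")
        assert np.allclose(freqs, f2)
        assert np.allclose(psd, p2)

    def test_no_clean_flank_falls_back_to_whole_signal(self, rng, caplog):
        x = rng.normal(0, 10, 1024)
        intervals = [FaultyInterval(0, 500), FaultyInterval(510, 1024)]
        with caplog.at_level("WARNING"):
            freqs, psd = context_spectrum(x, intervals[0], FS, exclude=intervals)
        assert psd.size > 0 and np.all(psd >= 0)


class TestSynthesizeNoise:
    def test_zero_psd_gives_zeros(self):
        freqs = np.linspace(0, 64, 100)
        out = synthesize_colored_noise((freqs, np.zeros(100)), 1024, FS, rng=0)
        assert np.array_equal(out, np.zeros(1024))

    def test_exact_length_and_determinism(self):
        freqs = np.linspace(0, 64, 100)
        psd = np.ones(100)
        a = synthesize_colored_noise((freqs, psd), 777, FS, rng=5)
        b = synthesize_colored_noise((freqs, psd), 777, FS, rng=5)
        assert a.shape == (777,)
        assert np.array_equal(a, b)

    def test_flat_target_yields_flat_ensemble_psd(self):
        # octave-averaged ensemble PSD within +-10% of the flat target
        freqs = np.linspace(0, 64, 129)
        target_val = 2.0
        acc = None
        for seed in range(200):
            y = synthesize_colored_noise((freqs, np.full(129, target_val)), 1024, FS, rng=seed)
            f, p = periodogram(y, fs=FS)
            acc = p if acc is None else acc + p
        mean_psd = acc / 200
        for lo, hi in [(0.5, 1), (1, 2), (2, 4), (4, 8), (8, 16), (16, 32), (32, 63)]:
            band = (f >= lo) & (f < hi)
            assert np.mean(mean_psd[band]) == pytest.approx(target_val, rel=0.10)

    def test_delta_dominant_template_band_ratios(self):
        # ensemble band powers of synthesized noise match the target ratios
        scheme = BandScheme()
        freqs = np.arange(0, 64.001, 0.25)
        weights = {"delta": 0.6, "theta": 0.15, "alpha": 0.1, "beta": 0.1, "gamma": 0.05}
        psd = np.zeros(freqs.size)
        for name, w in weights.items():
            band = scheme.band(name)
            mask = scheme.band_mask(freqs, band)
            psd[mask] = w / (band.high_hz - band.low_hz)
        band_power = {name: 0.0 for name in weights}
        for seed in range(200):
            y = synthesize_colored_noise((freqs, psd), 1024, FS, rng=seed)
            f, p = periodogram(y, fs=FS)
            for name in weights:
                band_power[name] += p[scheme.band_mask(f, name)].sum()
        total = sum(band_power.values())
        for name, w in weights.items():
            assert band_power[name] / total == pytest.approx(w, rel=0.10)


class TestRepairRecording:
    @pytest.fixture()
    def clipped_recording(self, rng):
        n = 128 * 600
        eeg = np.clip(rng.normal(0, 50, n), -RAIL, RAIL)
        injected = np.zeros(n, dtype=bool)
        for s in (5000, 20000, 40000, 60000):
            eeg[s : s + 300] = RAIL
            injected[s : s + 300] = True
        rec = Recording(eeg=eeg, motion=np.ones(n), adc_rail=RAIL)
        return rec, injected

    def test_clean_recording_unchanged(self, rng):
        n = 128 * 60
        rec = Recording(eeg=np.clip(rng.normal(0, 50, n), -RAIL, RAIL),
                        motion=np.ones(n), adc_rail=RAIL)
        out, report = repair_recording(rec, rng_seed=0)
        assert np.array_equal(out.eeg, rec.eeg)
        assert report.corrected_fraction == 0.0
        assert report.intervals == []

    def test_conservation_outside_flagged_intervals(self, clipped_recording):
        rec, _ = clipped_recording
        out, report = repair_recording(rec, rng_seed=3)
        mask = np.zeros(rec.n_samples, dtype=bool)
        for iv in report.intervals:
            mask[iv.start_sample : iv.end_sample] = True
        assert np.array_equal(out.eeg[~mask], rec.eeg[~mask])

    def test_corrected_fraction_is_exact_flagged_share(self, clipped_recording):
        rec, _ = clipped_recording
        _, report = repair_recording(rec, rng_seed=3)
        flagged = sum(len(iv) for iv in report.intervals)
        assert report.corrected_fraction == flagged / rec.n_samples

    def test_determinism(self, clipped_recording):
        rec, _ = clipped_recording
        a, _ = repair_recording(rec, rng_seed=11)
        b, _ = repair_recording(rec, rng_seed=11)
        assert np.array_equal(a.eeg, b.eeg)

    def test_idempotence(self, clipped_recording):
        rec, _ = clipped_recording
        once, _ = repair_recording(rec, rng_seed=4)
        twice, report2 = repair_recording(once, rng_seed=4)
        assert report2.intervals == []
        assert np.array_equal(once.eeg, twice.eeg)

    def test_detected_extent_close_to_injected(self):
        # 1-h recording with ~2% clipping injected by the generator
        rec, _, injected = synthesize_recording(GenConfig(), duration_s=3600.0, seed=21)
        _, report = repair_recording(rec, rng_seed=21)
        ratio = report.corrected_fraction / injected.mean()
        assert 0.8 <= ratio <= 1.5

    def test_replacement_spectrum_matches_context(self):
        # stationary delta-heavy input: ensemble band powers of the
        # replacement converge to those of the surrounding signal
        scheme = BandScheme()
        cfg = GenConfig(clip_rate=0.0)
        gap = (6000, 6512)
        band_repl = np.zeros(len(scheme.bands))
        band_ctx = np.zeros(len(scheme.bands))
        for seed in range(200):
            rec, _, _ = synthesize_recording(
                cfg, duration_s=96.0, seed=seed,
            )
            eeg = rec.eeg.copy()
            eeg[gap[0]: gap[1]] = RAIL  # inject one clipped stretch
            rec2 = rec.replace_eeg(eeg)
            out, report = repair_recording(rec2, rng_seed=seed)
            iv = report.intervals[0]
            f, p = periodogram(out.eeg[iv.start_sample: iv.end_sample], fs=FS)
            fc, pc = periodogram(rec.eeg[gap[0] - 512: gap[0]], fs=FS)
            for i, band in enumerate(scheme.bands):
                band_repl[i] += p[scheme.band_mask(f, band)].sum()
                band_ctx[i] += pc[scheme.band_mask(fc, band)].sum()
        rel_repl = band_repl / band_repl.sum()
        rel_ctx = band_ctx / band_ctx.sum()
        assert np.all(np.abs(rel_repl - rel_ctx) / rel_ctx < 0.10)

    def test_report_serializes(self, clipped_recording):
        rec, _ = clipped_recording
        _, report = repair_recording(rec, rng_seed=3)
        d = report.to_dict()
        assert d["n_samples"] == rec.n_samples
        assert len(d["intervals"]) == len(report.intervals)
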