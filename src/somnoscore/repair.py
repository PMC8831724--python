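"""Detection and repair of clipping artifacts in EEG recordings.

Short electrode contact losses pin the EEG at the digitizer rail.  Left in
place, those flat saturated stretches corrupt every spectrum-based quantity
computed later, so they are detected and replaced with colored Gaussian
noise whose power spectrum matches the clean signal flanking the fault.
The replacement has exactly the length of the faulty section, which keeps
the epoch grid and all aggregate spectral features intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import Recording

__all__ = [
    "FaultyInterval",
    "ArtifactReport",
    "RepairParams",
    "detect_clipped_intervals",
    "context_spectrum",
    "synthesize_colored_noise",
    "repair_recording",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FaultyInterval:
    """Half-open sample interval [start_sample, end_sample) flagged as faulty."""

    start_sample: int
    end_sample: int
    cause: str = "clipping"

    def __post_init__(self) -> None:
        if self.start_sample >= self.end_sample:
            raise ValueError("start_sample must be < end_sample")

    def __len__(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class ArtifactReport:
    """What was repaired: flagged intervals and the fraction of samples replaced."""

    intervals: list[FaultyInterval]
    corrected_fraction: float
    n_samples: int
    context_psd_per_interval: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "corrected_fraction": self.corrected_fraction,
            "intervals": [
                {"start_sample": iv.start_sample, "end_sample": iv.end_sample, "cause": iv.cause}
                for iv in self.intervals
            ],
        }


@dataclass
class RepairParams:
    """Detector and synthesis parameters.

    The clipping criterion is |x| >= ``rail_fraction`` x rail for at least
    ``min_run`` consecutive samples (4 samples = 31.25 ms at 128 Hz, long
    enough to ignore single-sample spikes).  Nearby runs separated by at
    most ``merge_gap_samples`` are merged and each merged run is padded by
    ``pad_samples`` of neighboring signal, so the distorted onset/offset of
    the contact loss is replaced too.  ``context_len_samples`` (4 s at
    128 Hz) sets the flanking window used to estimate the replacement
    spectrum, and ``crossfade_samples`` the raised-cosine splice length.
    """

    rail_fraction: float = 0.99
    min_run: int = 4
    merge_gap_samples: int = 32
    pad_samples: int = 16
    context_len_samples: int = 512
    crossfade_samples: int = 16

    def __post_init__(self) -> None:
        if not 0 < self.rail_fraction <= 1:
            raise ValueError("rail_fraction must be in (0, 1]")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as half-open (start, end) pairs."""
    if mask.size == 0 or not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_clipped_intervals(
    eeg: np.ndarray,
    adc_rail: float,
    rail_fraction: float = 0.99,
    min_run: int = 4,
    merge_gap_samples: int = 32,
    pad_samples: int = 16,
) -> list[FaultyInterval]:
    """Find rail-pinned stretches of the EEG.

    Every maximal run of at least ``min_run`` consecutive samples with
    |x| >= rail_fraction x adc_rail is flagged; runs separated by at most
    ``merge_gap_samples`` are merged; each merged run is extended by
    ``pad_samples`` on both sides (clamped to the recording).  The result
    is disjoint and sorted.
    """
    if rail_fraction <= 0:
        raise ValueError("rail_fraction must be positive")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    eeg = np.asarray(eeg)
    n = eeg.size
    if n == 0:
        return []
    runs = [
        (s, e)
        for s, e in _runs_from_mask(np.abs(eeg) >= rail_fraction * adc_rail)
        if e - s >= min_run
    ]
    if not runs:
        return []
    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= merge_gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    padded = []
    for s, e in merged:
        s, e = max(0, s - pad_samples), min(n, e + pad_samples)
        if padded and s <= padded[-1][1]:
            padded[-1][1] = max(padded[-1][1], e)
        else:
            padded.append([s, e])
    return [FaultyInterval(s, e) for s, e in padded]


def _clean_flank(n: int, anchor: int, direction: int, length: int,
                 exclude: list[FaultyInterval]) -> tuple[int, int] | None:
    """Longest clean window of up to ``length`` samples left/right of ``anchor``.

    ``direction`` -1 looks left of anchor (window ends at anchor), +1 looks
    right (window starts at anchor).  The window shrinks at neighboring
    faulty intervals.  Returns None if no clean sample is available.
    """
    if direction < 0:
        lo, hi = max(0, anchor - length), anchor
        for iv in exclude:
            if iv.end_sample <= anchor:
                lo = max(lo, iv.end_sample)
    else:
        lo, hi = anchor, min(n, anchor + length)
        for iv in exclude:
            if iv.start_sample >= anchor:
                hi = min(hi, iv.start_sample)
    if hi - lo <= 0:
        return None
    return lo, hi


def _hann_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Single Hanning-windowed periodogram as a one-sided PSD (density)."""
    freqs, psd = sps.periodogram(x, fs=fs, window="hann", detrend="constant",
                                 scaling="density")
    return freqs, psd


def context_spectrum(
    eeg: np.ndarray,
    interval: FaultyInterval,
    fs: float,
    context_len_samples: int = 512,
    exclude: list[FaultyInterval] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """PSD of the clean signal flanking a faulty interval.

    The mean of the Hanning-windowed periodograms of the left and right
    flanking windows (one flank when only one exists).  When no clean flank
    exists anywhere near the interval, the PSD of the whole non-faulty
    signal is used instead (logged).  Returns ``(freqs, psd)`` as a
    one-sided density; the synthesis step interpolates it onto whatever bin
    grid the replacement length requires.
    """
    eeg = np.asarray(eeg, dtype=float)
    n = eeg.size
    exclude = list(exclude) if exclude else [interval]
    flanks = []
    for direction, anchor in ((-1, interval.start_sample), (+1, interval.end_sample)):
        win = _clean_flank(n, anchor, direction, context_len_samples, exclude)
        if win is not None and win[1] - win[0] >= 8:  # too-short windows are useless
            flanks.append(eeg[win[0]: win[1]])
    if not flanks:
        logger.warning(
            "no clean flank around samples %d-%d; using whole-signal PSD",
            interval.start_sample, interval.end_sample,
        )
        mask = np.ones(n, dtype=bool)
        for iv in exclude:
            mask[iv.start_sample: iv.end_sample] = False
        clean = eeg[mask]
        if clean.size < 8:
            # pathological: nothing clean at all -> flat zero spectrum
            freqs = np.fft.rfftfreq(max(int(fs), 8), d=1.0 / fs)
            return freqs, np.zeros_like(freqs)
        return _hann_psd(clean, fs)
    spectra = [_hann_psd(f, fs) for f in flanks]
    if len(spectra) == 1:
        return spectra[0]
    # Flanks may differ in length; average on the denser frequency grid.
    (f0, p0), (f1, p1) = spectra
    if f0.size >= f1.size:
        return f0, 0.5 * (p0 + np.interp(f0, f1, p1))
    return f1, 0.5 * (np.interp(f1, f0, p0) + p1)


def synthesize_colored_noise(
    target_psd: tuple[np.ndarray, np.ndarray],
    n_samples: int,
    fs: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Gaussian noise of length ``n_samples`` with the given power spectrum.

    White Gaussian noise is drawn, its amplitude spectrum shaped in the
    frequency domain proportional to sqrt(PSD) (Hermitian symmetry holds by
    construction since the shaping is applied to the rFFT of a real
    sequence), and the result rescaled so its sample variance equals the
    variance implied by the target PSD.  Deterministic given the rng/seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    freqs, psd = target_psd
    psd = np.asarray(psd, dtype=float)
    if np.any(psd < 0):
        raise ValueError("target PSD must be nonnegative")
    target_var = float(np.trapezoid(psd, freqs))
    if target_var <= 0:
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    grid = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.sqrt(np.interp(grid, freqs, psd, left=psd[0], right=psd[-1]))
    colored = np.fft.irfft(np.fft.rfft(white) * shape, n=n_samples)
    sd = colored.std()
    if sd == 0:
        return np.zeros(n_samples)
    return colored * (np.sqrt(target_var) / sd)


def _child_seed(master_seed: int, index: int) -> np.random.Generator:
    """Per-interval generator so edits to one interval do not perturb others."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) % 2**31, index]))


def repair_recording(
    rec: Recording,
    params: RepairParams | None = None,
    rng_seed: int = 0,
) -> tuple[Recording, ArtifactReport]:
    """Replace clipped stretches with context-matched colored noise.

    Samples outside the flagged (padded) intervals are bit-identical to the
    input.  Inside each interval the synthesized noise is spliced in with a
    raised-cosine crossfade at each interior boundary; the crossfade lies
    within the padded region, which consists of clean signal, so continuity
    never reintroduces rail-pinned values.  Running detection on the output
    with the same parameters finds nothing, making the repair idempotent.
    """
    params = params or RepairParams()
    intervals = detect_clipped_intervals(
        rec.eeg,
        rec.adc_rail,
        rail_fraction=params.rail_fraction,
        min_run=params.min_run,
        merge_gap_samples=params.merge_gap_samples,
        pad_samples=params.pad_samples,
    )
    n = rec.n_samples
    out = rec.eeg.copy()
    psds = []
    for k, iv in enumerate(intervals):
        target = context_spectrum(
            rec.eeg, iv, rec.sample_rate_hz,
            context_len_samples=params.context_len_samples, exclude=intervals,
        )
        psds.append(target)
        m = len(iv)
        noise = synthesize_colored_noise(target, m, rec.sample_rate_hz, _child_seed(rng_seed, k))
        # Keep the replacement inside the rails so detection cannot re-fire.
        np.clip(noise, -params.rail_fraction * rec.adc_rail * 0.999,
                params.rail_fraction * rec.adc_rail * 0.999, out=noise)
        env = np.ones(m)
        c = min(params.crossfade_samples, m // 2)
        if c > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(c) + 1) / (c + 1)))
            if iv.start_sample > 0:
                env[:c] = ramp
            if iv.end_sample < n:
                env[m - c:] = ramp[::-1]
        out[iv.start_sample: iv.end_sample] = (
            env * noise + (1 - env) * rec.eeg[iv.start_sample: iv.end_sample]
        )
    n_flagged = int(sum(len(iv) for iv in intervals))
    report = ArtifactReport(
        intervals=intervals,
        corrected_fraction=n_flagged / n if n else 0.0,
        n_samples=n,
        context_psd_per_interval=psds,
    )
    return rec.replace_eeg(out), report
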