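"""Per-epoch handcrafted features for stage classification.

Twelve features per 8-s epoch: mean amplitude and standard deviation of the
band-limited EEG in each of the five analysis bands (delta, theta, alpha,
beta, low gamma), the standard deviation of the motion magnitude, and the
Petrosian fractal dimension of the raw epoch.  Band decomposition uses
discrete-Fourier masking, so the five bands tile the 0.5-48 Hz analysis
range exactly and band variances add up to the variance of the band-limited
epoch to machine precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BandScheme, EpochGrid, Recording, epoch_view

__all__ = [
    "FEATURE_COLUMNS",
    "band_component",
    "band_features",
    "petrosian_fd",
    "motion_sd",
    "extract_features",
]

_SCHEME = BandScheme()

#: Fixed feature order: per-band mean amplitudes, per-band SDs, motion SD, PFD.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    [f"{b}_mean_amp" for b in _SCHEME.names]
    + [f"{b}_sd" for b in _SCHEME.names]
    + ["motion_sd", "pfd"]
)


def band_component(
    epoch_eeg: np.ndarray,
    band: tuple[float, float],
    fs: float = 128.0,
    scheme: BandScheme | None = None,
) -> np.ndarray:
    """Band-limited reconstruction of an epoch by Fourier masking.

    All rFFT bins outside [low, high) are zeroed (the top analysis band is
    closed at its upper edge) and the spectrum inverse-transformed.  The
    operation is linear, deterministic, and idempotent.
    """
    low, high = band
    if low >= high:
        raise ValueError(f"inverted band: low={low} >= high={high}")
    if high > fs / 2 + 1e-12:
        raise ValueError(f"band edge {high} Hz above Nyquist {fs / 2} Hz")
    scheme = scheme or _SCHEME
    x = np.asarray(epoch_eeg, dtype=float)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    mask = (freqs >= low) & (freqs < high)
    if high == scheme.analysis_high_hz:
        mask |= freqs == high
    spec = np.fft.rfft(x)
    spec[~mask] = 0.0
    return np.fft.irfft(spec, n=x.size)


def band_features(
    epoch_eeg: np.ndarray,
    fs: float = 128.0,
    scheme: BandScheme | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean rectified amplitude and population SD per band for one epoch."""
    scheme = scheme or _SCHEME
    x = np.asarray(epoch_eeg, dtype=float)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    mean_amp = np.empty(len(scheme.bands))
    sd = np.empty(len(scheme.bands))
    for i, band in enumerate(scheme.bands):
        masked = np.where(scheme.band_mask(freqs, band), spec, 0.0)
        comp = np.fft.irfft(masked, n=x.size)
        mean_amp[i] = np.mean(np.abs(comp))
        sd[i] = np.std(comp)  # population (ddof=0)
    return mean_amp, sd


def petrosian_fd(series: np.ndarray) -> float:
    """Petrosian fractal dimension of a waveform.

    PFD = log10(n) / (log10(n) + log10(n / (n + 0.4 * N_delta))) where
    N_delta counts sign changes in the first-difference sequence.  Zero
    differences are dropped before counting, so plateaus do not register as
    changes; a strictly monotone (or constant) series gives PFD = 1 exactly.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Petrosian fractal dimension needs at least 3 samples")
    signs = np.sign(np.diff(x))
    signs = signs[signs != 0]
    n_delta = int(np.count_nonzero(np.diff(signs) != 0)) if signs.size > 1 else 0
    log_n = np.log10(n)
    return float(log_n / (log_n + np.log10(n / (n + 0.4 * n_delta))))


def motion_sd(epoch_motion: np.ndarray) -> float:
    """Population standard deviation of the motion magnitude within an epoch."""
    return float(np.std(np.asarray(epoch_motion, dtype=float)))


def extract_features(
    rec: Recording,
    grid: EpochGrid | None = None,
    scheme: BandScheme | None = None,
) -> pd.DataFrame:
    """Feature table: one row per epoch, columns in ``FEATURE_COLUMNS`` order.

    Features of epoch *i* depend only on the samples of epoch *i*; trailing
    samples beyond the last full epoch are ignored.  Run this on a repaired
    recording — clipped stretches otherwise leak rail-flat segments into
    the band amplitudes.
    """
    grid = grid or EpochGrid.from_recording(rec)
    scheme = scheme or _SCHEME
    eeg = epoch_view(rec.eeg, grid)
    motion = epoch_view(rec.motion, grid, rate_hz=rec.motion_rate_hz)
    rows = np.empty((grid.n_epochs, len(FEATURE_COLUMNS)))
    nb = len(scheme.bands)
    for i in range(grid.n_epochs):
        amp, sd = band_features(eeg[i], fs=rec.sample_rate_hz, scheme=scheme)
        rows[i, :nb] = amp
        rows[i, nb: 2 * nb] = sd
        rows[i, 2 * nb] = motion_sd(motion[i])
        rows[i, 2 * nb + 1] = petrosian_fd(eeg[i])
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    df.index.name = "epoch_index"
    return df
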