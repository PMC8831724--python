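"""Per-epoch power spectra and stage/phase-resolved spectral summaries.

Each 8-s epoch at 128 Hz yields a one-sided Hanning-windowed periodogram
with exactly 0.125 Hz bin spacing.  Total absolute band power is the sum of
bin powers inside a band; relative power divides each bin by the total
power in the 0.5-48 Hz analysis range, so per-epoch relative powers sum to
one.  Summaries average relative power per bin over the epochs of a stage,
substage, or light/dark phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .core import (
    ACTIVE,
    QUIET,
    STAGES,
    WAKE,
    BandScheme,
    EpochGrid,
    Hypnogram,
    Recording,
    epoch_view,
    phase_labels,
)

__all__ = [
    "epoch_power_spectrum",
    "spectrum_table",
    "total_absolute_power",
    "band_power_table",
    "relative_power",
    "SpectralSummary",
    "aggregate",
]

logger = logging.getLogger(__name__)

_SCHEME = BandScheme()


def epoch_power_spectrum(epoch_eeg: np.ndarray, fs: float = 128.0) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of a single epoch.

    The epoch is mean-removed, Hanning-windowed, and transformed; the
    spectrum is scaled so that the sum of power over all bins equals the
    power of the windowed epoch divided by the window's mean square
    (Parseval-consistent, window-gain corrected).  For an 8-s epoch at
    128 Hz the bin spacing is exactly 0.125 Hz.

    Returns ``(freqs, power)`` with power in µV².
    """
    x = np.asarray(epoch_eeg, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("epoch too short for a spectrum")
    w = get_window("hann", n, fftbins=True)
    xw = (x - x.mean()) * w
    spec = np.fft.rfft(xw)
    power = np.abs(spec) ** 2
    # one-sided: double interior bins (DC and, for even n, Nyquist are unique)
    scale = np.full(power.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power *= scale
    power /= n * np.sum(w**2)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, power


def spectrum_table(rec: Recording, grid: EpochGrid | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Spectra for every epoch: ``(freqs, power)`` with power (n_epochs, n_bins)."""
    grid = grid or EpochGrid.from_recording(rec)
    epochs = epoch_view(rec.eeg, grid)
    freqs = np.fft.rfftfreq(grid.samples_per_epoch, d=1.0 / rec.sample_rate_hz)
    power = np.empty((grid.n_epochs, freqs.size))
    for i in range(grid.n_epochs):
        _, power[i] = epoch_power_spectrum(epochs[i], fs=rec.sample_rate_hz)
    return freqs, power


def total_absolute_power(
    freqs: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] | str,
    scheme: BandScheme | None = None,
) -> np.ndarray | float:
    """Sum of bin powers inside a band (half-open; top band closed at 48 Hz).

    ``power`` may be a single spectrum or an (n_epochs, n_bins) stack; a
    named band uses the scheme's membership rule, an explicit (low, high)
    tuple uses plain half-open membership (empty if low == high).
    """
    scheme = scheme or _SCHEME
    freqs = np.asarray(freqs)
    if isinstance(band, str):
        mask = scheme.band_mask(freqs, band)
    else:
        low, high = band
        mask = (freqs >= low) & (freqs < high)
        if high == scheme.analysis_high_hz:
            mask |= freqs == high
    out = np.asarray(power)[..., mask].sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def relative_power(
    freqs: np.ndarray,
    power: np.ndarray,
    scheme: BandScheme | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin relative power over the analysis range (sums to 1 per epoch).

    Returns ``(analysis_freqs, rel)``.  Epochs with zero total power are
    undefined and returned as NaN rows (excluded and logged during
    aggregation).
    """
    scheme = scheme or _SCHEME
    freqs = np.asarray(freqs)
    mask = scheme.analysis_mask(freqs)
    p = np.atleast_2d(np.asarray(power, dtype=float))[:, mask]
    total = p.sum(axis=1, keepdims=True)
    rel = np.full_like(p, np.nan)
    ok = total[:, 0] > 0
    rel[ok] = p[ok] / total[ok]
    if np.asarray(power).ndim == 1:
        return freqs[mask], rel[0]
    return freqs[mask], rel


@dataclass
class SpectralSummary:
    """Mean relative power per bin and mean total power, per aggregation key."""

    freqs: np.ndarray
    rel: pd.DataFrame          # index: key, columns: analysis-bin frequencies
    total_power: pd.Series     # mean total power (0.5-48 Hz) per key
    n_epochs: pd.Series        # epoch count per key

    def to_long(self) -> pd.DataFrame:
        long = (
            self.rel.reset_index(names="key")
            .melt(id_vars="key", var_name="freq_hz", value_name="mean_relative_power")
        )
        long["freq_hz"] = long["freq_hz"].astype(float)
        counts = self.n_epochs.rename("n_epochs").rename_axis("key").reset_index()
        long = long.merge(counts, on="key")
        return long.sort_values(["key", "freq_hz"]).reset_index(drop=True)

    def band_table(self, scheme: BandScheme | None = None) -> pd.DataFrame:
        """Mean relative power summed per band, one row per (key, band)."""
        scheme = scheme or _SCHEME
        rows = []
        for key, rel_row in self.rel.iterrows():
            for band in scheme.bands:
                mask = scheme.band_mask(self.freqs, band)
                rows.append(
                    {
                        "key": key,
                        "band": band.name,
                        "mean_relative_power": float(rel_row.to_numpy()[mask].sum()),
                        "mean_total_power": float(self.total_power[key]),
                        "n_epochs": int(self.n_epochs[key]),
                    }
                )
        return pd.DataFrame(rows)


def _keys_for(by: str, h: Hypnogram, phases: np.ndarray) -> np.ndarray:
    if by == "whole":
        return np.full(len(h), "all", dtype="<U16")
    if by == "stage":
        return h.stages.astype("<U16")
    if by == "substage":
        keys = h.stages.astype("<U16").copy()
        keys[h.stages == WAKE] = h.substages[h.stages == WAKE]
        return keys
    if by == "phase":
        return phases.astype("<U16")
    if by == "stage_phase":
        return np.char.add(np.char.add(h.stages.astype("<U16"), "/"), phases.astype("<U16"))
    raise ValueError(f"unknown aggregation key {by!r}")


def aggregate(
    freqs: np.ndarray,
    power: np.ndarray,
    h: Hypnogram,
    rec: Recording,
    grid: EpochGrid,
    by: str = "stage",
    scheme: BandScheme | None = None,
) -> SpectralSummary:
    """Average relative spectra over epochs sharing a key.

    ``by`` is one of ``whole``, ``stage``, ``substage`` (wake split into
    ACTIVE/QUIET, sleep stages kept), ``phase`` (light/dark), or
    ``stage_phase``.  Epochs whose phase falls outside the analyzed window
    and epochs with undefined (zero-power) spectra are excluded; keys with
    zero remaining epochs are absent from the output (logged).
    """
    scheme = scheme or _SCHEME
    if len(h) != power.shape[0]:
        raise ValueError("hypnogram and spectra are misaligned")
    phases = phase_labels(rec, grid)[: len(h)]
    keys = _keys_for(by, h, phases)
    afreqs, rel = relative_power(freqs, power, scheme=scheme)
    total = np.asarray(power)[:, scheme.analysis_mask(freqs)].sum(axis=1)
    defined = ~np.isnan(rel).any(axis=1)
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("excluding %d zero-power epochs from aggregation", n_undef)
    usable = defined & (phases != "excluded")

    rel_rows, totals, counts = {}, {}, {}
    for key in np.unique(keys[usable]):
        sel = usable & (keys == key)
        rel_rows[key] = rel[sel].mean(axis=0)
        totals[key] = float(total[sel].mean())
        counts[key] = int(sel.sum())
    if not rel_rows:
        logger.warning("no epochs to aggregate for by=%r", by)
    rel_df = pd.DataFrame.from_dict(rel_rows, orient="index", columns=afreqs)
    rel_df.index.name = "key"
    return SpectralSummary(
        freqs=afreqs,
        rel=rel_df,
        total_power=pd.Series(totals, name="mean_total_power"),
        n_epochs=pd.Series(counts, name="n_epochs"),
    )


def band_power_table(
    freqs: np.ndarray,
    power: np.ndarray,
    scheme: BandScheme | None = None,
) -> pd.DataFrame:
    """Per-epoch total absolute power per band (µV²), columns named by band."""
    scheme = scheme or _SCHEME
    out = {}
    for band in scheme.bands:
        out[band.name] = np.atleast_2d(power)[:, scheme.band_mask(freqs, band)].sum(axis=1)
    df = pd.DataFrame(out)
    df.index.name = "epoch_index"
    return df
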