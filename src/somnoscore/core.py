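"""Core data containers: recordings, epoch grids, hypnograms, band schemes.

A :class:`Recording` holds a continuous single-channel EEG trace (µV) together
with a motion-magnitude trace from a 3-axis accelerometer (G), the sampling
metadata, and the light/dark schedule of the recording session.  Scoring and
spectral analysis operate on a fixed :class:`EpochGrid` (8-s epochs by
default); stage labels live in a :class:`Hypnogram` aligned to that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "STAGES",
    "SUBSTAGES",
    "WAKE",
    "NREM",
    "REM",
    "ACTIVE",
    "QUIET",
    "NA",
    "Recording",
    "EpochGrid",
    "Hypnogram",
    "Band",
    "BandScheme",
    "DEFAULT_BANDS",
    "epoch_view",
    "phase_labels",
    "phase_labels_from_schedule",
    "light_mask",
]

WAKE, NREM, REM = "WAKE", "NREM", "REM"
ACTIVE, QUIET, NA = "ACTIVE", "QUIET", "NA"

#: Canonical stage order, also the deterministic tie-break order in voting.
STAGES: tuple[str, ...] = (WAKE, NREM, REM)
SUBSTAGES: tuple[str, ...] = (ACTIVE, QUIET, NA)


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class Recording:
    """A synchronized EEG + motion recording.

    Parameters
    ----------
    eeg
        EEG samples in µV, band-limited by the acquisition front end
        (0.5–48 Hz in the telemetry system this models).
    motion
        Motion magnitude in G (Euclidean norm of the accelerometer axes).
        May be sampled at a different rate than the EEG; the durations of
        the two traces must agree within one motion sample.
    sample_rate_hz
        EEG sampling rate; 128 Hz for the telemetry hardware modeled here.
    motion_rate_hz
        Motion sampling rate; defaults to ``sample_rate_hz``.
    adc_rail
        Saturation amplitude of the digitizer in µV.  EEG values must lie
        in [-adc_rail, +adc_rail]; clipping artifacts sit pinned at the rail.
    start_offset_s
        Time of the first sample relative to lights-on.
    light_phase_s
        Duration of the light phase (12 h by default).
    analyzed_dark_s
        Portion of the dark phase included in analysis (9 h by default,
        giving the standard 21-h analysis window).
    motion_axes
        Optional (3, n) raw accelerometer axes, retained as metadata only.
    """

    eeg: np.ndarray
    motion: np.ndarray
    sample_rate_hz: float = 128.0
    motion_rate_hz: float | None = None
    adc_rail: float = 500.0
    start_offset_s: float = 0.0
    light_phase_s: float = 43200.0
    analyzed_dark_s: float = 32400.0
    motion_axes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        if self.motion_rate_hz is None:
            self.motion_rate_hz = float(self.sample_rate_hz)
        if self.sample_rate_hz <= 0 or self.motion_rate_hz <= 0:
            raise ValidationError("sampling rates must be positive")
        if self.adc_rail <= 0:
            raise ValidationError("adc_rail must be positive")
        if self.start_offset_s < 0:
            raise ValidationError("start_offset_s must be nonnegative")
        if self.light_phase_s <= 0 or self.analyzed_dark_s <= 0:
            raise ValidationError("phase durations must be positive")
        dur_eeg = self.eeg.size / self.sample_rate_hz
        dur_mot = self.motion.size / self.motion_rate_hz
        if abs(dur_eeg - dur_mot) > 1.0 / self.motion_rate_hz + 1e-9:
            raise ValidationError(
                f"EEG duration {dur_eeg:.3f}s and motion duration {dur_mot:.3f}s "
                "disagree by more than one motion sample"
            )
        amax = np.max(np.abs(self.eeg)) if self.eeg.size else 0.0
        if amax > self.adc_rail * (1 + 1e-9):
            raise ValidationError(
                f"EEG exceeds the ADC rail ({amax:.1f} > {self.adc_rail:.1f} µV)"
            )

    @property
    def duration_s(self) -> float:
        return self.eeg.size / self.sample_rate_hz

    @property
    def n_samples(self) -> int:
        return int(self.eeg.size)

    @staticmethod
    def motion_magnitude(axes: np.ndarray) -> np.ndarray:
        """Euclidean norm of (3, n) accelerometer axes, per sample."""
        axes = np.asarray(axes, dtype=float)
        if axes.ndim != 2 or axes.shape[0] != 3:
            raise ValidationError("expected a (3, n) array of accelerometer axes")
        return np.sqrt(np.sum(axes**2, axis=0))

    def replace_eeg(self, eeg: np.ndarray) -> "Recording":
        """Copy of this recording with a new EEG trace (same metadata)."""
        return Recording(
            eeg=eeg,
            motion=self.motion,
            sample_rate_hz=self.sample_rate_hz,
            motion_rate_hz=self.motion_rate_hz,
            adc_rail=self.adc_rail,
            start_offset_s=self.start_offset_s,
            light_phase_s=self.light_phase_s,
            analyzed_dark_s=self.analyzed_dark_s,
            motion_axes=self.motion_axes,
        )


@dataclass(frozen=True)
class EpochGrid:
    """Fixed scoring grid; trailing partial epochs are discarded.

    The grid is anchored at the first sample of the recording (no alignment
    to wall-clock boundaries).
    """

    epoch_length_s: float
    n_epochs: int
    samples_per_epoch: int

    @classmethod
    def from_recording(cls, rec: Recording, epoch_length_s: float = 8.0) -> "EpochGrid":
        if epoch_length_s <= 0:
            raise ValidationError("epoch_length_s must be positive")
        spe = epoch_length_s * rec.sample_rate_hz
        if abs(spe - round(spe)) > 1e-9:
            raise ValidationError(
                "epoch_length_s x sample_rate_hz must be an integer "
                f"(got {spe})"
            )
        spe = int(round(spe))
        n = int(rec.eeg.size // spe)
        return cls(epoch_length_s=float(epoch_length_s), n_epochs=n, samples_per_epoch=spe)


def epoch_view(x: np.ndarray, grid: EpochGrid, rate_hz: float | None = None,
               eeg_rate_hz: float = 128.0) -> np.ndarray:
    """Reshape a sample sequence into (n_epochs, samples_per_epoch).

    For sequences sampled at a rate other than the EEG's (e.g. motion),
    pass ``rate_hz``; the per-epoch sample count is recomputed and must be
    integral.
    """
    x = np.asarray(x)
    if rate_hz is None:
        spe = grid.samples_per_epoch
    else:
        spe_f = grid.epoch_length_s * rate_hz
        if abs(spe_f - round(spe_f)) > 1e-9:
            raise ValidationError("epoch length is not an integer number of samples at this rate")
        spe = int(round(spe_f))
    n = grid.n_epochs
    if x.size < n * spe:
        raise ValidationError("sequence shorter than the epoch grid")
    return x[: n * spe].reshape(n, spe)


def light_mask(rec: Recording, grid: EpochGrid) -> np.ndarray:
    """Boolean per-epoch mask, True where the epoch starts in the light phase.

    Phase membership uses the epoch's start time (half-open convention):
    an epoch is LIGHT iff ``start_offset_s + epoch_start < light_phase_s``.
    """
    t0 = rec.start_offset_s + np.arange(grid.n_epochs) * grid.epoch_length_s
    return t0 < rec.light_phase_s


def phase_labels_from_schedule(
    n_epochs: int,
    epoch_length_s: float = 8.0,
    start_offset_s: float = 0.0,
    light_phase_s: float = 43200.0,
    analyzed_dark_s: float = 32400.0,
) -> np.ndarray:
    """Per-epoch phase labels: 'light', 'dark', or 'excluded'.

    Phase membership uses the epoch's start time.  Epochs starting after
    the analyzed dark window (``light_phase_s + analyzed_dark_s``) are
    labeled 'excluded'.
    """
    t0 = start_offset_s + np.arange(n_epochs) * epoch_length_s
    out = np.where(t0 < light_phase_s, "light", "dark").astype("<U8")
    out[t0 >= light_phase_s + analyzed_dark_s] = "excluded"
    return out


def phase_labels(rec: Recording, grid: EpochGrid) -> np.ndarray:
    """Per-epoch phase labels for a recording's schedule (see above)."""
    return phase_labels_from_schedule(
        grid.n_epochs,
        grid.epoch_length_s,
        rec.start_offset_s,
        rec.light_phase_s,
        rec.analyzed_dark_s,
    )


@dataclass
class Hypnogram:
    """Per-epoch stage and wake-substage labels.

    ``substages[i]`` is ACTIVE or QUIET exactly when ``stages[i]`` is WAKE,
    and NA otherwise.
    """

    stages: np.ndarray
    substages: np.ndarray

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="<U6")
        self.substages = np.asarray(self.substages, dtype="<U6")
        if self.stages.shape != self.substages.shape or self.stages.ndim != 1:
            raise ValidationError("stages and substages must be 1-D and equal length")
        bad = set(np.unique(self.stages)) - set(STAGES) if self.stages.size else set()
        if bad:
            raise ValidationError(f"unknown stage labels: {sorted(bad)}")
        bad = set(np.unique(self.substages)) - set(SUBSTAGES) if self.substages.size else set()
        if bad:
            raise ValidationError(f"unknown substage labels: {sorted(bad)}")
        is_wake = self.stages == WAKE
        wake_sub = np.isin(self.substages, (ACTIVE, QUIET))
        if not np.array_equal(is_wake, wake_sub):
            raise ValidationError(
                "substage must be ACTIVE/QUIET exactly on WAKE epochs and NA elsewhere"
            )

    @classmethod
    def from_stages(cls, stages: Sequence[str] | np.ndarray,
                    substages: Sequence[str] | np.ndarray | None = None) -> "Hypnogram":
        """Build a hypnogram from stage labels alone.

        Without substage information wake epochs default to QUIET; use
        :func:`somnoscore.staging.split_wake_substages` to assign them from
        motion data.
        """
        stages = np.asarray(stages, dtype="<U6")
        if substages is None:
            substages = np.where(stages == WAKE, QUIET, NA)
        return cls(stages=stages, substages=np.asarray(substages, dtype="<U6"))

    def __len__(self) -> int:
        return int(self.stages.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return np.array_equal(self.stages, other.stages) and np.array_equal(
            self.substages, other.substages
        )


@dataclass(frozen=True)
class Band:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if self.low_hz >= self.high_hz:
            raise ValidationError(f"band {self.name}: low >= high")


#: The five analysis bands.  Membership is half-open [low, high) except the
#: top band, which is closed at 48 Hz, so the bands tile [0.5, 48] exactly.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 12.0, 30.0),
    Band("gamma", 30.0, 48.0),
)


@dataclass(frozen=True)
class BandScheme:
    """Frequency-band layout for feature extraction and spectral analysis."""

    bands: tuple[Band, ...] = DEFAULT_BANDS
    bin_width_hz: float = 0.125
    analysis_low_hz: float = 0.5
    analysis_high_hz: float = 48.0

    def __post_init__(self) -> None:
        lows = [b.low_hz for b in self.bands]
        highs = [b.high_hz for b in self.bands]
        if lows[0] != self.analysis_low_hz or highs[-1] != self.analysis_high_hz:
            raise ValidationError("bands must span the analysis range")
        for h, l2 in zip(highs[:-1], lows[1:]):
            if h != l2:
                raise ValidationError("bands must tile the analysis range without gap/overlap")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def band(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    def band_mask(self, freqs: np.ndarray, band: Band | str) -> np.ndarray:
        """Boolean mask over frequency bins belonging to a band.

        Half-open [low, high); the top band is closed at its upper edge so
        the 48 Hz bin is counted exactly once.
        """
        if isinstance(band, str):
            band = self.band(band)
        freqs = np.asarray(freqs)
        mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
        if band.high_hz == self.analysis_high_hz:
            mask |= freqs == band.high_hz
        return mask

    def analysis_mask(self, freqs: np.ndarray) -> np.ndarray:
        """Mask of all bins in the analysis range [low, high] (union of bands)."""
        freqs = np.asarray(freqs)
        return (freqs >= self.analysis_low_hz) & (freqs <= self.analysis_high_hz)
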