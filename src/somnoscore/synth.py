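"""Stage-annotated synthetic EEG + motion recordings.

The generator emulates the statistical structure the scoring pipeline
assumes: a Markov chain over wake/NREM/REM at the 8-s epoch step with a
diurnal bias toward wake persistence in the dark phase; stage-dependent
spectral content (delta-dominant high-amplitude NREM, theta-dominant REM,
mixed-spectrum wake); movement bursts longer than 1 s in active wake, brief
sub-second bursts at most in quiet wake, sub-threshold twitches in REM; and
clipping artifacts injected as rail-pinned runs with a ground-truth mask.
Every output is reproducible bit-exactly from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ACTIVE,
    NA,
    NREM,
    QUIET,
    REM,
    STAGES,
    WAKE,
    BandScheme,
    EpochGrid,
    Hypnogram,
    Recording,
    light_mask,
)

__all__ = ["GenConfig", "sample_stage_sequence", "synthesize_recording",
           "estimate_transition_matrix"]

logger = logging.getLogger(__name__)

_SCHEME = BandScheme()

#: Default per-8-s-step stage transition matrix (rows/cols WAKE, NREM, REM).
#: Persistence values give mean bout lengths of roughly 2 min (wake and
#: NREM) and 1 min (REM), typical of the polycyclic sleep of adult rats.
_DEFAULT_TRANSITIONS = np.array(
    [
        [0.94, 0.055, 0.005],
        [0.04, 0.93, 0.03],
        [0.10, 0.05, 0.85],
    ]
)

#: Relative band-power weights (delta, theta, alpha, beta, gamma) per stage,
#: honoring the qualitative stage signatures: NREM slow-wave dominated, REM
#: theta dominated, wake broadband.
_DEFAULT_TEMPLATES = {
    WAKE: np.array([0.20, 0.25, 0.15, 0.20, 0.20]),
    NREM: np.array([0.60, 0.15, 0.10, 0.10, 0.05]),
    REM: np.array([0.10, 0.60, 0.10, 0.10, 0.10]),
}

#: RMS EEG amplitude per stage (µV); NREM slow waves are high-amplitude.
_DEFAULT_AMPLITUDES = {WAKE: 60.0, NREM: 120.0, REM: 60.0}


@dataclass
class GenConfig:
    """Synthetic-recording parameters; the defaults are the benchmark conditions."""

    transition_matrix: np.ndarray = field(default_factory=lambda: _DEFAULT_TRANSITIONS.copy())
    dark_wake_bias: float = 0.04
    stage_spectral_templates: dict = field(default_factory=lambda: {k: v.copy() for k, v in _DEFAULT_TEMPLATES.items()})
    stage_amplitude_uV: dict = field(default_factory=lambda: dict(_DEFAULT_AMPLITUDES))
    amplitude_jitter_sd: float = 0.15    # lognormal sd of per-epoch amplitude factor
    wake_active_prob: float = 0.7
    movement_burst_amplitude_g: float = 0.3
    active_burst_duration_s: tuple[float, float] = (1.5, 3.5)
    quiet_burst_duration_s: tuple[float, float] = (0.1, 0.5)
    quiet_burst_prob: float = 0.5
    rem_twitch_amplitude_g: float = 0.05
    rem_twitch_duration_s: tuple[float, float] = (0.1, 0.3)
    rem_twitch_prob: float = 0.3
    motion_baseline_g: float = 1.0       # gravity offset of the magnitude
    motion_noise_sd_g: float = 0.02
    clip_rate: float = 0.02              # expected fraction of clipped samples
    clip_duration_s: tuple[float, float] = (0.5, 2.5)
    sample_rate_hz: float = 128.0
    epoch_length_s: float = 8.0
    adc_rail: float = 500.0
    light_phase_s: float = 43200.0
    analyzed_dark_s: float = 32400.0
    seed: int = 0

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (3, 3) or np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0):
            raise ValueError("transition_matrix must be 3x3 row-stochastic")
        self.transition_matrix = tm
        if not 0 <= self.clip_rate <= 0.2:
            raise ValueError("clip_rate must lie in [0, 0.2]")
        for w in self.stage_spectral_templates.values():
            if np.any(np.asarray(w) < 0):
                raise ValueError("spectral template weights must be nonnegative")

    def dark_matrix(self) -> np.ndarray:
        """Transition matrix during the dark phase: wake persistence boosted."""
        tm = self.transition_matrix.copy()
        boost = min(self.dark_wake_bias, 1.0 - tm[0, 0])
        rest = tm[0, 1:].sum()
        if rest > 0:
            tm[0, 1:] *= (rest - boost) / rest
        tm[0, 0] += boost
        return tm


def sample_stage_sequence(
    cfg: GenConfig,
    n_epochs: int,
    light: np.ndarray,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a stage/substage sequence from the (diurnally modulated) chain.

    ``light`` is a per-epoch boolean mask; dark epochs use the wake-biased
    matrix.  Wake epochs are tagged ACTIVE with probability
    ``wake_active_prob``, QUIET otherwise; other stages get NA.
    """
    light = np.asarray(light, dtype=bool)
    if light.size != n_epochs:
        raise ValueError("light mask must have one entry per epoch")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    matrices = {True: cfg.transition_matrix, False: cfg.dark_matrix()}
    stages = np.empty(n_epochs, dtype="<U6")
    state = 0  # recordings start at lights-on with the animal awake
    for i in range(n_epochs):
        stages[i] = STAGES[state]
        if i + 1 < n_epochs:
            state = rng.choice(3, p=matrices[bool(light[i + 1])][state])
    substages = np.full(n_epochs, NA, dtype="<U6")
    wake = stages == WAKE
    substages[wake] = np.where(
        rng.random(int(wake.sum())) < cfg.wake_active_prob, ACTIVE, QUIET
    )
    return stages, substages


def _epoch_eeg(rng: np.random.Generator, cfg: GenConfig, stage: str, n: int) -> np.ndarray:
    """One epoch of stage-colored noise with the template's relative band powers."""
    fs = cfg.sample_rate_hz
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    out = np.zeros(n)
    weights = cfg.stage_spectral_templates[stage]
    for band, w in zip(_SCHEME.bands, weights):
        if w <= 0:
            continue
        comp = np.fft.irfft(np.where(_SCHEME.band_mask(freqs, band), spec, 0.0), n=n)
        sd = comp.std()
        if sd > 0:
            out += np.sqrt(w) * comp / sd
    amp = cfg.stage_amplitude_uV[stage]
    if cfg.amplitude_jitter_sd > 0:
        amp *= np.exp(rng.normal(0.0, cfg.amplitude_jitter_sd))
    sd = out.std()
    return out * (amp / sd) if sd > 0 else out


def _add_burst(rng: np.random.Generator, trace: np.ndarray, rate: float,
               duration_range: tuple[float, float], amplitude: float) -> None:
    dur = int(round(rng.uniform(*duration_range) * rate))
    dur = min(max(dur, 1), trace.size)
    start = int(rng.integers(0, trace.size - dur + 1))
    trace[start: start + dur] += amplitude * (1 + 0.2 * rng.standard_normal(dur))


def _inject_clipping(rng: np.random.Generator, eeg: np.ndarray, cfg: GenConfig) -> np.ndarray:
    """Pin random stretches at the rail; returns the ground-truth mask."""
    n = eeg.size
    mask = np.zeros(n, dtype=bool)
    if cfg.clip_rate <= 0:
        return mask
    mean_dur = np.mean(cfg.clip_duration_s) * cfg.sample_rate_hz
    n_events = int(round(cfg.clip_rate * n / mean_dur))
    for _ in range(n_events):
        dur = int(round(rng.uniform(*cfg.clip_duration_s) * cfg.sample_rate_hz))
        start = int(rng.integers(0, max(n - dur, 1)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        eeg[start: start + dur] = sign * cfg.adc_rail
        mask[start: start + dur] = True
    return mask


def synthesize_recording(
    cfg: GenConfig | None = None,
    duration_s: float = 75600.0,
    seed: int | None = None,
) -> tuple[Recording, Hypnogram, np.ndarray]:
    """Generate a recording, its ground-truth hypnogram, and the clip mask.

    The default duration is the standard 21-h analysis window (12 h light +
    9 h dark).  Consecutive epochs are crossfaded over 0.125 s so epoch
    boundaries introduce no broadband splice artifacts.
    """
    cfg = cfg or GenConfig()
    fs = cfg.sample_rate_hz
    spe = int(round(cfg.epoch_length_s * fs))
    n_epochs_f = duration_s / cfg.epoch_length_s
    if abs(n_epochs_f - round(n_epochs_f)) > 1e-9:
        raise ValueError("duration_s must be a whole number of epochs")
    n_epochs = int(round(n_epochs_f))
    n = n_epochs * spe
    master = np.random.SeedSequence(
        (cfg.seed if seed is None else int(seed)) % 2**31
    )
    rng_stage, rng_eeg, rng_motion, rng_clip = (
        np.random.default_rng(s) for s in master.spawn(4)
    )

    t0 = np.arange(n_epochs) * cfg.epoch_length_s
    light = t0 < cfg.light_phase_s
    stages, substages = sample_stage_sequence(cfg, n_epochs, light,
                                              seed=rng_stage.integers(2**31))

    # EEG: per-epoch colored noise, overlap-added with a 0.125-s raised cosine.
    xf = int(round(0.125 * fs))
    eeg = np.zeros(n + xf)
    ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(xf) + 0.5) / xf))
    for i in range(n_epochs):
        chunk = _epoch_eeg(rng_eeg, cfg, stages[i], spe + xf)
        env = np.ones(spe + xf)
        if i > 0:
            env[:xf] = ramp
        if i < n_epochs - 1:
            env[-xf:] = 1 - ramp
        eeg[i * spe: i * spe + spe + xf] += env * chunk
    eeg = eeg[:n]

    # Motion: gravity + sensor noise + stage-dependent bursts.
    motion = cfg.motion_baseline_g + rng_motion.normal(0.0, cfg.motion_noise_sd_g, n)
    for i in range(n_epochs):
        ep = motion[i * spe: (i + 1) * spe]
        if substages[i] == ACTIVE:
            _add_burst(rng_motion, ep, fs, cfg.active_burst_duration_s,
                       cfg.movement_burst_amplitude_g)
        elif substages[i] == QUIET and rng_motion.random() < cfg.quiet_burst_prob:
            _add_burst(rng_motion, ep, fs, cfg.quiet_burst_duration_s,
                       cfg.movement_burst_amplitude_g)
        elif stages[i] == REM and rng_motion.random() < cfg.rem_twitch_prob:
            _add_burst(rng_motion, ep, fs, cfg.rem_twitch_duration_s,
                       cfg.rem_twitch_amplitude_g)

    np.clip(eeg, -cfg.adc_rail, cfg.adc_rail, out=eeg)
    clip_mask = _inject_clipping(rng_clip, eeg, cfg)

    rec = Recording(
        eeg=eeg,
        motion=motion,
        sample_rate_hz=fs,
        adc_rail=cfg.adc_rail,
        start_offset_s=0.0,
        light_phase_s=cfg.light_phase_s,
        analyzed_dark_s=cfg.analyzed_dark_s,
    )
    return rec, Hypnogram(stages=stages, substages=substages), clip_mask


def estimate_transition_matrix(h: Hypnogram) -> np.ndarray:
    """Maximum-likelihood bigram estimate of the stage transition matrix.

    Rows are WAKE, NREM, REM.  A stage never observed as a transition
    source yields a NaN row (logged).
    """
    if len(h) < 2:
        raise ValueError("need at least 2 epochs to estimate transitions")
    index = {s: i for i, s in enumerate(STAGES)}
    counts = np.zeros((3, 3))
    src = h.stages[:-1]
    dst = h.stages[1:]
    for a, b in zip(src, dst):
        counts[index[a], index[b]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tm = counts / totals
    for i, s in enumerate(STAGES):
        if totals[i, 0] == 0:
            logger.warning("stage %s never occurs as a transition source", s)
    return tm
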