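"""Sleep-architecture metrics: episodes, per-hour durations, phase breakdown.

An *episode* (bout) is a maximal run of consecutive epochs sharing a stage
label.  The summary table reports, per stage and per wake substage, the
mean minutes per hour spent in the state, the number of episodes per hour,
and the mean episode length in seconds — for the whole record and for the
light and dark phases separately.  Episodes spanning a phase boundary are
assigned to the phase containing their first epoch; partial hours are
weighted by covered time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ACTIVE, NA, QUIET, STAGES, WAKE, Hypnogram, phase_labels_from_schedule

__all__ = ["Episode", "find_episodes", "per_hour_metrics"]


@dataclass(frozen=True)
class Episode:
    stage: str
    start_epoch: int
    n_epochs: int
    duration_s: float


def find_episodes(h: Hypnogram, epoch_length_s: float = 8.0,
                  labels: np.ndarray | None = None) -> list[Episode]:
    """Run-length encode a label sequence into episodes.

    By default the stage sequence is encoded; pass ``labels`` to encode any
    other epoch-aligned sequence (e.g. substages).  Concatenating the
    episodes reproduces the sequence exactly.
    """
    seq = np.asarray(h.stages if labels is None else labels)
    if seq.size == 0:
        return []
    change = np.flatnonzero(seq[1:] != seq[:-1]) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, seq.size]
    return [
        Episode(
            stage=str(seq[s]),
            start_epoch=int(s),
            n_epochs=int(e - s),
            duration_s=float((e - s) * epoch_length_s),
        )
        for s, e in zip(starts, ends)
    ]


def _substage_labels(h: Hypnogram) -> np.ndarray:
    """Wake epochs labeled by substage, sleep epochs by stage (for bout runs)."""
    labels = h.stages.astype("<U16").copy()
    labels[h.stages == WAKE] = h.substages[h.stages == WAKE]
    return labels


def _scope_rows(
    episodes: list[Episode],
    seq: np.ndarray,
    in_scope: np.ndarray,
    scope: str,
    states: tuple[str, ...],
    epoch_length_s: float,
) -> list[dict]:
    hours = in_scope.sum() * epoch_length_s / 3600.0
    rows = []
    for state in states:
        n_min = np.count_nonzero((seq == state) & in_scope) * epoch_length_s / 60.0
        eps = [ep for ep in episodes if ep.stage == state and in_scope[ep.start_epoch]]
        rows.append(
            {
                "scope": scope,
                "state": state,
                "duration_min_per_h": n_min / hours if hours else np.nan,
                "n_episodes_per_h": len(eps) / hours if hours else np.nan,
                "mean_episode_len_s": float(np.mean([ep.duration_s for ep in eps]))
                if eps
                else np.nan,
            }
        )
    return rows


def per_hour_metrics(
    h: Hypnogram,
    epoch_length_s: float = 8.0,
    start_offset_s: float = 0.0,
    light_phase_s: float = 43200.0,
    analyzed_dark_s: float = 32400.0,
) -> pd.DataFrame:
    """Per-hour stage and substage metrics for whole/light/dark scopes.

    Columns: ``scope`` (whole/light/dark), ``state`` (WAKE, NREM, REM,
    ACTIVE, QUIET), ``duration_min_per_h``, ``n_episodes_per_h``,
    ``mean_episode_len_s``.  Stage minutes per hour sum to 60 within every
    scope; substage minutes sum to the wake minutes.  Epochs past the
    analyzed dark window are excluded from every scope.
    """
    phases = phase_labels_from_schedule(
        len(h), epoch_length_s, start_offset_s, light_phase_s, analyzed_dark_s
    )
    analyzed = phases != "excluded"
    stage_eps = find_episodes(h, epoch_length_s)
    sub_seq = _substage_labels(h)
    sub_eps = find_episodes(h, epoch_length_s, labels=sub_seq)

    rows: list[dict] = []
    for scope, mask in (
        ("whole", analyzed),
        ("light", analyzed & (phases == "light")),
        ("dark", analyzed & (phases == "dark")),
    ):
        rows += _scope_rows(stage_eps, h.stages, mask, scope, STAGES, epoch_length_s)
        rows += _scope_rows(sub_eps, sub_seq, mask, scope, (ACTIVE, QUIET), epoch_length_s)
    return pd.DataFrame(rows)
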