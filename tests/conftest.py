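"""Shared fixtures.

The expensive fixture is the default 21-h synthetic benchmark (generate ->
repair -> features); it is session-scoped and built lazily, so quick test
selections never pay for it.
"""

from __future__ import annotations

import numpy as np
import pytest

from somnoscore.core import EpochGrid
from somnoscore.features import extract_features
from somnoscore.repair import repair_recording
from somnoscore.synth import GenConfig, synthesize_recording

BENCHMARK_SEED = 7


@pytest.fixture(scope="session")
def benchmark():
    """Default 21-h benchmark: recording, ground truth, repair, features."""
    cfg = GenConfig()
    rec, truth, clip_mask = synthesize_recording(cfg, duration_s=75600.0, seed=BENCHMARK_SEED)
    clean, report = repair_recording(rec, rng_seed=BENCHMARK_SEED)
    grid = EpochGrid.from_recording(clean)
    feats = extract_features(clean, grid)
    return {
        "cfg": cfg,
        "rec": rec,
        "truth": truth,
        "clip_mask": clip_mask,
        "clean": clean,
        "report": report,
        "grid": grid,
        "features": feats,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
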