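"""Shared fixtures and oracles for the songtune test suite."""

from __future__ import annotations

import numpy as np
import pytest

from songtune import synth
from songtune.segmentation import Movie


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks."""
    inter = np.logical_and(pred, truth).sum()
    union = np.logical_or(pred, truth).sum()
    return inter / union if union else 0.0


def matched_iou(labels: np.ndarray, truth_labels: np.ndarray) -> list[float]:
    """Best-match IoU for every planted ROI in a ground-truth label image."""
    out = []
    for t in range(1, int(truth_labels.max()) + 1):
        tmask = truth_labels == t
        best = 0.0
        for p in range(1, int(labels.max()) + 1):
            best = max(best, iou(labels == p, tmask))
        out.append(best)
    return out


def two_blob_truth(seed: int = 0, noise_sd: float = 2.0,
                   peak: float = 100.0) -> synth.SyntheticGroundTruth:
    """Two well-separated somata on a 48x48 field; SNR = peak/noise_sd * ...

    With baseline 20 and peak 100 the blob-to-noise ratio at the planted
    noise_sd of 2 is 50; tests lower SNR by raising noise_sd.
    """
    return synth.SyntheticGroundTruth(
        rois=[synth.BlobROI(12.0, 14.0, 2.5, peak),
              synth.BlobROI(32.0, 30.0, 2.5, peak)],
        tuning=synth.pc1_like_model(),
        noise_sd=noise_sd, seed=seed)


def grid_events(ipi_grid=synth.DEFAULT_IPI_GRID, lead_s: float = 2.0,
                period_s: float = 8.0, level_db: float = 80.0) -> list[dict]:
    """One pulse-train event per IPI on a regular schedule."""
    return [{"onset": lead_s + i * period_s, "ipi_ms": float(ipi),
             "kind": "pulse", "level_db": level_db}
            for i, ipi in enumerate(np.asarray(ipi_grid, dtype=float))]


def synthetic_movie(truth: synth.SyntheticGroundTruth, events: list[dict],
                    shape=(48, 48), seed: int | None = None) -> Movie:
    duration = events[-1]["onset"] + 6.0
    return synth.simulate_movie(truth, events, duration_s=duration,
                                shape=shape, seed=seed)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
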