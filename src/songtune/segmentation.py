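"""Calcium-movie ROI segmentation and trace extraction.

Two segmentation paths, matching how somata and neurites are imaged:

* soma: k-means on the time-averaged intensity image; the brightest cluster
  is foreground and its connected components become ROIs (cell bodies).
* neurite: k-means (3 clusters) on the per-pixel time traces, z-scored per
  pixel so response kinetics rather than raw brightness drive the
  clustering; the cluster whose centroid trace has the largest temporal
  variance (the stimulus-locked, coherent one) supplies the ROI pixels.

Masks are cleaned with a morphological opening (erosion then dilation) and
relabeled; downstream analysis keeps only the most responsive ROI.

Conventions: frames are T x H x W row-major arrays, pixel coordinates are
0-based (row, column) at pixel centers; label 0 is background and ROI labels
are contiguous 1..K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage import measure, morphology
from sklearn.cluster import KMeans

__all__ = [
    "Movie",
    "ROIMask",
    "Trace",
    "segment_soma",
    "segment_neurite",
    "cluster_pixel_traces",
    "cleanup_mask",
    "extract_traces",
    "most_responding_roi",
]

DEFAULT_FRAME_RATE = 13.0


@dataclass
class Movie:
    """A grayscale calcium-imaging stack (T x H x W) with its frame rate."""

    frames: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if self.frames.shape[0] < 2:
            raise ValueError("movie needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def mean_image(self) -> np.ndarray:
        return self.frames.mean(axis=0)

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.frames.astype(np.float32),
                         photometric="minisblack")

    @classmethod
    def from_tiff(cls, path: str | Path,
                  frame_rate: float = DEFAULT_FRAME_RATE) -> "Movie":
        return cls(tifffile.imread(str(path)), frame_rate)


@dataclass
class ROIMask:
    """Label image (H x W): 0 = background, k = ROI id, labels 1..K."""

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        self.labels = self.labels.astype(np.int32)
        present = np.unique(self.labels[self.labels > 0])
        expected = np.arange(1, len(present) + 1)
        if not np.array_equal(present, expected):
            # renumber to a contiguous 1..K range
            remap = np.zeros(int(self.labels.max()) + 1, dtype=np.int32)
            remap[present] = expected
            self.labels = remap[self.labels]

    @property
    def n_rois(self) -> int:
        return int(self.labels.max())

    @property
    def roi_ids(self) -> list[int]:
        return list(range(1, self.n_rois + 1))

    def pixels(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.labels.astype(np.uint16))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ROIMask":
        return cls(tifffile.imread(str(path)).astype(np.int32))


@dataclass
class Trace:
    """Per-frame mean intensity of one ROI."""

    values: np.ndarray
    frame_rate: float
    roi_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("trace must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _label_components(foreground: np.ndarray, provenance: dict) -> ROIMask:
    labels = measure.label(foreground, connectivity=2)
    return ROIMask(labels, provenance)


def segment_soma(movie: Movie, k: int = 2, seed: int = 0,
                 n_foreground_clusters: int = 1) -> ROIMask:
    """Segment cell bodies by k-means on the time-averaged image.

    Pixels of the ``n_foreground_clusters`` brightest clusters form the
    foreground; its connected components become ROIs.  A constant mean image
    cannot be clustered and yields an empty mask with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 1 <= n_foreground_clusters < k:
        raise ValueError("n_foreground_clusters must be in 1..k-1")
    mean_img = movie.mean_image()
    prov = {"method": "soma_kmeans", "k": k, "seed": seed,
            "n_foreground_clusters": n_foreground_clusters}
    if np.ptp(mean_img) == 0:
        warnings.warn("constant mean image: no ROIs found", stacklevel=2)
        return ROIMask(np.zeros(mean_img.shape, dtype=np.int32), prov)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(mean_img.reshape(-1, 1)).reshape(mean_img.shape)
    order = np.argsort(km.cluster_centers_.ravel())[::-1]
    foreground = np.isin(assign, order[:n_foreground_clusters])
    return _label_components(foreground, prov)


def cluster_pixel_traces(movie: Movie, k: int = 3, seed: int = 0,
                         standardize: bool = True) -> np.ndarray:
    """k-means clustering of per-pixel traces.

    Returns ``(assignment, centroids)``: an H x W integer image of cluster
    ids and the (k, T) centroid traces.  Traces are z-scored per pixel by
    default so shared kinetics, not brightness, define the clusters;
    constant-trace pixels are left as an all-zero row.
    """
    T = movie.n_frames
    X = movie.frames.reshape(T, -1).T.copy()  # (H*W, T)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(X)
    return assign.reshape(movie.shape), km.cluster_centers_


def segment_neurite(movie: Movie, k: int = 3, seed: int = 0) -> ROIMask:
    """Segment neurites by k-means (3 clusters) on individual pixel traces.

    The cluster whose centroid trace has the largest temporal variance is
    taken as the responding (stimulus-locked) population; its connected
    components become ROIs.  On i.i.d.-noise movies every centroid is nearly
    flat and whichever cluster is picked is removed by the subsequent
    opening step.
    """
    if movie.n_frames < 3:
        raise ValueError("need at least 3 frames to cluster pixel traces")
    prov = {"method": "neurite_kmeans", "k": k, "seed": seed}
    if np.ptp(movie.frames) == 0:
        warnings.warn("constant movie: no ROIs found", stacklevel=2)
        return ROIMask(np.zeros(movie.shape, dtype=np.int32), prov)
    assign, centers = cluster_pixel_traces(movie, k=k, seed=seed)
    responding = int(np.argmax(centers.var(axis=1)))
    return _label_components(assign == responding, prov)


def cleanup_mask(mask: ROIMask, radius: int = 1) -> ROIMask:
    """Morphological opening (erosion then dilation) of each ROI.

    Removes speckles below the structuring-element scale (a square of side
    2*radius+1, 3x3 by default), drops emptied ROIs and relabels connected
    components.  Opening is idempotent, so repeated cleanup is a no-op.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    footprint = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    opened = np.zeros(mask.labels.shape, dtype=bool)
    for roi_id in mask.roi_ids:
        opened |= morphology.opening(mask.pixels(roi_id), footprint)
    prov = dict(mask.provenance)
    prov["cleanup_radius"] = radius
    return _label_components(opened, prov)


# ---------------------------------------------------------------------------
# Trace extraction and ROI selection
# ---------------------------------------------------------------------------

def extract_traces(movie: Movie, mask: ROIMask) -> list[Trace]:
    """Mean intensity over each ROI's pixels, per frame."""
    if mask.labels.shape != movie.shape:
        raise ValueError(
            f"mask shape {mask.labels.shape} != frame shape {movie.shape}")
    flat = movie.frames.reshape(movie.n_frames, -1)
    traces = []
    for roi_id in mask.roi_ids:
        idx = (mask.labels == roi_id).ravel()
        traces.append(Trace(flat[:, idx].mean(axis=1), movie.frame_rate, roi_id))
    return traces


def most_responding_roi(traces: list[Trace], events: list[dict],
                        pre_s: float = 1.0, post_s: float = 5.0,
                        smooth_window: int = 11) -> int:
    """ROI id with the largest mean event-locked peak dF/F.

    Responses are computed with :func:`songtune.traces.peak_dff` on the
    Savitzky-Golay-smoothed trace, averaged over events; ties break to the
    lowest ROI id.
    """
    from . import traces as trace_metrics

    if len(traces) == 0:
        raise ValueError("need at least one trace")
    if len(events) == 0:
        raise ValueError("need at least one stimulus event")
    best_id, best_score = None, -np.inf
    for tr in sorted(traces, key=lambda t: t.roi_id):
        smoothed = trace_metrics.smooth_trace(tr, window=smooth_window)
        peaks = [trace_metrics.peak_dff(smoothed, ev["onset"],
                                        pre_s=pre_s, post_s=post_s).peak_dff
                 for ev in events]
        score = float(np.mean(peaks))
        if score > best_score:
            best_id, best_score = tr.roi_id, score
    return best_id


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    """Long-format CSV view: frame, time_s, roi_id, F."""
    rows = [pd.DataFrame({"frame": np.arange(len(t)), "time_s": t.times,
                          "roi_id": t.roi_id, "F": t.values})
            for t in traces]
    return pd.concat(rows, ignore_index=True)
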