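"""Song-induced male-chaining behavior scoring.

Groups of (by default six) male flies are exposed to playback of synthetic
courtship song; an observer scores, every 3 s, how many flies are engaged in
a courtship chain.  The chaining index (CI) for a 30-s block is the sum of
these ten counts, so the maximum CI is 60 when all six flies chain through
the whole block.  The chain fraction is the proportion of samples in which
at least a threshold number of flies (default three) are chaining, used for
optogenetic-activation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChainCountSeries",
    "ChainingResult",
    "chaining_index",
    "chaining_heatmap",
    "summed_ci",
    "chain_fraction",
]


@dataclass
class ChainCountSeries:
    """Counts of chaining flies on a regular sampling grid.

    ``counts[i]`` is the number of flies in a chain at time
    ``t0 + i * interval_s``; each count lies in 0..group_size.
    """

    counts: np.ndarray
    interval_s: float = 3.0
    group_size: int = 6
    t0: float = 0.0
    group_id: str = "group0"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(int)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if self.interval_s <= 0:
            raise ValueError("interval_s must be positive")
        if np.any(self.counts < 0) or np.any(self.counts > self.group_size):
            raise ValueError(
                f"counts must lie in 0..group_size ({self.group_size})")

    @property
    def sample_times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.counts)) * self.interval_s

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_size: int = 6) -> list["ChainCountSeries"]:
        """Build one series per ``group_id`` from a long table with columns
        time_s, n_chaining, group_id.  Sampling must be regular per group."""
        out = []
        for gid, sub in df.groupby("group_id", sort=True):
            sub = sub.sort_values("time_s")
            t = sub["time_s"].to_numpy(dtype=float)
            if len(t) < 2:
                raise ValueError(f"group {gid!r}: need >= 2 samples")
            dt = np.diff(t)
            if not np.allclose(dt, dt[0]):
                raise ValueError(f"group {gid!r}: irregular sampling interval")
            out.append(cls(sub["n_chaining"].to_numpy(), float(dt[0]),
                           group_size, float(t[0]), str(gid)))
        return out

    @classmethod
    def from_csv(cls, path: str | Path, group_size: int = 6) -> list["ChainCountSeries"]:
        return cls.from_frame(pd.read_csv(path), group_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.sample_times,
                             "n_chaining": self.counts,
                             "group_id": self.group_id})


@dataclass
class ChainingResult:
    """Chaining index per block: CI_b = sum of counts within block b."""

    block_starts: np.ndarray
    ci_per_block: np.ndarray
    block_s: float
    interval_s: float
    group_size: int
    group_id: str = "group0"
    metadata: dict = field(default_factory=dict)

    @property
    def max_ci(self) -> float:
        """Upper bound on CI (all flies chaining at every sample)."""
        return self.block_s / self.interval_s * self.group_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"block_start_s": self.block_starts,
                             "ci": self.ci_per_block,
                             "group_id": self.group_id})


def chaining_index(series: ChainCountSeries, block_s: float = 30.0) -> ChainingResult:
    """Sum 3-s chain counts within consecutive ``block_s`` blocks.

    Blocks tile the series from its start; a partial trailing block is
    dropped so every reported CI has the same bound
    (block_s / interval_s * group_size, i.e. 60 by default).
    """
    n_per = block_s / series.interval_s
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            f"block_s ({block_s}) must be a multiple of the sampling "
            f"interval ({series.interval_s})")
    n_per = int(round(n_per))
    n_blocks = len(series.counts) // n_per
    trimmed = series.counts[: n_blocks * n_per]
    ci = trimmed.reshape(n_blocks, n_per).sum(axis=1)
    starts = series.t0 + np.arange(n_blocks) * block_s
    return ChainingResult(starts, ci, block_s, series.interval_s,
                          series.group_size, series.group_id)


def chaining_heatmap(results: list[ChainingResult] | list[ChainCountSeries],
                     per_sample: bool = False) -> np.ndarray:
    """Group-by-time matrix of chaining intensity.

    Rows are groups (one per input); columns are 30-s blocks (CI values) or,
    with ``per_sample``, raw 3-s counts.  Inputs must have equal length.
    """
    if len(results) == 0:
        raise ValueError("need at least one group")
    if per_sample:
        if not all(isinstance(r, ChainCountSeries) for r in results):
            raise TypeError("per_sample heat map needs ChainCountSeries inputs")
        rows = [r.counts for r in results]
    else:
        rows = [r.ci_per_block if isinstance(r, ChainingResult)
                else chaining_index(r).ci_per_block for r in results]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged inputs: row lengths {sorted(lengths)}")
    return np.vstack(rows)


def summed_ci(result: ChainingResult, window: tuple[float, float]) -> int:
    """Total CI over blocks lying fully inside ``window`` = (t0, t1)."""
    t0, t1 = window
    if t1 < t0:
        raise ValueError("window end precedes start")
    inside = (result.block_starts >= t0 - 1e-9) & \
             (result.block_starts + result.block_s <= t1 + 1e-9)
    return int(result.ci_per_block[inside].sum())


def save_heatmap_image(matrix: np.ndarray, path: str | Path,
                       block_s: float = 30.0, group_ids=None) -> None:
    """Render a chaining heat map (groups x time) to an image file.

    Colors encode the chaining intensity; one row per group of flies.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = np.atleast_2d(matrix)
    fig, ax = plt.subplots(figsize=(8, 0.5 + 0.3 * matrix.shape[0]))
    im = ax.imshow(matrix, aspect="auto", interpolation="nearest",
                   cmap="inferno",
                   extent=(0, matrix.shape[1] * block_s, matrix.shape[0], 0))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("group")
    if group_ids is not None:
        ax.set_yticks(np.arange(len(group_ids)) + 0.5, group_ids)
    fig.colorbar(im, ax=ax, label="chaining")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def chain_fraction(series: ChainCountSeries, threshold: int = 3) -> float:
    """Fraction of samples with at least ``threshold`` flies in a chain."""
    if threshold > series.group_size:
        raise ValueError("threshold exceeds group size")
    if len(series.counts) == 0:
        raise ValueError("empty series")
    return float(np.mean(series.counts >= threshold))
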