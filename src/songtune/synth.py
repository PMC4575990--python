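"""Ground-truth-known synthetic data emulating the study's data-generating
process.

Three generators make every pipeline stage testable without recordings:

* movies — Gaussian-blob somata on a noisy baseline image whose blobs
  transiently brighten after each stimulus event, with amplitude set by a
  planted IPI tuning model convolved with a GCaMP6m-like double-exponential
  kernel and intensity-proportional Gaussian noise;
* tuning tables — per-subject peak dF/F values drawn from a planted tuning
  model with multiplicative subject gain jitter (which is what makes
  per-fly max normalization necessary) plus additive noise;
* chaining series — per-3-s-sample Binomial(group_size, p) counts whose
  logit rate follows a logistic in intensity (planted EC50) times a planted
  IPI weighting, near zero during silence, with an exponential decay of
  drive after song offset.

Two planted tuning shapes mirror the neuron classes under study: a
saturating low-pass Hill curve (vPN1-like, strong response at IPIs of
35 ms and above) and a band-pass Gaussian (pC1-like, peaked in the
35-65 ms range with attenuation at both extremes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .behavior import ChainCountSeries
from .segmentation import Movie
from .stimulus import StimulusProtocol, _read_source

__all__ = [
    "LowPassHill",
    "BandPassGaussian",
    "GCaMPKernel",
    "BlobROI",
    "SyntheticGroundTruth",
    "vpn1_like_model",
    "pc1_like_model",
    "simulate_movie",
    "simulate_tuning_table",
    "simulate_chaining",
    "DEFAULT_IPI_GRID",
]

#: Imaging/behavior IPI grid (ms): 15-95 ms in 10-ms steps.
DEFAULT_IPI_GRID = np.arange(15.0, 96.0, 10.0)


# ---------------------------------------------------------------------------
# Tuning models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LowPassHill:
    """Saturating Hill curve of IPI: r(x) = r_max x^h / (K^h + x^h).

    The vPN1-like shape: substantial but attenuated response at short IPIs
    (~1/3 of max at 15 ms), a shoulder near 35 ms and saturation above it.
    """

    r_max: float = 1.0
    K: float = 20.0          # ms, half-saturation IPI
    n_hill: float = 2.5

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.K <= 0:
            raise ValueError("r_max and K must be positive")

    def response(self, ipi_ms) -> np.ndarray:
        x = np.asarray(ipi_ms, dtype=float)
        xh = x ** self.n_hill
        return self.r_max * xh / (self.K ** self.n_hill + xh)

    kind = "low_pass_hill"


@dataclass(frozen=True)
class BandPassGaussian:
    """Band-pass tuning: baseline + r_max exp(-(x - center)^2 / 2 width^2).

    Centered near 50 ms it is strong in the 35-65 ms band and attenuated at
    both short and long IPIs — the pC1-like (and behavioral) shape.
    """

    r_max: float = 1.0
    center: float = 50.0     # ms
    width: float = 15.0      # ms
    baseline: float = 0.05

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.width <= 0:
            raise ValueError("r_max and width must be positive")

    def response(self, ipi_ms) -> np.ndarray:
        x = np.asarray(ipi_ms, dtype=float)
        return self.baseline + self.r_max * np.exp(
            -(x - self.center) ** 2 / (2.0 * self.width ** 2))

    kind = "band_pass_gaussian"


def vpn1_like_model(r_max: float = 1.0) -> LowPassHill:
    return LowPassHill(r_max=r_max)


def pc1_like_model(r_max: float = 1.0) -> BandPassGaussian:
    return BandPassGaussian(r_max=r_max)


_MODEL_TYPES = {"low_pass_hill": LowPassHill, "band_pass_gaussian": BandPassGaussian}


# ---------------------------------------------------------------------------
# Indicator kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GCaMPKernel:
    """Double-exponential calcium-indicator impulse response, peak 1.

    k(t) = (1 - exp(-t/rise_tau)) exp(-t/decay_tau), t >= 0, normalized.
    Defaults (rise 0.08 s, decay 0.6 s) are order-of-magnitude GCaMP6m
    kinetics; the slow decay is what low-pass-filters pulse trains into a
    single envelope.
    """

    rise_tau: float = 0.08
    decay_tau: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.rise_tau < self.decay_tau:
            raise ValueError("need 0 < rise_tau < decay_tau")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        raw = np.where(t >= 0,
                       (1.0 - np.exp(-np.maximum(t, 0) / self.rise_tau))
                       * np.exp(-np.maximum(t, 0) / self.decay_tau), 0.0)
        t_peak = self.rise_tau * np.log1p(self.decay_tau / self.rise_tau)
        peak = (1.0 - np.exp(-t_peak / self.rise_tau)) * np.exp(-t_peak / self.decay_tau)
        return raw / peak


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _two_means_blob_contour() -> float:
    """Asymptotic 2-means decision level for a Gaussian blob on a dominant
    uniform background, as a fraction of the blob's peak.

    With cluster centers c_bg (background) and c_fg (mean blob excess above
    the threshold contour), the 2-means boundary sits midway between them;
    for a 2-D Gaussian profile this reduces to the fixed point
    2x ln(1/x) = 1 - x, x ~ 0.285.
    """
    from scipy.optimize import brentq
    return float(brentq(lambda x: 2 * x * np.log(1 / x) - (1 - x), 1e-9, 0.999))


TWO_MEANS_CONTOUR = _two_means_blob_contour()


@dataclass(frozen=True)
class BlobROI:
    """A planted Gaussian-blob ROI: center (row, col), SD and peak height.

    ``support`` (3-sigma disc) is where the blob's calcium dynamics are
    rendered; ``mask`` is the ground-truth ROI extent for segmentation
    scoring, defined at the ``mask_level`` intensity contour.  The default
    is the 2-means decision contour (~28.5% of peak): pixels dimmer than
    that are, to any intensity-based segmentation, part of the background,
    so a Gaussian blob has no sharper well-defined extent.
    """

    row: float
    col: float
    sigma_px: float = 3.0
    peak: float = 100.0
    mask_level: float = TWO_MEANS_CONTOUR

    def profile(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        return self.peak * np.exp(
            -((rr - self.row) ** 2 + (cc - self.col) ** 2)
            / (2.0 * self.sigma_px ** 2))

    def support(self, shape: tuple[int, int], trunc_sd: float = 3.0) -> np.ndarray:
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        return ((rr - self.row) ** 2 + (cc - self.col) ** 2) \
            <= (trunc_sd * self.sigma_px) ** 2

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return self.profile(shape) >= self.mask_level * self.peak


@dataclass
class SyntheticGroundTruth:
    """Everything needed to regenerate a synthetic dataset bit-for-bit."""

    rois: list[BlobROI] = field(default_factory=list)
    tuning: LowPassHill | BandPassGaussian = field(default_factory=pc1_like_model)
    kernel: GCaMPKernel = field(default_factory=GCaMPKernel)
    baseline: float = 20.0        # background fluorescence (counts)
    noise_sd: float = 2.0         # noise SD at background intensity
    gain_sigma: float = 0.2       # lognormal subject gain jitter (log-SD)
    # behavioral logistic-in-intensity model
    ec50_db: float = 70.6
    slope_db: float = 0.5         # 1/dB
    p_max: float = 0.85           # chaining probability at saturation, 35 ms
    p_silence: float = 0.02
    decay_tau_s: float = 30.0     # post-song chaining decay
    seed: int = 0

    def roi_masks(self, shape: tuple[int, int]) -> np.ndarray:
        """Ground-truth label image (later ROIs win where masks touch)."""
        labels = np.zeros(shape, dtype=np.int32)
        for i, roi in enumerate(self.rois, start=1):
            labels[roi.mask(shape)] = i
        return labels

    def to_json(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        doc["tuning"]["kind"] = self.tuning.kind
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticGroundTruth":
        text = _read_source(source)
        doc = json.loads(text)
        tun = doc.pop("tuning")
        model = _MODEL_TYPES[tun.pop("kind")](**tun)
        rois = [BlobROI(**r) for r in doc.pop("rois")]
        kernel = GCaMPKernel(**doc.pop("kernel"))
        return cls(rois=rois, tuning=model, kernel=kernel, **doc)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_movie(truth: SyntheticGroundTruth, events: list[dict],
                   duration_s: float, shape: tuple[int, int] = (128, 128),
                   frame_rate: float = 13.0,
                   seed: int | None = None) -> Movie:
    """Render a calcium movie from planted ground truth.

    Each blob's dF/F trace is the sum over events of the tuning-model
    amplitude (at the event's IPI) times the indicator kernel; pixel
    fluorescence inside a blob's support is (baseline + blob) * (1 + dF/F),
    so the pipeline's measured peak dF/F matches the planted amplitude.
    Noise is Gaussian with SD proportional to sqrt(intensity), equal to
    ``noise_sd`` at the background level.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames) / frame_rate

    dff = np.zeros(n_frames)
    for ev in events:
        amp = float(truth.tuning.response(ev["ipi_ms"])) \
            if ev.get("ipi_ms") is not None else 0.0
        dff += amp * truth.kernel.evaluate(t - ev["onset"])

    frames = np.broadcast_to(
        np.full(shape, truth.baseline), (n_frames, *shape)).copy()
    for roi in truth.rois:
        prof = roi.profile(shape)
        sup = roi.support(shape)
        static = truth.baseline + prof[sup]
        frames[:, sup] = static[None, :] * (1.0 + dff[:, None])
    if truth.noise_sd > 0:
        sd = truth.noise_sd * np.sqrt(frames / truth.baseline)
        frames = frames + rng.standard_normal(frames.shape) * sd
    return Movie(np.maximum(frames, 0.0), frame_rate)


def simulate_tuning_table(truth: SyntheticGroundTruth,
                          ipi_grid=DEFAULT_IPI_GRID,
                          n_subjects: int = 10,
                          noise_sd: float = 0.05,
                          seed: int | None = None) -> pd.DataFrame:
    """Per-subject peak dF/F table: tuning(ipi) * gain_j + noise.

    Gains are lognormal with log-SD ``gain_sigma``; noise is additive
    Gaussian.  Returns a long table (subject, ipi_ms, value) ready for
    :func:`songtune.tuning.build_tuning`.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ipi_grid = np.asarray(ipi_grid, dtype=float)
    base = truth.tuning.response(ipi_grid)
    rows = []
    for j in range(n_subjects):
        gain = rng.lognormal(mean=0.0, sigma=truth.gain_sigma)
        vals = base * gain + rng.standard_normal(len(ipi_grid)) * noise_sd
        rows.append(pd.DataFrame({"subject": f"fly{j:02d}",
                                  "ipi_ms": ipi_grid, "value": vals}))
    return pd.concat(rows, ignore_index=True)


def _chaining_probability(truth: SyntheticGroundTruth, level_db: float,
                          ipi_ms: float | None) -> float:
    """Instantaneous chaining probability during song playback."""
    w = float(truth.tuning.response(ipi_ms)) / truth.tuning.r_max \
        if ipi_ms is not None else 1.0
    drive = float(expit(truth.slope_db * (level_db - truth.ec50_db)))
    return truth.p_silence + (truth.p_max - truth.p_silence) * w * drive


def simulate_chaining(truth: SyntheticGroundTruth,
                      protocol: StimulusProtocol,
                      n_groups: int = 14,
                      interval_s: float = 3.0,
                      group_size: int = 6,
                      seed: int | None = None) -> list[ChainCountSeries]:
    """Binomial chain counts for groups of flies under a playback protocol.

    At each 3-s sample the count is Binomial(group_size, p); during a song
    segment p follows the logistic-in-intensity x IPI-weight model, in
    silence it sits at ``p_silence``, and after song offset the above-
    silence drive decays exponentially with ``decay_tau_s`` (chaining
    persists then fades).  Fly-fly dependence within a chain is ignored.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    times = np.arange(0.0, protocol.total_s, interval_s)
    segs = protocol.segments

    p = np.full(len(times), truth.p_silence)
    last_active = None  # (end_time, p at end)
    for i, t in enumerate(times):
        active = None
        for seg in segs:
            if seg.start_s <= t < seg.start_s + seg.duration_s:
                active = seg
                break
            # intermittent trains: treat the whole inter-train period as song
            per = protocol.metadata.get("period_s")
            if per is not None and seg.start_s <= t < seg.start_s + per:
                active = seg
                break
        if active is not None:
            ipi = active.spec.ipi_ms if hasattr(active.spec, "ipi_ms") else None
            p[i] = _chaining_probability(truth, active.level_db, ipi)
            last_active = (t, p[i])
        elif last_active is not None and t > last_active[0]:
            decay = np.exp(-(t - last_active[0]) / truth.decay_tau_s)
            p[i] = truth.p_silence + (last_active[1] - truth.p_silence) * decay

    return [
        ChainCountSeries(rng.binomial(group_size, p), interval_s,
                         group_size, t0=0.0, group_id=f"group{g:02d}")
        for g in range(n_groups)
    ]
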