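"""End-to-end analysis pipelines with reproducible configuration.

Each runner composes the module-level operations into the study's analysis
chains and returns a plain dict that serializes to JSON:

* imaging: movie -> segmentation -> cleanup -> traces -> most-responding
  ROI -> smoothed peak dF/F per event -> per-subject tuning curve (and
  optionally a sigmoid intensity fit);
* behavior: chain counts + protocol -> CI blocks, heat map, summed CI
  (and optionally a sigmoid fit of CI vs intensity);
* correlation report: normalized neural and behavioral curves -> Pearson r
  with permutation p per neural curve, plus Meng's z comparing the two
  neural/behavior correlations.

Every report embeds the seed and a hash of the resolved configuration so a
re-run from the recorded config reproduces the outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import segmentation as seg
from . import stats as st
from . import traces as tm
from . import tuning as tun
from .stimulus import StimulusProtocol

__all__ = [
    "IMAGING_DEFAULTS",
    "run_imaging_pipeline",
    "run_behavior_pipeline",
    "run_correlation_report",
]

logger = logging.getLogger("songtune")

IMAGING_DEFAULTS = {
    "mode": "soma",            # 'soma' | 'neurite'
    "k_soma": 2,
    "k_neurite": 3,
    "cleanup_radius": 1,
    "smooth_window": 11,
    "pre_s": 1.0,
    "post_s": 5.0,
    "seed": 0,
    "normalize": True,
    "axis": "ipi_ms",
}


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> dict:
    """Read a YAML run configuration."""
    import yaml
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def run_imaging_pipeline(subjects: dict[str, tuple[seg.Movie, list[dict]]],
                         config: dict | None = None) -> dict:
    """Run the imaging chain over a set of subjects.

    ``subjects`` maps a subject id to (movie, event list); events are dicts
    with at least ``onset`` (s) and the tuning-axis value (``ipi_ms`` or
    ``level_db``).  Returns per-subject peak dF/F, the (optionally
    per-subject-normalized) tuning curve and provenance.
    """
    cfg = {**IMAGING_DEFAULTS, **(config or {})}
    if not subjects:
        raise ValueError("no subjects provided")
    for sid, (_, events) in subjects.items():
        if len(events) == 0:
            raise ValueError(f"subject {sid!r}: empty event table")

    rows = []
    selected = {}
    for sid, (movie, events) in subjects.items():
        logger.info("imaging: subject %s (%d frames, %d events)",
                    sid, movie.n_frames, len(events))
        if cfg["mode"] == "soma":
            mask = seg.segment_soma(movie, k=cfg["k_soma"], seed=cfg["seed"])
        elif cfg["mode"] == "neurite":
            mask = seg.segment_neurite(movie, k=cfg["k_neurite"],
                                       seed=cfg["seed"])
        else:
            raise ValueError(f"unknown segmentation mode {cfg['mode']!r}")
        mask = seg.cleanup_mask(mask, radius=cfg["cleanup_radius"])
        if mask.n_rois == 0:
            raise RuntimeError(f"subject {sid!r}: no ROIs after cleanup")
        traces = seg.extract_traces(movie, mask)
        roi_id = seg.most_responding_roi(
            traces, events, pre_s=cfg["pre_s"], post_s=cfg["post_s"],
            smooth_window=cfg["smooth_window"])
        selected[sid] = roi_id
        trace = tm.smooth_trace(next(t for t in traces if t.roi_id == roi_id),
                                window=cfg["smooth_window"])
        for ev in events:
            resp = tm.peak_dff(trace, ev["onset"],
                               pre_s=cfg["pre_s"], post_s=cfg["post_s"])
            rows.append({"subject": sid, cfg["axis"]: ev[cfg["axis"]],
                         "roi_id": roi_id, "value": resp.peak_dff})

    table = pd.DataFrame(rows)
    curve = tun.build_tuning(table, axis=cfg["axis"])
    if cfg["normalize"]:
        curve = tun.normalize_per_subject(curve)
    result = {
        "config": cfg, "config_hash": _config_hash(cfg), "seed": cfg["seed"],
        "responses": table, "tuning_curve": curve, "selected_rois": selected,
    }
    if cfg.get("fit_sigmoid"):
        result["sigmoid_fit"] = tun.fit_sigmoid(curve.conditions, curve)
    return result


def run_behavior_pipeline(series_list: list[bhv.ChainCountSeries],
                          protocol: StimulusProtocol | None = None,
                          config: dict | None = None) -> dict:
    """Score chaining for a set of groups against a playback protocol."""
    cfg = {"block_s": 30.0, **(config or {})}
    if not series_list:
        raise ValueError("no chain-count series provided")
    if protocol is not None:
        for s in series_list:
            if s.sample_times[-1] + s.interval_s < protocol.total_s - 1e-9:
                raise ValueError(
                    f"group {s.group_id!r}: series ends at "
                    f"{s.sample_times[-1]:.0f}s but the protocol runs to "
                    f"{protocol.total_s:.0f}s")

    results = [bhv.chaining_index(s, block_s=cfg["block_s"])
               for s in series_list]
    heat = bhv.chaining_heatmap(results)
    out = {
        "config": cfg, "config_hash": _config_hash(cfg),
        "ci": results, "heatmap": heat,
        "ci_table": pd.concat([r.to_frame() for r in results],
                              ignore_index=True),
    }
    if protocol is not None and "levels_db" in protocol.metadata:
        # ramp protocol: mean CI per level block across groups, sigmoid fit
        levels = np.asarray(protocol.metadata["levels_db"], dtype=float)
        lead = protocol.metadata["lead_silence_s"]
        block_s = protocol.metadata["block_s"]
        per_level = []
        for i in range(len(levels)):
            window = (lead + i * block_s, lead + (i + 1) * block_s)
            per_level.append([bhv.summed_ci(r, window) for r in results])
        ci_vs_db = np.asarray(per_level, dtype=float).mean(axis=1)
        out["levels_db"] = levels
        out["ci_vs_db"] = ci_vs_db
        if cfg.get("fit_sigmoid", True) and len(levels) >= 4:
            out["sigmoid_fit"] = tun.fit_sigmoid(levels, ci_vs_db)
    if protocol is not None and "song_window" in protocol.metadata:
        window = tuple(protocol.metadata["song_window"])
        out["summed_ci"] = [bhv.summed_ci(r, window) for r in results]
    return out


def run_correlation_report(neural_curves: dict[str, tun.TuningCurve],
                           behavior_curve: tun.TuningCurve,
                           config: dict | None = None) -> dict:
    """Correlate each neural tuning curve with behavior across IPIs.

    Curves are max-normalized (group mean / max) and aligned on the
    intersection of their condition grids.  Each pair gets a Pearson r and
    a one-sided permutation p; when exactly two neural curves are given,
    Meng's z compares their behavior correlations (r_x = correlation
    between the two neural curves on the shared grid, n = number of shared
    conditions).
    """
    cfg = {"n_perm": 10_000, "seed": 0, "sided": "greater",
           "meng_sided": "two-sided", **(config or {})}
    if not neural_curves:
        raise ValueError("no neural curves provided")

    report = {"config": cfg, "config_hash": _config_hash(cfg),
              "seed": cfg["seed"], "pairs": {}}
    aligned = {}
    for name, curve in neural_curves.items():
        shared = np.intersect1d(curve.conditions, behavior_curve.conditions)
        if len(shared) < 4:
            raise ValueError(
                f"curve {name!r}: only {len(shared)} shared conditions")
        ni = np.searchsorted(curve.conditions, shared)
        bi = np.searchsorted(behavior_curve.conditions, shared)
        x = curve.mean[ni] / curve.mean[ni].max()
        y = behavior_curve.mean[bi] / behavior_curve.mean[bi].max()
        aligned[name] = (shared, x, y)
        res = st.permutation_corr_test(x, y, n_perm=cfg["n_perm"],
                                       seed=cfg["seed"], sided=cfg["sided"])
        report["pairs"][name] = res

    if len(neural_curves) == 2:
        (n1, (s1, x1, y1)), (n2, (s2, x2, y2)) = aligned.items()
        shared = np.intersect1d(s1, s2)
        i1 = np.searchsorted(s1, shared)
        i2 = np.searchsorted(s2, shared)
        r1 = report["pairs"][n1].r_observed
        r2 = report["pairs"][n2].r_observed
        r_x = st.pearson_r(x1[i1], x2[i2])
        report["meng"] = st.meng_z(r1, r2, r_x, n=len(shared),
                                   sided=cfg["meng_sided"])
        report["meng_order"] = [n1, n2]
    return report
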