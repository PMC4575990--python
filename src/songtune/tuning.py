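"""Tuning curves, sigmoid (EC50) fits and the neuron-to-neuron transfer
function.

A tuning curve holds per-subject responses (peak dF/F or chaining index)
across conditions on one axis (IPI in ms, or intensity in dB), with the
group mean and SEM (sample SD / sqrt(n)).  Per-subject normalization
divides each subject's row by its maximum before averaging, the convention
used when comparing curves across flies or across neurons and behavior.

Intensity-response data are fit with a four-parameter logistic

    R(I) = floor + (ceiling - floor) / (1 + exp(-s (I - EC50)))

whose half-maximal point is EC50 by construction.  The transfer function
between two tuning curves is the element-wise ratio of their means with
first-order (independent-samples) SEM propagation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "TuningCurve",
    "SigmoidFit",
    "TransferFunction",
    "build_tuning",
    "normalize_per_subject",
    "fit_sigmoid",
    "sigmoid4",
    "transfer_function",
]


@dataclass
class TuningCurve:
    """Per-subject responses on one stimulus axis.

    ``values[i, j]`` is subject i's response at ``conditions[j]``.
    """

    conditions: np.ndarray
    values: np.ndarray          # (n_subjects, n_conditions)
    subjects: list[str]
    axis: str = "ipi_ms"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.conditions = np.asarray(self.conditions, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.subjects), len(self.conditions)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"(n_subjects={len(self.subjects)}, "
                f"n_conditions={len(self.conditions)})")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.n_subjects
        if n < 2:
            return np.zeros(len(self.conditions))
        return self.values.std(axis=0, ddof=1) / np.sqrt(n)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.conditions,
                          index=pd.Index(self.subjects, name="subject"))
        return df.reset_index().melt(id_vars="subject", var_name=self.axis,
                                     value_name="value")


def build_tuning(table: pd.DataFrame, axis: str = "ipi_ms",
                 subject_col: str = "subject",
                 value_col: str = "value") -> TuningCurve:
    """Pivot a long (subject, condition, value) table into a TuningCurve.

    Replicate (subject, condition) rows are averaged; every subject must
    cover every condition.
    """
    if table.empty:
        raise ValueError("empty response table")
    pivot = table.pivot_table(index=subject_col, columns=axis,
                              values=value_col, aggfunc="mean")
    if pivot.isna().any().any():
        missing = pivot.isna().stack()
        missing = missing[missing].index.tolist()
        raise ValueError(f"missing subject x condition cells: {missing}")
    return TuningCurve(pivot.columns.to_numpy(dtype=float),
                       pivot.to_numpy(), [str(s) for s in pivot.index],
                       axis=axis)


def normalize_per_subject(curve: TuningCurve) -> TuningCurve:
    """Divide each subject's row by its maximum response.

    Subjects whose maximum is not positive carry no usable signal and are
    excluded with a warning.  Idempotent: normalizing twice is a no-op.
    """
    maxima = curve.values.max(axis=1)
    keep = maxima > 0
    if not np.any(keep):
        raise ValueError("no subject has a positive maximum response")
    if not np.all(keep):
        dropped = [s for s, k in zip(curve.subjects, keep) if not k]
        warnings.warn(f"excluding subjects with non-positive maxima: {dropped}",
                      stacklevel=2)
    values = curve.values[keep] / maxima[keep, None]
    subjects = [s for s, k in zip(curve.subjects, keep) if k]
    return TuningCurve(curve.conditions.copy(), values, subjects,
                       axis=curve.axis, normalized=True)


# ---------------------------------------------------------------------------
# Sigmoid intensity-response fit
# ---------------------------------------------------------------------------

def sigmoid4(x: np.ndarray, floor: float, ceiling: float,
             ec50: float, slope: float) -> np.ndarray:
    """Four-parameter logistic; EC50 is the half-maximal abscissa."""
    return floor + (ceiling - floor) * expit(slope * (np.asarray(x) - ec50))


@dataclass
class SigmoidFit:
    """Fitted 4PL parameters with convergence/flatness diagnostics."""

    ec50: float
    slope: float
    floor: float
    ceiling: float
    residual_norm: float
    converged: bool
    flat: bool = False
    message: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        return sigmoid4(x, self.floor, self.ceiling, self.ec50, self.slope)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def fit_sigmoid(intensities: np.ndarray, responses, flat_rtol: float = 1e-3
                ) -> SigmoidFit:
    """Least-squares 4PL fit of response vs intensity (dB).

    ``responses`` may be a TuningCurve (its group mean is fit) or a 1-D
    array.  The fit is multi-started from EC50 initializations at the data
    quantiles; the best residual wins.  A flat dataset (ceiling ~ floor) or
    an EC50 outside the data span +/- one span is flagged rather than
    silently reported.
    """
    x = np.asarray(intensities, dtype=float)
    y = responses.mean if isinstance(responses, TuningCurve) else \
        np.asarray(responses, dtype=float)
    if len(x) != len(y):
        raise ValueError("intensities and responses differ in length")
    if len(x) < 4:
        raise ValueError("need at least 4 intensity levels for a 4PL fit")

    span = float(x.max() - x.min())
    yspan = float(y.max() - y.min())
    if yspan <= flat_rtol * max(abs(y.max()), 1e-12):
        return SigmoidFit(float(np.median(x)), 0.0, float(y.mean()),
                          float(y.mean()), 0.0, converged=False, flat=True,
                          message="flat responses: ceiling ~ floor")

    best = None
    for q in (0.25, 0.5, 0.75):
        p0 = [float(y.min()), float(y.max()),
              float(np.quantile(x, q)), 4.0 / max(span, 1e-9)]
        try:
            popt, _ = curve_fit(sigmoid4, x, y, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(y - sigmoid4(x, *popt)))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.inf,
                          converged=False, message="optimizer did not converge")

    (floor, ceiling, ec50, slope), resid = best
    if slope < 0:  # re-express with increasing slope convention
        floor, ceiling, slope = ceiling, floor, -slope
    if floor > ceiling:
        floor, ceiling = ceiling, floor
    in_range = x.min() - span <= ec50 <= x.max() + span
    return SigmoidFit(float(ec50), float(slope), float(floor), float(ceiling),
                      resid, converged=in_range,
                      message="" if in_range else
                      "EC50 outside data span +/- one span")


# ---------------------------------------------------------------------------
# Transfer function
# ---------------------------------------------------------------------------

@dataclass
class TransferFunction:
    """Element-wise ratio of two tuning curves with propagated SEM."""

    conditions: np.ndarray
    ratio: np.ndarray
    sem: np.ndarray
    axis: str = "ipi_ms"
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"axis": self.axis, "conditions": self.conditions.tolist(),
               "ratio": self.ratio.tolist(), "sem": self.sem.tolist(),
               "metadata": self.metadata}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def transfer_function(numerator: TuningCurve, denominator: TuningCurve,
                      min_denominator: float = 1e-9) -> TransferFunction:
    """Ratio of group means, condition by condition.

    ratio_i = mu_num,i / mu_den,i with first-order error propagation
    assuming independent samples (different flies / genotypes):

        sem_i = |ratio_i| sqrt((s_num,i/mu_num,i)^2 + (s_den,i/mu_den,i)^2)

    Conditions where the denominator mean is at or below
    ``min_denominator`` are dropped with a warning.
    """
    if numerator.axis != denominator.axis or \
            not np.array_equal(numerator.conditions, denominator.conditions):
        raise ValueError("tuning curves must share the same condition axis")
    mu_n, mu_d = numerator.mean, denominator.mean
    se_n, se_d = numerator.sem, denominator.sem
    keep = mu_d > min_denominator
    if not np.all(keep):
        warnings.warn(
            f"dropping conditions with near-zero denominator: "
            f"{numerator.conditions[~keep].tolist()}", stacklevel=2)
    mu_n, mu_d, se_n, se_d = mu_n[keep], mu_d[keep], se_n[keep], se_d[keep]
    ratio = mu_n / mu_d
    sem = np.abs(ratio) * np.sqrt((se_n / mu_n) ** 2 + (se_d / mu_d) ** 2)
    return TransferFunction(numerator.conditions[keep], ratio, sem,
                            axis=numerator.axis)
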