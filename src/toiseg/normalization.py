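"""Piecewise-linear approximation and reference-state z-normalization.

Each changepoint segment carries its own independently fitted
ordinary-least-squares line (no continuity constraint — the approximation is
deliberately step-like at changepoints).  Signals and their PLAs are then
z-normalized against the subject's own reference TOI (usually basal):

    z(t)    = (y(t)    - mean_ref(y))   / sd_ref(y)
    z_pla(t) = (y_hat(t) - mean_ref(y_hat)) / sd_ref(y_hat)

where the reference statistics are computed over the *optimal* reference TOI
only — transition-window samples, which carry intervention artifacts, never
enter them.  For two post-intervention TOIs k and l the aligned difference
series satisfies the identity

    z(t_k) - z(t_l) = (y(t_k) - y(t_l)) / sd_ref(y)

which makes between-state contrasts comparable across subjects regardless of
each subject's raw perfusion level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .changepoint import ChangepointSet
from .cohort import PerfusionRecord
from .transitions import SegmentationResult

__all__ = [
    "DegenerateReferenceError",
    "PLAModel",
    "NormalizedSignal",
    "DifferencePair",
    "fit_pla",
    "znormalize",
    "toi_difference",
]


class DegenerateReferenceError(ValueError):
    """The reference TOI has zero standard deviation."""


@dataclass
class PLAModel:
    """Per-segment OLS lines over a changepoint partition."""

    breakpoints: ChangepointSet
    coefficients: list[tuple[float, float]]  # (slope, intercept) per segment, x = sample index
    fitted: np.ndarray
    total_rss: float = float("nan")


@dataclass
class NormalizedSignal:
    """z and z_pla series with the reference statistics that produced them."""

    ref_label: str
    ref_mean: float
    ref_sd: float
    ref_mean_pla: float
    ref_sd_pla: float
    z: np.ndarray
    z_pla: np.ndarray


@dataclass
class DifferencePair:
    """Aligned difference between two TOIs' normalized segments."""

    toi_k: int
    toi_l: int
    diff: np.ndarray
    alignment_len: int
    source: str = "z"


def fit_pla(values, cpts: ChangepointSet) -> PLAModel:
    """Fit an independent least-squares line on every changepoint segment.

    The total residual sum of squares equals the unpenalized part of the
    segmentation objective at the same changepoints.
    """
    y = np.asarray(values, dtype=float)
    if cpts.n != len(y):
        raise ValueError(f"changepoints are for n={cpts.n}, values have n={len(y)}")
    fitted = np.empty_like(y)
    coefs: list[tuple[float, float]] = []
    for a, b in cpts.segments():
        if b - a + 1 < 2:
            raise ValueError(f"segment [{a}, {b}] shorter than 2 samples")
        x = np.arange(a, b + 1, dtype=float)
        seg = y[a - 1 : b]
        xm, ym = x.mean(), seg.mean()
        sxx = float(np.sum((x - xm) ** 2))
        slope = float(np.sum((x - xm) * (seg - ym)) / sxx)
        intercept = ym - slope * xm
        coefs.append((slope, intercept))
        fitted[a - 1 : b] = slope * x + intercept
    rss = float(np.sum((fitted - y) ** 2))
    return PLAModel(breakpoints=cpts, coefficients=coefs, fitted=fitted, total_rss=rss)


def znormalize(
    record: PerfusionRecord,
    pla: PLAModel,
    seg: SegmentationResult,
    ref: int = 1,
) -> NormalizedSignal:
    """z-normalize a subject's signal and PLA against a reference TOI.

    Reference mean and standard deviation (sample, n-1 divisor) are computed
    over the optimal reference TOI only; the normalization itself is applied
    to every sample of the record (including transitions, for plotting).
    The PLA is normalized with its own reference statistics.
    """
    a, b = seg.otoi[ref - 1]
    y_ref = record.values[a - 1 : b]
    yhat_ref = pla.fitted[a - 1 : b]
    ref_mean = float(y_ref.mean())
    ref_sd = float(y_ref.std(ddof=1))
    ref_mean_pla = float(yhat_ref.mean())
    ref_sd_pla = float(yhat_ref.std(ddof=1))
    if ref_sd == 0.0 or ref_sd_pla == 0.0:
        raise DegenerateReferenceError(
            f"subject {record.subject_index}: reference TOI {ref} has zero "
            "standard deviation"
        )
    label = seg.toi_labels[ref - 1] if seg.toi_labels else str(ref)
    return NormalizedSignal(
        ref_label=label,
        ref_mean=ref_mean,
        ref_sd=ref_sd,
        ref_mean_pla=ref_mean_pla,
        ref_sd_pla=ref_sd_pla,
        z=(record.values - ref_mean) / ref_sd,
        z_pla=(pla.fitted - ref_mean_pla) / ref_sd_pla,
    )


def toi_difference(
    norm: NormalizedSignal,
    seg: SegmentationResult,
    k: int,
    l: int,
    source: str = "z",
) -> DifferencePair:
    """Aligned difference of normalized segments of TOIs ``k`` and ``l``.

    Segments are aligned by within-TOI sample order from each TOI's first
    post-transition sample and truncated to the shorter length (padding would
    inject invented values into downstream statistics).
    """
    if k == l:
        raise ValueError("TOI indices must differ")
    n_toi = seg.n_toi
    for j in (k, l):
        if not (1 <= j <= n_toi):
            raise ValueError(f"TOI index {j} out of range 1..{n_toi}")
    series = norm.z if source == "z" else norm.z_pla
    if source not in ("z", "z_pla"):
        raise ValueError("source must be 'z' or 'z_pla'")
    zk = series[seg.toi_slice(k)]
    zl = series[seg.toi_slice(l)]
    if zk.size == 0 or zl.size == 0:
        raise ValueError(f"TOI {k if zk.size == 0 else l} is empty")
    m = min(len(zk), len(zl))
    return DifferencePair(
        toi_k=k, toi_l=l, diff=zk[:m] - zl[:m], alignment_len=m, source=source
    )
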