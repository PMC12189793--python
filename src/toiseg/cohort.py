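"""In-memory cohort containers: per-subject recordings and per-TOI matrices.

A recording is one subject's uniformly sampled perfusion trace together with
the experimenter's TOI markers (one contiguous marker block per experimental
state, basal first).  All segment arithmetic downstream is done in 1-based
sample-index space; real time stamps are kept only for plotting and export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .normalization import NormalizedSignal
    from .transitions import SegmentationResult

#: Relative tolerance on sampling-interval uniformity.
UNIFORMITY_RTOL = 1e-6


@dataclass
class PerfusionRecord:
    """One subject's perfusion recording with metadata.

    Parameters
    ----------
    subject_index : int
        1-based position of the subject in the cohort.
    internal_code : str
        Experimenter's label, e.g. ``"WT14D4"``.
    group : str
        ``"control"`` or ``"experimental"``.
    sex : str
        ``"female"`` or ``"male"``.
    times : ndarray
        Strictly increasing, uniformly spaced time stamps (length ``ni``).
    markers : ndarray of str
        Per-sample TOI label; labels form contiguous non-repeating blocks.
    values : ndarray
        Perfusion measurements (arbitrary perfusion units), length ``ni``.
    """

    subject_index: int
    internal_code: str
    group: str
    sex: str
    times: np.ndarray
    markers: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.markers = np.asarray(self.markers, dtype=object)
        self.validate()

    @property
    def n(self) -> int:
        """Number of samples ``ni``."""
        return len(self.values)

    def validate(self) -> None:
        if not (len(self.times) == len(self.markers) == len(self.values)):
            raise ValueError(
                f"subject {self.subject_index}: times/markers/values lengths differ "
                f"({len(self.times)}/{len(self.markers)}/{len(self.values)})"
            )
        if self.n < 2:
            raise ValueError(f"subject {self.subject_index}: fewer than 2 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            from .cohort_io import TimeOrderError

            raise TimeOrderError(
                f"subject {self.subject_index}: times are not strictly increasing"
            )
        if dt.size and not np.allclose(dt, dt.mean(), rtol=UNIFORMITY_RTOL, atol=1e-9 * abs(dt.mean())):
            raise ValueError(
                f"subject {self.subject_index}: sampling is not uniform within tolerance"
            )
        # markers must be contiguous, non-repeating blocks
        labels = self.marker_labels()
        if len(set(labels)) != len(labels):
            from .cohort_io import MarkerError

            raise MarkerError(
                f"subject {self.subject_index}: marker label repeats in a "
                "non-contiguous block"
            )

    def marker_labels(self) -> list[str]:
        """Marker labels in order of first appearance (basal is first)."""
        labels: list[str] = []
        for m in self.markers:
            if not labels or labels[-1] != m:
                labels.append(m)
        return labels

    def marker_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous marker blocks as ``(label, first, last)`` 1-based closed ranges."""
        blocks: list[tuple[str, int, int]] = []
        start = 1
        for i in range(1, self.n):
            if self.markers[i] != self.markers[i - 1]:
                blocks.append((str(self.markers[i - 1]), start, i))
                start = i + 1
        blocks.append((str(self.markers[-1]), start, self.n))
        return blocks


@dataclass
class Cohort:
    """An ordered collection of recordings sharing one TOI vocabulary."""

    records: list[PerfusionRecord]
    toi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.toi_labels and self.records:
            self.toi_labels = self.records[0].marker_labels()
        self.validate()

    @property
    def n_subjects(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        idx = sorted(r.subject_index for r in self.records)
        if idx != list(range(1, len(self.records) + 1)):
            raise ValueError("subject_index values must be unique and dense 1..N")
        for r in self.records:
            if r.marker_labels() != self.toi_labels:
                from .cohort_io import MarkerError

                raise MarkerError(
                    f"subject {r.subject_index}: marker blocks {r.marker_labels()} "
                    f"do not match cohort TOI labels {self.toi_labels}"
                )

    def record(self, subject_index: int) -> PerfusionRecord:
        for r in self.records:
            if r.subject_index == subject_index:
                return r
        raise KeyError(subject_index)


@dataclass
class ToiMatrix:
    """Per-TOI columns of one subject's series, ragged or NaN-padded.

    ``columns[j]`` holds the chosen series restricted to optimal TOI ``j``;
    transition samples appear in no column.  The padded form is rectangular
    with ``NaN`` as the explicit missing-value sentinel.
    """

    subject_index: int
    labels: list[str]
    columns: list[np.ndarray]

    @property
    def padded(self) -> np.ndarray:
        nrow = max((len(c) for c in self.columns), default=0)
        out = np.full((nrow, len(self.columns)), np.nan)
        for j, col in enumerate(self.columns):
            out[: len(col), j] = col
        return out

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.padded, columns=self.labels).to_csv(path, index=False)


def toi_matrix(
    record: PerfusionRecord,
    seg: "SegmentationResult",
    source: str = "values",
    norm: "NormalizedSignal | None" = None,
) -> ToiMatrix:
    """Format one subject's series into per-optimal-TOI columns.

    Parameters
    ----------
    source : {"values", "z", "pla_z"}
        Which series to slice: raw perfusion values, the z-normalized signal,
        or the z-normalized piecewise-linear approximation.  The latter two
        require ``norm``.
    """
    if seg.otoi[-1][1] != record.n:
        raise ValueError(
            f"subject {record.subject_index}: segmentation covers {seg.otoi[-1][1]} "
            f"samples but record has {record.n}"
        )
    if source == "values":
        series = record.values
    elif source == "z":
        if norm is None:
            raise ValueError("source 'z' requires a NormalizedSignal")
        series = norm.z
    elif source == "pla_z":
        if norm is None:
            raise ValueError("source 'pla_z' requires a NormalizedSignal")
        series = norm.z_pla
    else:
        raise ValueError(f"unknown source {source!r}")
    cols = [series[a - 1 : b].copy() for a, b in seg.otoi]
    labels = list(seg.toi_labels) if seg.toi_labels else [f"toi{j+1}" for j in range(len(cols))]
    return ToiMatrix(subject_index=record.subject_index, labels=labels, columns=cols)
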