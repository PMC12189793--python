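"""Optimal TOIs and transition windows from detected changepoints.

Given a subject's changepoint vector and the experimenter's marker blocks,
this module (1) splits the interior changepoints into per-TOI subsets by the
marker of the sample at each changepoint position, (2) derives the
intervention time of each TOI as the earliest changepoint in its subset, and
(3) builds the optimal segmentation: a symmetric transition window of
half-width ``k`` around each intervention time (``k`` = the number of
interior changepoints outside the basal subset), with the optimal TOIs
filling the gaps.  Transition windows absorb the instrumentation artifacts
produced by applying a stimulus, so every downstream statistic can be
computed on artifact-free samples only.

All arithmetic is in 1-based sample-index space; ranges are closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .changepoint import ChangepointSet
from .cohort import PerfusionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "InadmissibleWindowError",
    "SegmentationResult",
    "split_by_marker",
    "intervention_times",
    "algorithm1",
]


class InadmissibleWindowError(ValueError):
    """A transition window would overlap a neighbour or empty a TOI."""


@dataclass
class SegmentationResult:
    """Optimal TOIs and transition windows for one subject.

    Attributes
    ----------
    it_times : ndarray of float
        Intervention time per TOI (sample index).  Entry 1 is computed when
        the basal subset is nonempty but is unused by the windowing; NaN
        marks "unused/undefined".
    k : int
        Transition half-width: the count of interior changepoints outside
        the basal TOI subset.
    otoi : list of (a, b)
        Closed index range of each optimal TOI, one per TOI.
    ott : list of (a, b)
        Closed index range of each transition window (nT - 1 of them).  In
        strict mode each is ``[IT - k, IT + k]`` (length 2k + 1).
    toi_subsets : list of ndarray
        Per-TOI interior-changepoint subsets (tau_1 .. tau_nT).
    fallback : list of bool
        True where the intervention time fell back to the experimenter's
        marker boundary because no changepoint was detected in that TOI.
    """

    it_times: np.ndarray
    k: int
    otoi: list[tuple[int, int]]
    ott: list[tuple[int, int]]
    toi_subsets: list[np.ndarray]
    toi_labels: list[str] = field(default_factory=list)
    fallback: list[bool] = field(default_factory=list)
    clamped: bool = False

    @property
    def n_toi(self) -> int:
        return len(self.otoi)

    def covers_exactly(self, ni: int) -> bool:
        """True iff otoi and ott ranges partition ``[1, ni]`` with no gap/overlap."""
        ranges = sorted(list(self.otoi) + list(self.ott))
        pos = 1
        for a, b in ranges:
            if a != pos or b < a:
                return False
            pos = b + 1
        return pos == ni + 1

    def transition_mask(self, ni: int) -> np.ndarray:
        """Boolean mask (0-based, length ni), True on transition-window samples."""
        mask = np.zeros(ni, dtype=bool)
        for a, b in self.ott:
            mask[a - 1 : b] = True
        return mask

    def toi_slice(self, j: int) -> slice:
        """0-based slice of optimal TOI ``j`` (1-based TOI index)."""
        a, b = self.otoi[j - 1]
        return slice(a - 1, b)

    def to_json(self) -> dict:
        return {
            "k": int(self.k),
            "IT": [None if np.isnan(v) else int(v) for v in self.it_times],
            "otoi": [[int(a), int(b)] for a, b in self.otoi],
            "ott": [[int(a), int(b)] for a, b in self.ott],
            "toi_labels": list(self.toi_labels),
            "fallback": list(map(bool, self.fallback)),
            "clamped": bool(self.clamped),
        }


def split_by_marker(cpts: ChangepointSet, record: PerfusionRecord) -> list[np.ndarray]:
    """Split interior changepoints into per-TOI subsets.

    A changepoint at position ``p`` (boundary after sample ``p``) is assigned
    to the TOI whose marker labels sample ``p``; sentinels are excluded.
    Empty subsets are allowed.
    """
    labels = record.marker_labels()
    by_label: dict[str, list[int]] = {lab: [] for lab in labels}
    markers = record.markers
    for p in cpts.interior:
        by_label[str(markers[int(p) - 1])].append(int(p))
    return [np.array(sorted(by_label[lab]), dtype=int) for lab in labels]


def intervention_times(
    subsets: list[np.ndarray], record: PerfusionRecord
) -> tuple[np.ndarray, list[bool]]:
    """Intervention time per TOI: the earliest changepoint in its subset.

    For TOIs j >= 2 with an empty subset, the first sample index of the
    experimenter's marker block is used instead (logged as a warning) — the
    marker is the only information left when no changepoint was detected.
    An empty basal subset leaves IT_1 undefined (NaN); it is unused anyway.
    """
    blocks = record.marker_blocks()
    n_toi = len(subsets)
    it = np.full(n_toi, np.nan)
    fallback = [False] * n_toi
    for j in range(n_toi):
        if subsets[j].size:
            it[j] = float(subsets[j].min())
        elif j >= 1:
            it[j] = float(blocks[j][1])
            fallback[j] = True
            logger.warning(
                "subject %s: no changepoint in TOI %d (%s); falling back to "
                "marker-block start %d",
                record.subject_index,
                j + 1,
                blocks[j][0],
                blocks[j][1],
            )
    return it, fallback


def algorithm1(
    cpts: ChangepointSet, record: PerfusionRecord, clamp: bool = False
) -> SegmentationResult:
    """Build optimal TOIs and transition windows for one subject.

    The transition half-width ``k`` is the total number of interior
    changepoints outside the basal subset.  Each transition window is the
    symmetric range ``[IT_j - k, IT_j + k]`` around the intervention time of
    TOI ``j`` (j >= 2); optimal TOIs are the complementary ranges, so the
    result partitions ``[1, ni]`` exactly.

    Parameters
    ----------
    clamp : bool
        If False (default), windows that would overlap a neighbouring TOI's
        territory raise :class:`InadmissibleWindowError`.  If True, each
        window is truncated at the midpoints between adjacent intervention
        times (and at the record ends), trading window symmetry for an
        always-admissible cover.
    """
    labels = record.marker_labels()
    n_toi = len(labels)
    if n_toi < 2:
        raise ValueError(f"need at least 2 TOIs, got {n_toi}")
    ni = record.n
    subsets = split_by_marker(cpts, record)
    it, fallback = intervention_times(subsets, record)
    k = int(sum(s.size for s in subsets[1:]))

    # transition window j (between TOI j and j+1) is centred on IT_{j+1}
    centres = [int(it[j]) for j in range(1, n_toi)]
    if clamp:
        lo_lim = [2] + [ (centres[j - 1] + centres[j]) // 2 + 1 for j in range(1, n_toi - 1) ]
        hi_lim = [ (centres[j] + centres[j + 1]) // 2 - 1 for j in range(n_toi - 2) ] + [ni - 1]
        ott = [
            (max(c - k, lo_lim[j]), min(c + k, hi_lim[j]))
            for j, c in enumerate(centres)
        ]
        clamped = any(
            w != (c - k, c + k) for w, c in zip(ott, centres)
        )
    else:
        ott = [(c - k, c + k) for c in centres]
        clamped = False
        # admissibility: every optimal TOI must be a nonempty in-bounds range
        if ott[0][0] <= 1:
            raise InadmissibleWindowError(
                f"subject {record.subject_index}: transition window 1 "
                f"[{ott[0][0]}, {ott[0][1]}] leaves no basal TOI (IT_2 - k <= 1); "
                "reduce k by raising the changepoint penalty"
            )
        if ott[-1][1] >= ni:
            raise InadmissibleWindowError(
                f"subject {record.subject_index}: transition window {n_toi - 1} "
                f"[{ott[-1][0]}, {ott[-1][1]}] leaves no final TOI (IT_{n_toi} + k >= ni); "
                "reduce k by raising the changepoint penalty"
            )
        for j in range(len(ott) - 1):
            if ott[j][1] + 1 > ott[j + 1][0] - 1:
                raise InadmissibleWindowError(
                    f"subject {record.subject_index}: optimal TOI {j + 2} between "
                    f"transition windows {j + 1} and {j + 2} is empty; reduce k by "
                    "raising the changepoint penalty"
                )

    otoi: list[tuple[int, int]] = []
    otoi.append((1, ott[0][0] - 1))
    for j in range(1, n_toi - 1):
        otoi.append((ott[j - 1][1] + 1, ott[j][0] - 1))
    otoi.append((ott[-1][1] + 1, ni))
    for j, (a, b) in enumerate(otoi):
        if a > b:
            raise InadmissibleWindowError(
                f"subject {record.subject_index}: optimal TOI {j + 1} is empty "
                f"([{a}, {b}]); reduce k by raising the changepoint penalty"
            )

    result = SegmentationResult(
        it_times=it,
        k=k,
        otoi=otoi,
        ott=ott,
        toi_subsets=subsets,
        toi_labels=labels,
        fallback=fallback,
        clamped=clamped,
    )
    assert result.covers_exactly(ni), "internal error: segmentation does not cover [1, ni]"
    return result
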