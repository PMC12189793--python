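"""Synthetic perfusion cohorts with the structure the analysis assumes.

The generator emulates a thermal-stimulus perfusion experiment: each subject
has three marker blocks (basal, cold, warm), a subject-specific baseline
level, segment-level mean shifts in responders (controls drop under cold and
recover under warm; the experimental group is flat), stationary AR(1) noise,
and a large transient artifact burst centred on each marker boundary — the
instrumentation noise the transition windows are meant to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, PerfusionRecord

__all__ = ["SimulationDesign", "simulate_subject", "simulate_cohort"]

_GROUP_SEX = [
    ("control", "female"),
    ("control", "male"),
    ("experimental", "female"),
    ("experimental", "male"),
]


@dataclass
class SimulationDesign:
    """Cohort design: sizes, effects and noise of the emulated experiment.

    Defaults mirror the emulated study: 33 subjects (16 control + 17
    experimental, both sexes), three TOIs, controls responding to cold with
    a perfusion drop (and near-recovery under warm) while the experimental
    group is unresponsive, AR(1) noise and square artifact bursts at the two
    intervention boundaries.

    Parameters
    ----------
    n_per_group : dict
        Subject counts keyed by ``(group, sex)``.
    toi_lengths : tuple of int
        Samples per marker block (basal, cold, warm).
    baseline_mean : float
        Population basal perfusion level (arbitrary perfusion units).
    subject_sd : float
        Between-subject SD of the baseline level (intrinsic individual
        variability; removed by the reference-state normalization).
    effects : dict
        Per-group tuple of per-TOI mean offsets relative to baseline.
    noise_sd : float
        Stationary SD of the AR(1) noise.
    ar_coef : float
        AR(1) coefficient in [0, 1).
    artifact_amp : float
        Amplitude of the transient burst at each intervention boundary.
    artifact_halfwidth : int
        Burst half-width in samples (< min(toi_lengths)/2).
    artifact_shape : {"square", "triangular", "exp_decay"}
        Burst profile.
    seed : int
        Root seed; per-subject seeds are derived deterministically.
    """

    n_per_group: dict = field(
        default_factory=lambda: {
            ("control", "female"): 8,
            ("control", "male"): 8,
            ("experimental", "female"): 9,
            ("experimental", "male"): 8,
        }
    )
    toi_lengths: tuple = (300, 300, 300)
    toi_labels: tuple = ("basal", "cold", "warm")
    baseline_mean: float = 250.0
    subject_sd: float = 15.0
    effects: dict = field(
        default_factory=lambda: {
            "control": (0.0, -40.0, -5.0),
            "experimental": (0.0, 5.0, 0.0),
        }
    )
    noise_sd: float = 10.0
    ar_coef: float = 0.6
    artifact_amp: float = 80.0
    artifact_halfwidth: int = 5
    artifact_shape: str = "square"
    seed: int = 0

    def validate(self) -> None:
        if len(self.toi_lengths) != len(self.toi_labels):
            raise ValueError("toi_lengths and toi_labels must have equal length")
        if any(L < 9 for L in self.toi_lengths):
            raise ValueError("every TOI must have at least 9 samples (3 * min_len)")
        if not 0.0 <= abs(self.ar_coef) < 1.0:
            raise ValueError("|ar_coef| must be < 1")
        if self.artifact_halfwidth >= min(self.toi_lengths) / 2:
            raise ValueError("artifact_halfwidth must be < min(toi_lengths)/2")
        if self.artifact_shape not in ("square", "triangular", "exp_decay"):
            raise ValueError(f"unknown artifact shape {self.artifact_shape!r}")
        for g in ("control", "experimental"):
            if g not in self.effects or len(self.effects[g]) != len(self.toi_lengths):
                raise ValueError(f"effects[{g!r}] must give one offset per TOI")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group.values()))

    def mean_profile(self, group: str, baseline: float) -> np.ndarray:
        """Piecewise-constant mean profile for one subject."""
        parts = [
            np.full(L, baseline + d)
            for L, d in zip(self.toi_lengths, self.effects[group])
        ]
        return np.concatenate(parts)

    def boundaries(self) -> list[int]:
        """1-based index of the last sample of each non-final marker block."""
        return list(np.cumsum(self.toi_lengths)[:-1].astype(int))


def _artifact_profile(design: SimulationDesign, n: int) -> np.ndarray:
    """Deterministic artifact bursts centred on each marker boundary."""
    burst = np.zeros(n)
    h = design.artifact_halfwidth
    amp = design.artifact_amp
    for b in design.boundaries():
        centre = b + 1  # first sample of the new state, where the stimulus lands
        lo, hi = centre - h, centre + h
        idx = np.arange(max(lo, 1), min(hi, n) + 1)
        if design.artifact_shape == "square":
            shape = np.ones_like(idx, dtype=float)
        elif design.artifact_shape == "triangular":
            shape = 1.0 - np.abs(idx - centre) / (h + 1.0)
        else:  # exp_decay
            shape = np.exp(-np.abs(idx - centre) / max(h / 2.0, 1.0))
        burst[idx - 1] += amp * shape
    return burst


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    e = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def simulate_subject(
    design: SimulationDesign,
    group: str,
    sex: str,
    subject_seed: int,
    subject_index: int = 1,
    internal_code: str | None = None,
) -> PerfusionRecord:
    """Generate one subject's recording; reproducible given the seed."""
    design.validate()
    rng = np.random.default_rng(subject_seed)
    n = int(sum(design.toi_lengths))
    baseline = design.baseline_mean + rng.normal(0.0, design.subject_sd)
    values = (
        design.mean_profile(group, baseline)
        + _ar1(rng, n, design.noise_sd, design.ar_coef)
        + _artifact_profile(design, n)
    )
    markers = np.concatenate(
        [
            np.full(L, lab, dtype=object)
            for L, lab in zip(design.toi_lengths, design.toi_labels)
        ]
    )
    if internal_code is None:
        prefix = "WT" if group == "control" else "L"
        internal_code = f"{prefix}{10 + subject_index}D{1 + subject_index % 5}"
    return PerfusionRecord(
        subject_index=subject_index,
        internal_code=internal_code,
        group=group,
        sex=sex,
        times=np.arange(1.0, n + 1.0),
        markers=markers,
        values=values,
    )


def simulate_cohort(design: SimulationDesign) -> Cohort:
    """Generate the full cohort with distinct derived per-subject seeds."""
    design.validate()
    root = np.random.default_rng(design.seed)
    seeds = root.integers(0, 2**31 - 1, size=design.n_subjects)
    records = []
    idx = 0
    for group, sex in _GROUP_SEX:
        for _ in range(int(design.n_per_group.get((group, sex), 0))):
            idx += 1
            prefix = "WT" if group == "control" else "L"
            code = f"{prefix}{6 + idx // 3}D{1 + idx % 5}"
            records.append(
                simulate_subject(
                    design,
                    group,
                    sex,
                    subject_seed=int(seeds[idx - 1]),
                    subject_index=idx,
                    internal_code=code,
                )
            )
    return Cohort(records=records, toi_labels=list(design.toi_labels))
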