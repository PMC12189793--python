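"""Penalized optimal changepoint detection with a piecewise-linear segment cost.

The segmentation objective is

    min over partitions  sum_j C(y[a_j..b_j]) + beta * m

where ``C`` is the residual sum of squares of the ordinary-least-squares line
fitted to the segment (the piecewise-linear approximation cost), ``m`` is the
number of interior changepoints and ``beta >= 0`` the per-changepoint penalty.
``pelt_segment`` solves this exactly by the PELT dynamic program (pruned exact
linear time); ``exhaustive_segment`` solves the same objective by enumerating
every admissible partition and serves as the independent oracle in tests.

Conventions: sample indices are 1-based; a changepoint at position ``p`` is a
boundary *after* sample ``p``, so segments are closed index ranges
``[p_prev+1, p]``.  The position vector carries sentinels ``0`` and ``n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChangepointSet",
    "PenaltyConfig",
    "linear_segment_cost",
    "pelt_segment",
    "exhaustive_segment",
    "default_penalty",
]

_EXHAUSTIVE_GUARD = 25


@dataclass
class PenaltyConfig:
    """Penalty and segment constraints for the penalized segmentation.

    Parameters
    ----------
    beta : float
        Penalty added per interior changepoint (>= 0).
    min_len : int
        Minimum segment length (>= 2).  Default 3: a 2-point segment has zero
        line-fit residual and would be degenerately favoured.
    sigma_hat : float
        Noise-scale estimate that produced ``beta`` (informational).
    cost : {"linear", "constant"}
        Per-segment cost family: RSS of the OLS line, or RSS about the mean.
    """

    beta: float
    min_len: int = 3
    sigma_hat: float = float("nan")
    cost: str = "linear"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if self.cost not in ("linear", "constant"):
            raise ValueError("cost must be 'linear' or 'constant'")


@dataclass
class ChangepointSet:
    """Changepoint positions with sentinels, and the penalized objective value."""

    positions: np.ndarray  # strictly increasing, positions[0] == 0, positions[-1] == n
    total_cost: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        if self.positions[0] != 0:
            raise ValueError("positions must start with the 0 sentinel")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.positions[-1])

    @property
    def interior(self) -> np.ndarray:
        return self.positions[1:-1]

    @property
    def interior_count(self) -> int:
        return len(self.positions) - 2

    def segments(self) -> list[tuple[int, int]]:
        """Closed 1-based index ranges ``[p_prev+1, p]`` of each segment."""
        p = self.positions
        return [(int(p[i]) + 1, int(p[i + 1])) for i in range(len(p) - 1)]

    def to_json(self) -> dict:
        return {"positions": self.positions.tolist(), "cost": float(self.total_cost)}


class _SegmentCost:
    """O(1) segment cost via prefix sums over (x, y) with x = 1-based sample index."""

    def __init__(self, values: np.ndarray, cost: str = "linear") -> None:
        y = np.asarray(values, dtype=float)
        n = len(y)
        x = np.arange(1, n + 1, dtype=float)
        z = np.zeros(1)
        self.cost_kind = cost
        self.Sy = np.concatenate([z, np.cumsum(y)])
        self.Syy = np.concatenate([z, np.cumsum(y * y)])
        self.Sx = np.concatenate([z, np.cumsum(x)])
        self.Sxx = np.concatenate([z, np.cumsum(x * x)])
        self.Sxy = np.concatenate([z, np.cumsum(x * y)])
        self.n = n

    def __call__(self, a, b):
        """RSS on closed range [a, b]; ``a`` may be a vector, ``b`` a scalar."""
        a = np.asarray(a)
        m = b - a + 1
        sy = self.Sy[b] - self.Sy[a - 1]
        syy = self.Syy[b] - self.Syy[a - 1]
        cyy = syy - sy * sy / m
        if self.cost_kind == "constant":
            return np.maximum(cyy, 0.0)
        sx = self.Sx[b] - self.Sx[a - 1]
        sxx = self.Sxx[b] - self.Sxx[a - 1]
        sxy = self.Sxy[b] - self.Sxy[a - 1]
        cxx = sxx - sx * sx / m
        cxy = sxy - sx * sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            rss = cyy - np.where(cxx > 0, cxy * cxy / np.where(cxx > 0, cxx, 1.0), 0.0)
        return np.maximum(rss, 0.0)


def linear_segment_cost(values, a: int, b: int) -> float:
    """RSS of the least-squares line on samples ``a..b`` (1-based, closed).

    Returns 0 iff the samples are exactly collinear (any 2-point segment is).
    """
    if b - a + 1 < 2:
        raise ValueError(f"segment [{a}, {b}] is shorter than 2 samples")
    values = np.asarray(values, dtype=float)
    if not (1 <= a <= b <= len(values)):
        raise ValueError(f"segment [{a}, {b}] out of bounds for n={len(values)}")
    return float(_SegmentCost(values)(a, b))


def default_penalty(
    values, min_len: int = 3, cost: str = "linear", ar_aware: bool = True
) -> PenaltyConfig:
    """BIC-flavoured default penalty with a robust noise-scale estimate.

    The noise scale is estimated from first differences, which cancel slowly
    varying trend: the Gaussian-consistent robust SD of the differences is
    ``1.4826 * MAD(diff(y))``, and for white noise the sample SD equals
    ``sqrt(2)`` times the noise SD, giving ``sigma_hat = 1.4826 * MAD / sqrt(2)``.

    Perfusion noise is autocorrelated, which makes white-noise penalties far
    too permissive (slow noise wander mimics mean shifts).  With
    ``ar_aware=True`` an AR(1) coefficient is estimated from the lag-1
    autocorrelation of the differences (``rho_d = -(1 - phi)/2`` for AR(1))
    and ``sigma_hat`` becomes the long-run scale
    ``s * sqrt((1 + phi)/(1 - phi))``, which reduces to the white-noise value
    at ``phi = 0``.  The penalty is ``beta = 2 * sigma_hat**2 * log(n)``.
    Both are freely overridable through :class:`PenaltyConfig`.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 samples to estimate a noise scale")
    d = np.diff(values)
    mad = float(np.median(np.abs(d - np.median(d))))
    sd_d = 1.4826 * mad  # robust SD of the differenced series
    phi = 0.0
    if ar_aware and sd_d > 0 and len(d) >= 3:
        # artifact bursts put huge spikes in d that crush |rho| toward zero
        # (and hence inflate phi); estimate the autocorrelation on the
        # spike-trimmed differences only
        keep = np.abs(d - np.median(d)) <= 5.0 * sd_d
        pair = keep[1:] & keep[:-1]
        if pair.sum() >= 3:
            dk = d - np.median(d[keep])
            num = float(np.sum(dk[1:][pair] * dk[:-1][pair]))
            denom = float(np.sum(dk[1:][pair] ** 2 + dk[:-1][pair] ** 2) / 2.0)
            if denom > 0:
                rho_d = num / denom
                phi = min(max(1.0 + 2.0 * rho_d, 0.0), 0.95)
    # stationary SD from Var(diff) = 2 s^2 (1 - phi), then long-run inflation
    sigma_hat = sd_d / np.sqrt(2.0 * (1.0 - phi)) * np.sqrt((1.0 + phi) / (1.0 - phi))
    if sigma_hat == 0.0:
        warnings.warn(
            "degenerate noise estimate (sigma_hat = 0); applying penalty floor",
            RuntimeWarning,
            stacklevel=2,
        )
        scale = float(np.ptp(values))
        beta = 1e-8 * max(scale * scale, 1.0)
    else:
        beta = 2.0 * sigma_hat * sigma_hat * np.log(n)
    return PenaltyConfig(beta=float(beta), min_len=min_len, sigma_hat=sigma_hat, cost=cost)


def pelt_segment(values, cfg: PenaltyConfig) -> ChangepointSet:
    """Exact penalized segmentation by the PELT dynamic program.

    Minimizes ``sum of segment costs + beta * (number of changepoints)``.
    Pruning never discards the optimum because the RSS cost is subadditive
    under splitting.  Ties are broken toward the fewest changepoints, then
    the leftmost last changepoint, so results are deterministic.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    L = cfg.min_len
    if n < 2 * L:
        raise ValueError(f"input length {n} is shorter than 2*min_len = {2 * L}")
    costf = _SegmentCost(y, cfg.cost)
    beta = float(cfg.beta)

    F = np.full(n + 1, np.inf)
    F[0] = -beta
    nseg = np.zeros(n + 1, dtype=int)  # interior changepoints used by F[t]
    prev = np.full(n + 1, -1, dtype=int)
    cand = [0]  # candidate last-changepoint positions
    pruned_at: dict[int, int] = {}  # s -> time the prune condition first held

    for t in range(L, n + 1):
        # a candidate pruned at t_p is provably non-optimal only for ends
        # >= t_p + min_len (the path through t_p needs a full segment after it)
        cand = [s for s in cand if s not in pruned_at or t < pruned_at[s] + L]
        adm = np.array([s for s in cand if s <= t - L], dtype=int)
        if adm.size == 0:
            cand.append(t)
            continue
        vals = F[adm] + costf(adm + 1, t) + beta
        vmin = vals.min()
        tie = np.flatnonzero(vals == vmin)
        # fewest changepoints first, then leftmost position
        m_new = nseg[adm[tie]] + (adm[tie] > 0)
        order = np.lexsort((adm[tie], m_new))
        best = tie[order[0]]
        s = int(adm[best])
        F[t] = vmin
        nseg[t] = nseg[s] + (1 if s > 0 else 0)
        prev[t] = s
        for sp, v in zip(adm, vals):
            if v - beta > F[t] and sp not in pruned_at:
                pruned_at[int(sp)] = t
        cand.append(t)

    # backtrack
    pos = [n]
    t = n
    while prev[t] > 0:
        t = int(prev[t])
        pos.append(t)
    pos.append(0)
    return ChangepointSet(positions=np.array(pos[::-1]), total_cost=float(F[n]))


def exhaustive_segment(values, cfg: PenaltyConfig) -> ChangepointSet:
    """Global optimum by enumeration of all admissible partitions (test oracle).

    Refuses inputs longer than 25 samples; the search is exponential and is
    meant only to certify :func:`pelt_segment` on tiny signals.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n > _EXHAUSTIVE_GUARD:
        raise ValueError(f"exhaustive search refused for n={n} > {_EXHAUSTIVE_GUARD}")
    L = cfg.min_len
    if n < 2 * L:
        # a single segment is the only admissible partition if n >= L
        if n < L:
            raise ValueError(f"input length {n} is shorter than min_len={L}")
    costf = _SegmentCost(y, cfg.cost)
    beta = float(cfg.beta)

    best_cost = np.inf
    best_parts: tuple[int, ...] | None = None

    def recurse(start: int, acc_cost: float, parts: list[int]) -> None:
        nonlocal best_cost, best_parts
        for end in range(start + L, n + 1):  # segment [start+1, end], length >= min_len
            seg_cost = float(costf(start + 1, end))
            total = acc_cost + seg_cost + beta
            if end == n:
                final = total - 0.0
                cand_parts = tuple(parts)
                if final < best_cost or (
                    final == best_cost
                    and best_parts is not None
                    and (len(cand_parts), cand_parts) < (len(best_parts), best_parts)
                ):
                    best_cost = final
                    best_parts = cand_parts
            elif n - end >= L:
                parts.append(end)
                recurse(end, total, parts)
                parts.pop()

    recurse(0, -beta, [])  # -beta cancels the first segment's +beta
    assert best_parts is not None
    pos = np.array([0, *best_parts, n])
    return ChangepointSet(positions=pos, total_cost=float(best_cost))
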