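"""Rank-based comparative statistics for normalized perfusion responses.

Each subject contributes one sample (its aligned difference series, e.g.
cold-to-basal); the Kruskal-Wallis omnibus test asks whether the samples
share one distribution, and Dunn's pairwise rank test with a family-wise
correction localizes which subjects (or interest groups) differ.  Everything
here operates on ranks of the pooled data, so all results are invariant
under strictly monotone transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonReport",
    "kruskal_wallis",
    "pairwise_multicompare",
    "dunn_pvalues",
    "difference_counts",
    "box_stats",
    "compare_subjects",
    "compare_groups",
]


def kruskal_wallis(samples: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value.

    Degenerate input (every value identical across all groups) returns
    ``(0.0, 1.0)`` instead of raising.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def dunn_pvalues(samples: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Dunn's pairwise z-statistics and two-sided p-values on pooled ranks.

    The pairwise statistic compares mean ranks of groups i and j on the
    pooled ranking, with the usual tie correction:

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    where ``T = sum(t^3 - t)`` over tie groups of size t.  Returns the
    (z, p) matrices (symmetric |z|, p; diagonal 0 and 1).
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    g = len(arrays)
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(g)]
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    z = np.zeros((g, g))
    p = np.ones((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            zij = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            z[i, j] = z[j, i] = abs(zij)
            pij = 2.0 * sps.norm.sf(abs(zij))
            p[i, j] = p[j, i] = min(pij, 1.0)
    return z, p


def _conover_pvalues(samples: list[np.ndarray]) -> np.ndarray:
    """Conover-Iman pairwise t-statistics on pooled ranks (raw p-values)."""
    arrays = [np.asarray(s, dtype=float) for s in samples]
    g = len(arrays)
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array([ranks[bounds[i] : bounds[i + 1]].mean() for i in range(g)])
    h, _ = kruskal_wallis(arrays)
    s2 = (float(np.sum(ranks**2)) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    df = n - g
    factor = s2 * (n - 1 - h) / df
    p = np.ones((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            se = np.sqrt(factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
            t = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            pij = 2.0 * sps.t.sf(abs(t), df)
            p[i, j] = p[j, i] = min(pij, 1.0)
    return p


_POSTHOC_METHODS = {
    "dunn-holm": ("dunn", "holm"),
    "dunn-bonferroni": ("dunn", "bonferroni"),
    "conover-holm": ("conover", "holm"),
}


def pairwise_multicompare(
    samples: list[np.ndarray],
    alpha: float = 0.05,
    method: str = "dunn-holm",
) -> np.ndarray:
    """Symmetric boolean significance matrix from pairwise rank comparisons.

    ``method`` selects the pairwise statistic and family-wise correction:
    ``"dunn-holm"`` (default), ``"dunn-bonferroni"`` or ``"conover-holm"``.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if method not in _POSTHOC_METHODS:
        raise ValueError(f"unknown post-hoc method {method!r}")
    stat, correction = _POSTHOC_METHODS[method]
    if stat == "dunn":
        _, pmat = dunn_pvalues(samples)
    else:
        pmat = _conover_pvalues(samples)
    g = pmat.shape[0]
    iu = np.triu_indices(g, k=1)
    raw = pmat[iu]
    reject, _, _, _ = multipletests(raw, alpha=alpha, method=correction)
    sig = np.zeros((g, g), dtype=bool)
    sig[iu] = reject
    sig |= sig.T
    return sig


def difference_counts(
    sig_matrix: np.ndarray,
    group_labels: list[str],
    group_names: tuple[str, str] = ("WT", "LNAME"),
) -> list[dict]:
    """Per-subject counts of significant pairwise differences, split by group.

    ``group_labels[i]`` is ``"control"`` or ``"experimental"`` for subject i.
    Each entry reports ``total``, ``vs_control``, ``vs_experimental`` and a
    formatted string like ``"32: 15 WT and 17 LNAME"``.
    """
    sig = np.asarray(sig_matrix, dtype=bool)
    g = sig.shape[0]
    if len(group_labels) != g:
        raise ValueError("group_labels must cover all subjects")
    is_control = np.array([lab == "control" for lab in group_labels])
    out = []
    for i in range(g):
        row = sig[i].copy()
        row[i] = False
        vs_c = int(np.sum(row & is_control))
        vs_e = int(np.sum(row & ~is_control))
        out.append(
            {
                "subject": i + 1,
                "total": vs_c + vs_e,
                "vs_control": vs_c,
                "vs_experimental": vs_e,
                "formatted": f"{vs_c + vs_e}: {vs_c} {group_names[0]} and {vs_e} {group_names[1]}",
            }
        )
    return out


def box_stats(series) -> dict:
    """Tukey box-and-whisker summary: quartiles, 1.5*IQR whiskers, outliers."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be nonempty")
    # type-6 (Weibull) quantiles: Q1 of 1..7 is 2, matching the usual
    # box-plot convention of interpolating at (n+1)p
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="weibull")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = np.sort(x[(x < lo_fence) | (x > hi_fence)])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": outliers.tolist(),
    }


@dataclass
class ComparisonReport:
    """Omnibus + post-hoc comparison across subjects (or groups)."""

    kw_stat: float
    kw_p: float
    sig_matrix: np.ndarray
    counts: list[dict]
    box: list[dict]
    alpha: float = 0.05
    method: str = "dunn-holm"
    labels: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "kw_stat": self.kw_stat,
            "kw_p": self.kw_p,
            "alpha": self.alpha,
            "posthoc_method": self.method,
            "sig_matrix": self.sig_matrix.astype(int).tolist(),
            "counts": self.counts,
            "box": self.box,
            "labels": self.labels,
        }


def compare_subjects(
    samples: list[np.ndarray],
    group_labels: list[str],
    alpha: float = 0.05,
    method: str = "dunn-holm",
    labels: list[str] | None = None,
) -> ComparisonReport:
    """Individual-level comparison: one sample per subject.

    Runs the Kruskal-Wallis omnibus test across subjects, Dunn's pairwise
    post-hoc with family-wise correction, per-subject difference counts and
    box summaries.
    """
    h, p = kruskal_wallis(samples)
    sig = pairwise_multicompare(samples, alpha=alpha, method=method)
    counts = difference_counts(sig, group_labels)
    box = [box_stats(s) for s in samples]
    return ComparisonReport(
        kw_stat=h,
        kw_p=p,
        sig_matrix=sig,
        counts=counts,
        box=box,
        alpha=alpha,
        method=method,
        labels=labels or [str(i + 1) for i in range(len(samples))],
    )


def compare_groups(
    samples: list[np.ndarray],
    group_keys: list[str],
    pooling: str = "pool",
    alpha: float = 0.05,
    method: str = "dunn-holm",
) -> ComparisonReport:
    """Group-level comparison of per-subject samples.

    ``group_keys[i]`` names subject i's interest group (e.g. "WT female").
    With ``pooling="pool"`` (default) each group's sample is the
    concatenation of its subjects' samples; with ``"subject-median"`` each
    subject contributes a single summary value (its median), which keeps the
    group test calibrated when within-subject samples are autocorrelated.
    """
    order: list[str] = []
    for kkey in group_keys:
        if kkey not in order:
            order.append(kkey)
    if pooling == "pool":
        grouped = [
            np.concatenate([np.asarray(s) for s, kk in zip(samples, group_keys) if kk == gk])
            for gk in order
        ]
    elif pooling == "subject-median":
        grouped = [
            np.array([float(np.median(s)) for s, kk in zip(samples, group_keys) if kk == gk])
            for gk in order
        ]
    else:
        raise ValueError("pooling must be 'pool' or 'subject-median'")
    h, p = kruskal_wallis(grouped)
    sig = pairwise_multicompare(grouped, alpha=alpha, method=method)
    counts = difference_counts(sig, ["control"] * len(order))
    box = [box_stats(gs) for gs in grouped]
    return ComparisonReport(
        kw_stat=h, kw_p=p, sig_matrix=sig, counts=counts, box=box,
        alpha=alpha, method=method, labels=order,
    )
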