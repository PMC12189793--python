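"""Basic figures: segmented normalized traces and box-and-whisker panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_TOI_COLORS = ["0.85", "#cce6ff", "#ffd6cc", "#e6ffcc", "#f0ccff"]


def plot_subject(analysis, path) -> None:
    """One subject's z and z_pla with shaded optimal TOIs and transition lines."""
    rec, seg, norm = analysis.record, analysis.seg, analysis.norm
    fig, ax = plt.subplots(figsize=(9, 3.2))
    t = np.arange(1, rec.n + 1)
    for j, (a, b) in enumerate(seg.otoi):
        ax.axvspan(a, b, color=_TOI_COLORS[j % len(_TOI_COLORS)], zorder=0)
    for a, b in seg.ott:
        ax.axvline(a, color="k", ls="--", lw=0.8)
        ax.axvline(b, color="k", ls="--", lw=0.8)
    ax.plot(t, norm.z, lw=0.6, color="C0", label="z")
    ax.plot(t, norm.z_pla, lw=1.4, color="C3", label="z (PLA)")
    ax.set_xlabel("sample")
    ax.set_ylabel("normalized perfusion")
    ax.set_title(
        f"subject {rec.subject_index} ({rec.internal_code}, {rec.group} {rec.sex}), "
        f"k={seg.k}"
    )
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_boxes(report, path) -> None:
    """Box-and-whisker panel from precomputed five-number summaries."""
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(report.box)), 3.5))
    boxes = [
        {
            "med": b["median"],
            "q1": b["q1"],
            "q3": b["q3"],
            "whislo": b["whisker_low"],
            "whishi": b["whisker_high"],
            "fliers": b["outliers"],
            "label": lab,
        }
        for b, lab in zip(report.box, report.labels)
    ]
    ax.bxp(boxes, showfliers=True, flierprops={"markersize": 2})
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    ax.set_ylabel("value")
    ax.set_title(f"KW H={report.kw_stat:.2f}, p={report.kw_p:.3g} ({report.method})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
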