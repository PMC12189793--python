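"""End-to-end orchestration: ingest/simulate, segment, normalize, compare.

``run_pipeline`` executes the whole flow for a cohort — changepoint
segmentation, transition windowing, PLA fitting, reference-state
normalization, difference series, and individual- plus group-level rank
statistics — and (optionally) writes a report bundle of JSON/TSV tables and
figures.  Each stage error is re-raised with the offending subject named.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .changepoint import PenaltyConfig, default_penalty, pelt_segment
from .cohort import Cohort, PerfusionRecord
from .cohort_io import LayoutConfig, read_cohort_table, read_workbook
from .normalization import NormalizedSignal, PLAModel, fit_pla, toi_difference, znormalize
from .simulate import SimulationDesign, simulate_cohort
from .stats import ComparisonReport, compare_groups, compare_subjects
from .transitions import SegmentationResult, algorithm1

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SubjectAnalysis", "PipelineResult", "analyze_subject", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one analysis run.

    Exactly one of ``input_path`` (workbook or long-format table) or
    ``design`` (synthetic cohort) must be set.
    """

    input_path: str | None = None
    design: SimulationDesign | None = None
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    penalty: PenaltyConfig | None = None  # None -> per-subject automatic penalty
    ref_toi: int = 1
    alpha: float = 0.05
    posthoc: str = "dunn-holm"
    group_pooling: str = "pool"
    clamp: bool = False
    outdir: str | None = None
    seed: int = 0
    make_plots: bool = False

    def validate(self) -> None:
        if (self.input_path is None) == (self.design is None):
            raise ValueError("exactly one of input_path / design must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = raw.pop("design", None)
        if design is not None:
            if "n_per_group" in design:
                design["n_per_group"] = {
                    tuple(k.split("/")): v for k, v in design["n_per_group"].items()
                }
            if "toi_lengths" in design:
                design["toi_lengths"] = tuple(design["toi_lengths"])
            if "effects" in design:
                design["effects"] = {g: tuple(v) for g, v in design["effects"].items()}
            design = SimulationDesign(**design)
        penalty = raw.pop("penalty", None)
        if penalty is not None:
            penalty = PenaltyConfig(**penalty)
        return cls(design=design, penalty=penalty, **raw)


@dataclass
class SubjectAnalysis:
    """Everything computed for one subject."""

    record: PerfusionRecord
    penalty: PenaltyConfig
    seg: SegmentationResult
    pla: PLAModel
    norm: NormalizedSignal
    diffs: dict  # (k, l, source) -> DifferencePair


@dataclass
class PipelineResult:
    cohort: Cohort
    subjects: list[SubjectAnalysis]
    reports: dict  # name -> ComparisonReport

    def report_json(self) -> dict:
        return {
            "n_subjects": self.cohort.n_subjects,
            "toi_labels": self.cohort.toi_labels,
            "subjects": [
                {
                    "subject": s.record.subject_index,
                    "code": s.record.internal_code,
                    "group": s.record.group,
                    "sex": s.record.sex,
                    "penalty_beta": s.penalty.beta,
                    **s.seg.to_json(),
                }
                for s in self.subjects
            ],
            "comparisons": {name: rep.to_json() for name, rep in self.reports.items()},
        }


def analyze_subject(
    record: PerfusionRecord,
    penalty: PenaltyConfig | None = None,
    ref_toi: int = 1,
    clamp: bool = False,
) -> SubjectAnalysis:
    """Segment, window, fit and normalize one subject's recording."""
    pen = penalty or default_penalty(record.values)
    cpts = pelt_segment(record.values, pen)
    seg = algorithm1(cpts, record, clamp=clamp)
    pla = fit_pla(record.values, cpts)
    norm = znormalize(record, pla, seg, ref=ref_toi)
    diffs = {}
    n_toi = seg.n_toi
    for source in ("z", "z_pla"):
        for kk in range(2, n_toi + 1):
            diffs[(kk, kk - 1, source)] = toi_difference(norm, seg, kk, kk - 1, source=source)
    logger.info(
        "subject %s (%s): k=%d, IT=%s, beta=%.4g",
        record.subject_index,
        record.internal_code,
        seg.k,
        [None if np.isnan(v) else int(v) for v in seg.it_times],
        pen.beta,
    )
    logger.debug("subject %s: changepoints %s", record.subject_index, cpts.positions.tolist())
    return SubjectAnalysis(record=record, penalty=pen, seg=seg, pla=pla, norm=norm, diffs=diffs)


def _load_cohort(cfg: PipelineConfig) -> Cohort:
    if cfg.design is not None:
        return simulate_cohort(cfg.design)
    path = Path(cfg.input_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return read_workbook(path, cfg.layout)
    return read_cohort_table(path)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full analysis; write the report bundle if ``cfg.outdir`` is set."""
    cfg.validate()
    cohort = _load_cohort(cfg)
    subjects: list[SubjectAnalysis] = []
    for rec in cohort.records:
        try:
            subjects.append(
                analyze_subject(rec, penalty=cfg.penalty, ref_toi=cfg.ref_toi, clamp=cfg.clamp)
            )
        except Exception as exc:
            raise type(exc)(
                f"subject {rec.subject_index} ({rec.internal_code}): {exc}"
            ) from exc

    group_labels = [s.record.group for s in subjects]
    group_keys = [f"{s.record.group}/{s.record.sex}" for s in subjects]
    n_toi = len(cohort.toi_labels)

    reports: dict[str, ComparisonReport] = {}
    # basal-state comparisons (normalized z over the optimal reference TOI)
    basal = [s.norm.z[s.seg.toi_slice(cfg.ref_toi)] for s in subjects]
    reports["basal_subjects"] = compare_subjects(
        basal, group_labels, alpha=cfg.alpha, method=cfg.posthoc,
        labels=[s.record.internal_code for s in subjects],
    )
    reports["basal_groups"] = compare_groups(
        basal, group_keys, pooling=cfg.group_pooling, alpha=cfg.alpha, method=cfg.posthoc
    )
    # successive-TOI difference comparisons, raw-based and PLA-based
    names = {2: "cold_to_basal", 3: "warm_to_cold"}
    for kk in range(2, n_toi + 1):
        base = names.get(kk, f"toi{kk}_to_toi{kk - 1}")
        for source, suffix in (("z", ""), ("z_pla", "_pla")):
            diffs = [s.diffs[(kk, kk - 1, source)].diff for s in subjects]
            reports[f"{base}{suffix}_subjects"] = compare_subjects(
                diffs, group_labels, alpha=cfg.alpha, method=cfg.posthoc,
                labels=[s.record.internal_code for s in subjects],
            )
            reports[f"{base}{suffix}_groups"] = compare_groups(
                diffs, group_keys, pooling=cfg.group_pooling,
                alpha=cfg.alpha, method=cfg.posthoc,
            )

    result = PipelineResult(cohort=cohort, subjects=subjects, reports=reports)
    if cfg.outdir is not None:
        _write_bundle(result, cfg)
    return result


def _write_bundle(result: PipelineResult, cfg: PipelineConfig) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report_json(), fh, indent=2)

    # difference-count tables in the publication layout
    for name in list(result.reports):
        if not name.endswith("_subjects"):
            continue
        rep = result.reports[name]
        rows = []
        for s, c in zip(result.subjects, rep.counts):
            rows.append(
                {
                    "no": s.record.subject_index,
                    "code": s.record.internal_code,
                    "group": f"{'WT' if s.record.group == 'control' else 'LNAME'} {s.record.sex}",
                    "overall_differences": c["formatted"],
                    "differences_with_WT": c["vs_control"],
                    "differences_with_LNAME": c["vs_experimental"],
                }
            )
        df = pd.DataFrame(rows).sort_values("overall_differences", ascending=False, key=lambda s: s.str.split(":").str[0].astype(int))
        df.to_csv(outdir / f"{name}_counts.tsv", sep="\t", index=False)

    # long-format normalized series
    frames = []
    for s in result.subjects:
        ni = s.record.n
        toi_of = np.zeros(ni, dtype=int)
        for j, (a, b) in enumerate(s.seg.otoi, start=1):
            toi_of[a - 1 : b] = j
        frames.append(
            pd.DataFrame(
                {
                    "subject": s.record.subject_index,
                    "code": s.record.internal_code,
                    "sample": np.arange(1, ni + 1),
                    "toi": toi_of,  # 0 marks transition-window samples
                    "z": s.norm.z,
                    "z_pla": s.norm.z_pla,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "normalized_signals.tsv", sep="\t", index=False
    )

    if cfg.make_plots:
        from . import plots

        figdir = outdir / "figures"
        figdir.mkdir(exist_ok=True)
        for s in result.subjects:
            plots.plot_subject(s, figdir / f"subject_{s.record.subject_index:02d}.png")
        for name, rep in result.reports.items():
            if name.endswith("_subjects"):
                plots.plot_boxes(rep, figdir / f"{name}_box.png")
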