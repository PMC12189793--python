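"""Reading and writing cohort tables.

Two on-disk layouts are supported:

* an XLSX workbook with subject blocks laid side by side on one sheet, four
  columns per subject (row index, time, marker, perfusion value), a metadata
  row carrying the subject's internal code, group and sex, and a column-name
  row below it;
* a long-format UTF-8 tab-separated table with one row per sample and columns
  ``subject_index, code, group, sex, time, marker, value`` (lossless
  round-trip partner of the workbook layout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, PerfusionRecord


class LayoutError(ValueError):
    """A subject block does not match the declared column layout."""


class TimeOrderError(ValueError):
    """Time stamps are not strictly increasing."""


class MarkerError(ValueError):
    """Marker labels are unknown or not in contiguous blocks."""


@dataclass
class LayoutConfig:
    """Describes how subject blocks are arranged in a workbook sheet.

    ``column_roles`` maps the four columns of each block to their meaning;
    the default follows the convention col1 = within-subject row index,
    col2 = time, col3 = marker, col4 = perfusion value.
    """

    column_roles: tuple[str, str, str, str] = ("index", "time", "marker", "value")
    meta_row: int = 1          # internal code, group, sex in the block's first 3 cells
    header_row: int = 2        # per-column names (ignored on read)
    data_start_row: int = 3
    sheet: int | str = 0
    toi_order: list[str] = field(default_factory=list)  # override first-appearance order

    @property
    def block_width(self) -> int:
        return len(self.column_roles)


def read_workbook(path, layout: LayoutConfig | None = None) -> Cohort:
    """Read a side-by-side-block workbook into a :class:`Cohort`.

    Subject blocks are discovered left to right; each must provide the four
    roles of ``layout.column_roles``.  Trailing empty cells are trimmed.
    """
    import openpyxl

    layout = layout or LayoutConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    ws = wb[wb.sheetnames[layout.sheet]] if isinstance(layout.sheet, int) else wb[layout.sheet]
    rows = list(ws.iter_rows(values_only=True))
    wb.close()
    if not rows:
        return Cohort(records=[], toi_labels=list(layout.toi_order))

    ncol = max(len(r) for r in rows)
    w = layout.block_width
    records: list[PerfusionRecord] = []
    subject = 0
    for c0 in range(0, ncol, w):
        meta = rows[layout.meta_row - 1][c0 : c0 + w] if len(rows) >= layout.meta_row else ()
        meta = tuple(m for m in meta)
        if not any(m is not None and str(m).strip() for m in meta):
            continue  # empty block slot
        subject += 1
        if len(meta) < 3 or any(meta[i] is None for i in range(3)):
            raise LayoutError(
                f"subject block {subject}: metadata row must carry code, group, sex"
            )
        code, group, sex = (str(meta[i]).strip() for i in range(3))
        time_i = layout.column_roles.index("time")
        marker_i = layout.column_roles.index("marker")
        value_i = layout.column_roles.index("value")
        times, markers, values = [], [], []
        for r in rows[layout.data_start_row - 1 :]:
            cells = r[c0 : c0 + w]
            cells = tuple(cells) + (None,) * (w - len(cells))
            if all(c is None or (isinstance(c, str) and not c.strip()) for c in cells):
                break  # trailing empty region of this block
            t, m, v = cells[time_i], cells[marker_i], cells[value_i]
            for name, cell in (("time", t), ("marker", m), ("value", v)):
                if cell is None or (isinstance(cell, str) and not cell.strip()):
                    raise LayoutError(
                        f"subject block {subject} ({code}): missing {name} column value"
                    )
            try:
                times.append(float(t))
                values.append(float(v))
            except (TypeError, ValueError) as exc:
                raise LayoutError(
                    f"subject block {subject} ({code}): non-numeric time/value cell"
                ) from exc
            markers.append(str(m).strip())
        if not times:
            raise LayoutError(f"subject block {subject} ({code}): no data rows")
        rec = PerfusionRecord(
            subject_index=subject,
            internal_code=code,
            group=group,
            sex=sex,
            times=np.array(times),
            markers=np.array(markers, dtype=object),
            values=np.array(values),
        )
        records.append(rec)

    toi_labels = list(layout.toi_order) or (records[0].marker_labels() if records else [])
    for rec in records:
        unknown = [m for m in rec.marker_labels() if m not in toi_labels]
        if unknown:
            raise MarkerError(
                f"subject {rec.subject_index} ({rec.internal_code}): unknown marker "
                f"label(s) {unknown}; expected {toi_labels}"
            )
    return Cohort(records=records, toi_labels=toi_labels)


def write_workbook(cohort: Cohort, path, layout: LayoutConfig | None = None) -> None:
    """Write a cohort in the side-by-side-block workbook layout."""
    import openpyxl

    layout = layout or LayoutConfig()
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "cohort"
    w = layout.block_width
    for k, rec in enumerate(cohort.records):
        c0 = k * w + 1
        ws.cell(row=layout.meta_row, column=c0, value=rec.internal_code)
        ws.cell(row=layout.meta_row, column=c0 + 1, value=rec.group)
        ws.cell(row=layout.meta_row, column=c0 + 2, value=rec.sex)
        for j, role in enumerate(layout.column_roles):
            ws.cell(row=layout.header_row, column=c0 + j, value=role)
        for i in range(rec.n):
            row = layout.data_start_row + i
            for j, role in enumerate(layout.column_roles):
                if role == "index":
                    v = i + 1
                elif role == "time":
                    v = float(rec.times[i])
                elif role == "marker":
                    v = str(rec.markers[i])
                else:
                    v = float(rec.values[i])
                ws.cell(row=row, column=c0 + j, value=v)
    wb.save(path)


_TABLE_COLUMNS = ["subject_index", "code", "group", "sex", "time", "marker", "value"]


def write_cohort_table(cohort: Cohort, path) -> None:
    """Write the long-format tab-separated table (one row per sample)."""
    frames = []
    for rec in cohort.records:
        frames.append(
            pd.DataFrame(
                {
                    "subject_index": rec.subject_index,
                    "code": rec.internal_code,
                    "group": rec.group,
                    "sex": rec.sex,
                    "time": rec.times,
                    "marker": rec.markers.astype(str),
                    "value": rec.values,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_TABLE_COLUMNS)
    )
    df.to_csv(path, sep="\t", index=False)


def read_cohort_table(path, toi_order: list[str] | None = None) -> Cohort:
    """Read the long-format table written by :func:`write_cohort_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "code": str})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"cohort table missing column(s) {missing}")
    records = []
    for idx, sub in df.groupby("subject_index", sort=True):
        records.append(
            PerfusionRecord(
                subject_index=int(idx),
                internal_code=str(sub["code"].iloc[0]),
                group=str(sub["group"].iloc[0]),
                sex=str(sub["sex"].iloc[0]),
                times=sub["time"].to_numpy(dtype=float),
                markers=sub["marker"].to_numpy(dtype=object),
                values=sub["value"].to_numpy(dtype=float),
            )
        )
    labels = list(toi_order) if toi_order else (records[0].marker_labels() if records else [])
    return Cohort(records=records, toi_labels=labels)
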