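"""Deposition-report writers: CSV (region, count, fraction) + JSON mirror."""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .transport import DepositionReport, GENERATION_ORDER

#: fixed row ordering: inlet/upper airways, generations, sections, the rest
ROW_ORDER = (
    "upper", "gen1", "gen2", "gen3", "gen4", "gen5",
    "left", "right", "outlet", "in-flight", "unlabelled",
)

__all__ = ["ROW_ORDER", "write_report", "read_report_csv", "report_rows"]


def report_rows(report: DepositionReport) -> list[tuple[str, int, float]]:
    rows = []
    for key in ROW_ORDER:
        if key in GENERATION_ORDER:
            c = report.generation_counts[key]
        elif key in ("left", "right"):
            c = report.section_counts[key]
        else:
            c = report.section_counts[key]
        rows.append((key, int(c), c / report.injected))
    return rows


def write_report(report: DepositionReport, path) -> tuple[Path, Path]:
    """Write ``<path>.csv`` and ``<path>.json`` (or honor a .csv suffix)."""
    path = Path(path)
    if path.suffix == ".csv":
        csv_path = path
        json_path = path.with_suffix(".json")
    else:
        csv_path = path.with_suffix(".csv")
        json_path = path.with_suffix(".json")
    rows = report_rows(report)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["region", "count", "fraction"])
        for name, count, frac in rows:
            w.writerow([name, count, f"{frac:.4f}"])
    payload = {
        "injected": report.injected,
        "rejected": report.rejected,
        "sections": report.section_counts,
        "section_fractions": report.section_fractions,
        "generations": report.generation_counts,
        "generation_fractions": report.generation_fractions,
        "sides": report.side_counts,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return csv_path, json_path


def read_report_csv(path) -> list[tuple[str, int, float]]:
    with open(path, newline="") as fh:
        rd = csv.reader(fh)
        header = next(rd)
        if header != ["region", "count", "fraction"]:
            raise ValueError(f"{path} is not a deposition report CSV")
        return [(name, int(c), float(f)) for name, c, f in rd]
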