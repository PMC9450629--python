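"""Packaged per-case ruler readings, table reproduction and report rendering.

The six cadaver cases' per-segment readings ship as a CSV fixture inside the
package (``data/table3.csv``), normalized from their comma-decimal originals
(kept as provenance comments in the file).  ``verify_fixtures`` cross-checks
every case's segment sum against its expected total.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .ruler import Segment, SegmentTable, sum_segments

__all__ = [
    "CaseFixture",
    "MeasurementReport",
    "CASE_IDS",
    "FIXTURE_SHA256",
    "fixture_checksum",
    "load_fixture",
    "all_fixtures",
    "verify_fixtures",
    "table_from_readings",
    "write_segments_csv",
    "read_segments_csv",
    "render_report",
    "render_case_matrix",
]

CASE_IDS = tuple(f"case{i}" for i in range(1, 7))

#: sha256 of the packaged fixture CSV; guards against silent edits.
FIXTURE_SHA256 = "5fac1470d33bc0df46ec422c2155a75ac47bc7f89dcd0a1e198628814263a8f5"

_DNM = "DNM"


@dataclass(frozen=True)
class CaseFixture:
    """One case's ordered readings (DNM rows omitted) and expected total."""

    case_id: str
    readings: tuple[float, ...]
    expected_total: float


@dataclass
class MeasurementReport:
    """A rendered measurement: provenance, the segment table, totals."""

    provenance: dict
    table: SegmentTable
    total: float
    bias: dict | None = None


def _fixture_bytes() -> bytes:
    return resources.files("cochlen").joinpath("data/table3.csv").read_bytes()


def fixture_checksum() -> str:
    """sha256 hex digest of the packaged fixture CSV."""
    return hashlib.sha256(_fixture_bytes()).hexdigest()


def _fixture_frame() -> pd.DataFrame:
    from io import BytesIO

    return pd.read_csv(BytesIO(_fixture_bytes()), comment="#", dtype=str)


def load_fixture(case_id: str) -> CaseFixture:
    """Load one case's packaged readings.

    Raises
    ------
    KeyError
        For an unknown ``case_id`` (valid ids: case1..case6).
    """
    if case_id not in CASE_IDS:
        raise KeyError(f"unknown case id {case_id!r}; valid: {', '.join(CASE_IDS)}")
    df = _fixture_frame()
    col = df.set_index("label")[case_id]
    readings = tuple(
        float(v) for v in col.drop("total") if v != _DNM
    )
    return CaseFixture(
        case_id=case_id,
        readings=readings,
        expected_total=float(col["total"]),
    )


def all_fixtures() -> list[CaseFixture]:
    return [load_fixture(cid) for cid in CASE_IDS]


def verify_fixtures() -> dict[str, dict]:
    """Sum each case's readings and compare with its expected total.

    Returns a per-case summary; failures are reported, not raised.
    """
    out: dict[str, dict] = {}
    for fx in all_fixtures():
        computed = sum_segments(list(fx.readings))
        out[fx.case_id] = {
            "computed_total": computed,
            "expected_total": fx.expected_total,
            "n_segments": len(fx.readings),
            "passed": abs(computed - fx.expected_total) < 1e-12,
        }
    return out


def table_from_readings(readings: Sequence[float]) -> SegmentTable:
    """Build a SegmentTable from bare nominal lengths.

    Endpoints are laid out along a straight line, so each chord equals the
    arc it spans; useful for rendering packaged fixtures that carry no
    geometry.
    """
    table = SegmentTable()
    pos = 0.0
    for i, length in enumerate(readings):
        table.segments.append(
            Segment(
                label=f"R{i + 1}",
                nominal_length=float(length),
                start_point=(pos, 0.0, 0.0),
                end_point=(pos + length, 0.0, 0.0),
                start_arc=pos,
                end_arc=pos + length,
            )
        )
        pos += length
    return table


# ---------------------------------------------------------------------------
# Segments CSV (the chordwalk output dialect) and reports
# ---------------------------------------------------------------------------

_SEG_COLUMNS = [
    "label",
    "length_mm",
    "x0",
    "y0",
    "z0",
    "x1",
    "y1",
    "z1",
    "start_arc_mm",
    "end_arc_mm",
]


def _fmt(value: float, decimal: str = ".") -> str:
    text = f"{value:.2f}"
    return text.replace(".", decimal) if decimal != "." else text


def write_segments_csv(table: SegmentTable, path: str | Path) -> None:
    """Write placed chords plus a trailing metadata block."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SEG_COLUMNS)
        for seg in table.segments:
            writer.writerow(
                [
                    seg.label,
                    repr(float(seg.nominal_length)),
                    *(repr(float(v)) for v in seg.start_point),
                    *(repr(float(v)) for v in seg.end_point),
                    repr(float(seg.start_arc)),
                    repr(float(seg.end_arc)),
                ]
            )
        fh.write(f"# total_mm={table.total!r}\n")
        fh.write(f"# remainder_arc_mm={table.remainder_arc!r}\n")
        fh.write(f"# terminated_with_remainder={table.terminated_with_remainder}\n")


def read_segments_csv(path: str | Path) -> SegmentTable:
    """Parse a segments CSV back into a SegmentTable (lossless round-trip)."""
    table = SegmentTable()
    meta: dict[str, str] = {}
    with open(path, newline="") as fh:
        rows = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
            elif line:
                rows.append(line)
    for rec in csv.DictReader(rows):
        table.segments.append(
            Segment(
                label=rec["label"],
                nominal_length=float(rec["length_mm"]),
                start_point=(float(rec["x0"]), float(rec["y0"]), float(rec["z0"])),
                end_point=(float(rec["x1"]), float(rec["y1"]), float(rec["z1"])),
                start_arc=float(rec["start_arc_mm"]),
                end_arc=float(rec["end_arc_mm"]),
            )
        )
    table.remainder_arc = float(meta.get("remainder_arc_mm", 0.0))
    table.terminated_with_remainder = (
        meta.get("terminated_with_remainder", "False") == "True"
    )
    return table


def render_report(
    table: SegmentTable,
    meta: dict,
    out_csv: str | Path | None = None,
    out_txt: str | Path | None = None,
    decimal: str = ".",
) -> MeasurementReport:
    """Render a single-case measurement report (CSV + plain text).

    The text report lists one row per placed ruler and a totals row; trailing
    unplaced rows are omitted for single-case reports.  ``decimal=","``
    mirrors the comma-decimal rendering of the source tables.
    """
    report = MeasurementReport(
        provenance=dict(meta), table=table, total=table.total
    )
    if out_csv is not None:
        write_segments_csv(table, out_csv)
    if out_txt is not None:
        lines = [f"# {k}: {v}" for k, v in meta.items()]
        for seg in table.segments:
            lines.append(f"{seg.label}\t{_fmt(seg.nominal_length, decimal)}")
        if table.terminated_with_remainder:
            lines.append(f"# unmeasured remainder: {_fmt(table.remainder_arc, decimal)} mm")
        lines.append(f"length (mm)\t{_fmt(table.total, decimal)}")
        Path(out_txt).write_text("\n".join(lines) + "\n")
    return report


def render_case_matrix(
    fixtures: Sequence[CaseFixture], decimal: str = "."
) -> str:
    """Multi-case text table: rows R1..Rmax, ``DNM`` for unplaced cells.

    Mirrors the layout of the source per-case table, totals row last.
    """
    n_rows = max(len(fx.readings) for fx in fixtures)
    header = ["Distance", *(fx.case_id for fx in fixtures)]
    lines = ["\t".join(header)]
    for i in range(n_rows):
        cells = [f"R{i + 1}"]
        for fx in fixtures:
            cells.append(
                _fmt(fx.readings[i], decimal) if i < len(fx.readings) else _DNM
            )
        lines.append("\t".join(cells))
    totals = ["length (mm)", *(_fmt(fx.expected_total, decimal) for fx in fixtures)]
    lines.append("\t".join(totals))
    return "\n".join(lines) + "\n"
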