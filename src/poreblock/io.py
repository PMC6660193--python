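"""Delimited-text readers and writers for the package's dataset schemas.

Dialect is fixed, not sniffed: comma-separated, ``.`` decimal, UTF-8, with
``#``-prefixed ``key=value`` metadata header lines.  Schemas:

* time course  — ``t_s,i_norm``        meta: tx_conc_uM, application_start_s,
  application_end_s, condition
* trace pair   — ``t_ms,i_ctrl_uA,i_tx_uA``  meta: v_mV, vh_mV, tx_conc_uM
* titration    — ``k_mM,value,kind,cell_id``
* tonic        — ``v_mV,i_ratio,regime``
* G-V          — ``v_mV,g_norm``
"""

from __future__ import annotations

import csv
from typing import Sequence

import numpy as np

from .relaxation import BlockTimeCourse, TracePair
from .state_model import GVPoint, TonicPoint
from .titration import TitrationPoint

__all__ = [
    "ParseError",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_titration_csv",
    "write_titration_csv",
    "read_tonic_csv",
    "write_tonic_csv",
    "read_gv_csv",
    "write_gv_csv",
]


def _fmt(x) -> str:
    return repr(float(x))


class ParseError(ValueError):
    """Malformed dataset file; carries the 1-based line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


def _split_file(path) -> tuple[dict[str, str], list[tuple[int, list[str]]]]:
    """Metadata dict plus (line_no, fields) rows, header line excluded."""
    meta: dict[str, str] = {}
    rows: list[tuple[int, list[str]]] = []
    header_seen = False
    with open(path, newline="", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            fields = next(csv.reader([line]))
            if not header_seen:
                header_seen = True
                continue
            rows.append((line_no, [f.strip() for f in fields]))
    if not header_seen:
        raise ParseError(path, 1, "no header row found")
    return meta, rows


def _require_meta(meta: dict[str, str], keys: Sequence[str], path) -> None:
    for key in keys:
        if key not in meta:
            raise ParseError(path, 1, f"missing mandatory metadata key '{key}'")


def _floats(path, line_no: int, fields: list[str], n: int) -> list[float]:
    if len(fields) < n:
        raise ParseError(path, line_no, f"expected {n} columns, got {len(fields)}")
    try:
        return [float(f) for f in fields[:n]]
    except ValueError as exc:
        raise ParseError(path, line_no, f"non-numeric value: {exc}") from None


def read_timecourse_csv(path) -> BlockTimeCourse:
    meta, rows = _split_file(path)
    _require_meta(meta, ("tx_conc_uM", "application_start_s", "application_end_s"), path)
    data = np.array([_floats(path, ln, fields, 2) for ln, fields in rows])
    if data.size == 0:
        raise ParseError(path, 1, "no data rows")
    times = data[:, 0]
    if np.any(np.diff(times) <= 0):
        bad = int(np.nonzero(np.diff(times) <= 0)[0][0])
        raise ParseError(path, rows[bad + 1][0], "non-monotone time column")
    return BlockTimeCourse(
        times=times,
        amplitudes=data[:, 1],
        toxin_conc=float(meta["tx_conc_uM"]),
        application_window=(
            float(meta["application_start_s"]),
            float(meta["application_end_s"]),
        ),
        condition_label=meta.get("condition", ""),
    )


def write_timecourse_csv(path, course: BlockTimeCourse) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# tx_conc_uM={_fmt(course.toxin_conc)}\n")
        fh.write(f"# application_start_s={_fmt(course.application_window[0])}\n")
        fh.write(f"# application_end_s={_fmt(course.application_window[1])}\n")
        fh.write(f"# condition={course.condition_label}\n")
        fh.write("t_s,i_norm\n")
        for t, a in zip(course.times, course.amplitudes):
            fh.write(f"{_fmt(t)},{_fmt(a)}\n")


def read_trace_csv(path) -> TracePair:
    meta, rows = _split_file(path)
    _require_meta(meta, ("v_mV", "vh_mV", "tx_conc_uM"), path)
    data = np.array([_floats(path, ln, fields, 3) for ln, fields in rows])
    if data.size == 0:
        raise ParseError(path, 1, "no data rows")
    times = data[:, 0]
    if np.any(np.diff(times) <= 0):
        bad = int(np.nonzero(np.diff(times) <= 0)[0][0])
        raise ParseError(path, rows[bad + 1][0], "non-monotone time column")
    return TracePair(
        times=times,
        control_current=data[:, 1],
        toxin_current=data[:, 2],
        step_voltage=float(meta["v_mV"]),
        holding_voltage=float(meta["vh_mV"]),
        toxin_conc=float(meta["tx_conc_uM"]),
    )


def write_trace_csv(path, pair: TracePair) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# v_mV={_fmt(pair.step_voltage)}\n")
        fh.write(f"# vh_mV={_fmt(pair.holding_voltage)}\n")
        fh.write(f"# tx_conc_uM={_fmt(pair.toxin_conc)}\n")
        fh.write("t_ms,i_ctrl_uA,i_tx_uA\n")
        for t, c, x in zip(pair.times, pair.control_current, pair.toxin_current):
            fh.write(f"{_fmt(t)},{_fmt(c)},{_fmt(x)}\n")


def read_titration_csv(path) -> list[TitrationPoint]:
    _, rows = _split_file(path)
    points = []
    for ln, fields in rows:
        if len(fields) < 4:
            raise ParseError(path, ln, f"expected 4 columns, got {len(fields)}")
        k, value = _floats(path, ln, fields[:2], 2)
        try:
            points.append(
                TitrationPoint(k_conc=k, value=value, kind=fields[2], cell_id=fields[3])
            )
        except ValueError as exc:
            raise ParseError(path, ln, str(exc)) from None
    if not points:
        raise ParseError(path, 1, "no data rows")
    return points


def write_titration_csv(path, points: Sequence[TitrationPoint]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("k_mM,value,kind,cell_id\n")
        for p in points:
            fh.write(f"{_fmt(p.k_conc)},{_fmt(p.value)},{p.kind},{p.cell_id}\n")


def read_tonic_csv(path) -> list[TonicPoint]:
    _, rows = _split_file(path)
    points = []
    for ln, fields in rows:
        if len(fields) < 3:
            raise ParseError(path, ln, f"expected 3 columns, got {len(fields)}")
        v, ratio = _floats(path, ln, fields[:2], 2)
        try:
            points.append(TonicPoint(voltage=v, inhibition_ratio=ratio, regime=fields[2]))
        except ValueError as exc:
            raise ParseError(path, ln, str(exc)) from None
    if not points:
        raise ParseError(path, 1, "no data rows")
    return points


def write_tonic_csv(path, points: Sequence[TonicPoint]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("v_mV,i_ratio,regime\n")
        for p in points:
            fh.write(f"{_fmt(p.voltage)},{_fmt(p.inhibition_ratio)},{p.regime}\n")


def read_gv_csv(path) -> list[GVPoint]:
    _, rows = _split_file(path)
    points = []
    for ln, fields in rows:
        v, g = _floats(path, ln, fields, 2)
        try:
            points.append(GVPoint(voltage=v, g_norm=g))
        except ValueError as exc:
            raise ParseError(path, ln, str(exc)) from None
    if not points:
        raise ParseError(path, 1, "no data rows")
    return points


def write_gv_csv(path, points: Sequence[GVPoint]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("v_mV,g_norm\n")
        for p in points:
            fh.write(f"{_fmt(p.voltage)},{_fmt(p.g_norm)}\n")
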