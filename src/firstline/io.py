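"""Readers and writers for the delimited file formats the pipeline uses.

Records files are CSV/TSV with header ``patient_id,record_id,record_date,
text`` (dates ISO-8601 or empty).  Label files carry ``patient_id,group``.
A counts file carries one one-vs-rest 2x2 table per group for evaluating
directly from published tables.
"""

from __future__ import annotations

import csv
from datetime import date
from pathlib import Path
from typing import Iterable

import pandas as pd

from .classify import PatientClassification, RecordClassification, TreatmentGroup
from .evaluation import ContingencyTable2x2, EvaluationReport, round_half_up
from .matcher import TextRecord

__all__ = [
    "read_records",
    "write_records",
    "read_labels",
    "write_labels",
    "read_counts",
    "write_record_classifications",
    "write_patient_classifications",
    "render_report",
]

_RECORD_COLUMNS = ["patient_id", "record_id", "record_date", "text"]


class SchemaError(ValueError):
    """An input file does not have the expected columns."""


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_records(path: str | Path) -> list[TextRecord]:
    """Parse a records file.  Empty dates become absent; text is preserved
    verbatim (normalization happens downstream)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=_delimiter_for(path))
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    records: list[TextRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw_date = getattr(row, "record_date").strip()
        record_date: date | None = None
        if raw_date:
            try:
                record_date = date.fromisoformat(raw_date)
            except ValueError as exc:
                raise ValueError(f"{path} line {i}: invalid date {raw_date!r}: {exc}") from exc
        try:
            records.append(
                TextRecord(
                    patient_id=getattr(row, "patient_id"),
                    record_id=getattr(row, "record_id"),
                    text=getattr(row, "text"),
                    record_date=record_date,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return records


def write_records(records: Iterable[TextRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_delimiter_for(path), lineterminator="\n")
        writer.writerow(_RECORD_COLUMNS)
        for r in records:
            writer.writerow(
                [r.patient_id, r.record_id, r.record_date.isoformat() if r.record_date else "", r.text]
            )


def read_labels(path: str | Path) -> list[tuple[str, TreatmentGroup]]:
    """Parse a patient-label file with header ``patient_id,group``."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=_delimiter_for(path))
    missing = [c for c in ("patient_id", "group") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out: list[tuple[str, TreatmentGroup]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append((row.patient_id, TreatmentGroup(row.group)))
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return out


def write_labels(labels: Iterable[tuple[str, TreatmentGroup]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_delimiter_for(path), lineterminator="\n")
        writer.writerow(["patient_id", "group"])
        for pid, group in labels:
            writer.writerow([pid, TreatmentGroup(group).value])


def read_counts(path: str | Path) -> dict[TreatmentGroup, ContingencyTable2x2]:
    """Parse a counts file with header ``group,tp,fp,fn,tn`` — one published
    one-vs-rest table per row."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=_delimiter_for(path))
    missing = [c for c in ("group", "tp", "fp", "fn", "tn") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out: dict[TreatmentGroup, ContingencyTable2x2] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out[TreatmentGroup(row.group)] = ContingencyTable2x2(
                tp=int(row.tp), fp=int(row.fp), fn=int(row.fn), tn=int(row.tn)
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return out


def write_record_classifications(
    classifications: Iterable[RecordClassification], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_delimiter_for(path), lineterminator="\n")
        writer.writerow(["record_id", "group", "rule_fired", "evidence"])
        for c in classifications:
            evidence = "|".join(
                f"{m.canonical}[{m.start}:{m.end}]"
                + ("(neg)" if m.negated else "")
                + ("(unc)" if m.uncertain else "")
                for m in c.mentions
            )
            writer.writerow([c.record_id, c.group.value, c.rule_fired, evidence])


def write_patient_classifications(
    classifications: Iterable[PatientClassification], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_delimiter_for(path), lineterminator="\n")
        writer.writerow(["patient_id", "group", "source_record_id", "n_records"])
        for c in classifications:
            writer.writerow(
                [c.patient_id, c.group.value, c.source_record_id or "", c.n_records]
            )


def _pct(metric) -> str:
    return (
        f"{round_half_up(100 * metric.estimate, 1):.1f} "
        f"(95% CI {round_half_up(100 * metric.ci_low, 1):.1f}, "
        f"{round_half_up(100 * metric.ci_high, 1):.1f})"
    )


def render_report(report: EvaluationReport) -> str:
    """Render an evaluation report as structured key-value text: one block
    per group with contingency counts, agreement, kappa, sensitivity,
    specificity, PPV, NPV and error counts."""
    lines = [f"n_patients: {report.n}", ""]
    for g in TreatmentGroup:
        ge = report.groups[g]
        t = ge.table
        k = ge.kappa
        lines += [
            f"[{g.value}]",
            f"tp: {t.tp}",
            f"fp: {t.fp}",
            f"fn: {t.fn}",
            f"tn: {t.tn}",
            f"agreement_pct: {_pct(ge.agreement)}",
            f"kappa: {round_half_up(k.estimate, 2):.2f} "
            f"(95% CI {round_half_up(k.ci_low, 2):.2f}, {round_half_up(k.ci_high, 2):.2f})",
            f"sensitivity_pct: {_pct(ge.sensitivity)}",
            f"specificity_pct: {_pct(ge.specificity)}",
            f"ppv_pct: {_pct(ge.ppv)}",
            f"npv_pct: {_pct(ge.npv)}",
            f"false_positives: {ge.fp} ({round_half_up(100 * ge.fp / report.n, 1):.1f})",
            f"false_negatives: {ge.fn} ({round_half_up(100 * ge.fn / report.n, 1):.1f})",
            f"total_errors: {ge.total_errors} ({round_half_up(100 * ge.total_errors / report.n, 1):.1f})",
            "",
        ]
    return "\n".join(lines)
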