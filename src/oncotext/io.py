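"""Readers and writers for the corpus, label, prediction and survival tables.

Documents travel as JSON-lines (one document object per line); every tabular
artifact is CSV with a fixed header.  All writers emit UTF-8 with LF line
endings and canonical field ordering so that round-trips are byte-identical.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .data_model import (
    METASTATIC_SITES,
    Corpus,
    ClinicalDocument,
    DocumentLabel,
    DocumentPrediction,
    PatientRecord,
    TreatmentLine,
    ValidationError,
    parse_date,
)

DOCUMENT_FIELDS = ("doc_id", "patient_id", "date", "kind", "text")
LABEL_COLUMNS = ("doc_id", "any_cancer", "progression", "response") + tuple(
    f"site_{s}" for s in METASTATIC_SITES
)
PATIENT_COLUMNS = (
    "patient_id",
    "cancer_type",
    "sex",
    "age_group",
    "ngs_date",
    "tmb",
    "death_date",
    "last_contact_date",
)
TREATMENT_COLUMNS = ("patient_id", "line_number", "start_date", "intent", "contains_ici")
PREDICTION_COLUMNS = ("doc_id", "outcome", "score", "probability", "provenance")
SPLIT_COLUMNS = ("patient_id", "partition", "fold")


def validate_header(path: Path, expected: tuple[str, ...]) -> None:
    """Hard-fail on a CSV whose header does not match the documented schema."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    if tuple(header) != expected:
        raise ValidationError(
            f"{path}: header {header} does not match expected schema {list(expected)}"
        )


def _date_or_none(value):
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    return parse_date(value)


def read_documents(path) -> list[ClinicalDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}:{lineno}: invalid JSON") from exc
            missing = [f for f in DOCUMENT_FIELDS if f not in obj]
            if missing:
                raise ValidationError(f"{path}:{lineno}: missing fields {missing}")
            docs.append(
                ClinicalDocument(
                    doc_id=str(obj["doc_id"]),
                    patient_id=str(obj["patient_id"]),
                    date=parse_date(obj["date"]),
                    kind=obj["kind"],
                    text=obj["text"],
                )
            )
    return docs


def write_documents(docs: Iterable[ClinicalDocument], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for d in docs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": d.doc_id,
                        "patient_id": d.patient_id,
                        "date": d.date.isoformat(),
                        "kind": d.kind,
                        "text": d.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_labels(path) -> dict[str, DocumentLabel]:
    validate_header(Path(path), LABEL_COLUMNS)
    df = pd.read_csv(path, dtype={"doc_id": str})
    labels = {}
    for row in df.itertuples(index=False):
        site_values = {s: getattr(row, f"site_{s}") for s in METASTATIC_SITES}
        has_sites = not any(
            isinstance(v, float) and math.isnan(v) for v in site_values.values()
        )
        labels[row.doc_id] = DocumentLabel(
            doc_id=row.doc_id,
            any_cancer=int(row.any_cancer),
            progression=int(row.progression),
            response=int(row.response),
            sites={s: int(v) for s, v in site_values.items()} if has_sites else None,
        )
    return labels


def write_labels(labels: dict[str, DocumentLabel], path) -> None:
    rows = []
    for doc_id in sorted(labels):
        lab = labels[doc_id]
        row = {
            "doc_id": doc_id,
            "any_cancer": lab.any_cancer,
            "progression": lab.progression,
            "response": lab.response,
        }
        for s in METASTATIC_SITES:
            row[f"site_{s}"] = "" if lab.sites is None else lab.sites[s]
        rows.append(row)
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def read_patients(path, treatments_path=None) -> dict[str, PatientRecord]:
    validate_header(Path(path), PATIENT_COLUMNS)
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    lines_by_patient: dict[str, list[TreatmentLine]] = {}
    if treatments_path is not None:
        validate_header(Path(treatments_path), TREATMENT_COLUMNS)
        tdf = pd.read_csv(treatments_path, dtype={"patient_id": str})
        for row in tdf.itertuples(index=False):
            lines_by_patient.setdefault(row.patient_id, []).append(
                TreatmentLine(
                    start_date=parse_date(row.start_date),
                    intent=row.intent,
                    contains_ici=bool(row.contains_ici),
                    line_number=int(row.line_number),
                )
            )
    patients = {}
    for row in df.itertuples(index=False):
        tmb = float(row.tmb)
        if tmb < 0:
            raise ValidationError(f"patient {row.patient_id}: tmb < 0 rejected")
        patients[row.patient_id] = PatientRecord(
            patient_id=row.patient_id,
            cancer_type=row.cancer_type,
            sex=row.sex,
            age_group=str(row.age_group),
            ngs_date=parse_date(row.ngs_date),
            tmb=tmb,
            death_date=_date_or_none(row.death_date),
            last_contact_date=parse_date(row.last_contact_date),
            treatment_lines=sorted(
                lines_by_patient.get(row.patient_id, []), key=lambda t: t.line_number
            ),
        )
    return patients


def write_patients(patients: dict[str, PatientRecord], path, treatments_path=None) -> None:
    rows = []
    trows = []
    for pid in sorted(patients):
        p = patients[pid]
        rows.append(
            {
                "patient_id": p.patient_id,
                "cancer_type": p.cancer_type,
                "sex": p.sex,
                "age_group": p.age_group,
                "ngs_date": p.ngs_date.isoformat(),
                "tmb": repr(p.tmb),
                "death_date": "" if p.death_date is None else p.death_date.isoformat(),
                "last_contact_date": p.last_contact_date.isoformat(),
            }
        )
        for t in p.treatment_lines:
            trows.append(
                {
                    "patient_id": p.patient_id,
                    "line_number": t.line_number,
                    "start_date": t.start_date.isoformat(),
                    "intent": t.intent,
                    "contains_ici": int(t.contains_ici),
                }
            )
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False, lineterminator="\n")
    if treatments_path is not None:
        pd.DataFrame(trows, columns=TREATMENT_COLUMNS).to_csv(
            treatments_path, index=False, lineterminator="\n"
        )


def read_corpus(documents_path, patients_path, labels_path=None, treatments_path=None) -> Corpus:
    """Read and link the corpus artifacts, reporting all join errors together."""
    documents = read_documents(documents_path)
    patients = read_patients(patients_path, treatments_path)
    labels = read_labels(labels_path) if labels_path is not None else {}
    errors = []
    doc_ids = {d.doc_id for d in documents}
    for doc_id in labels:
        if doc_id not in doc_ids:
            errors.append(f"label row doc_id {doc_id} matches no document")
    for d in documents:
        if d.patient_id not in patients:
            errors.append(f"document {d.doc_id} references unknown patient {d.patient_id}")
    if errors:
        raise ValidationError("; ".join(errors))
    return Corpus(patients=patients, documents=documents, labels=labels)


def write_corpus(corpus: Corpus, out_dir, prefix: str = "corpus") -> dict[str, Path]:
    """Write all corpus artifacts under ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "documents": out_dir / f"{prefix}_documents.jsonl",
        "patients": out_dir / f"{prefix}_patients.csv",
        "treatments": out_dir / f"{prefix}_treatments.csv",
        "labels": out_dir / f"{prefix}_labels.csv",
    }
    docs = sorted(corpus.documents, key=lambda d: d.doc_id)
    write_documents(docs, paths["documents"])
    write_patients(corpus.patients, paths["patients"], paths["treatments"])
    write_labels(corpus.labels, paths["labels"])
    return paths


def read_predictions(path) -> list[DocumentPrediction]:
    validate_header(Path(path), PREDICTION_COLUMNS)
    df = pd.read_csv(path, dtype={"doc_id": str}, float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        prob = float(row.probability)
        if not 0.0 <= prob <= 1.0:
            raise ValidationError(
                f"prediction {row.doc_id}/{row.outcome}: probability outside [0, 1] rejected"
            )
        out.append(
            DocumentPrediction(
                doc_id=row.doc_id,
                outcome=row.outcome,
                score=float(row.score),
                probability=prob,
                provenance=row.provenance,
            )
        )
    return out


def write_predictions(preds: Iterable[DocumentPrediction], path) -> None:
    rows = [
        {
            "doc_id": p.doc_id,
            "outcome": p.outcome,
            "score": repr(p.score),
            "probability": repr(p.probability),
            "provenance": p.provenance,
        }
        for p in preds
    ]
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(
        path, index=False, lineterminator="\n"
    )
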