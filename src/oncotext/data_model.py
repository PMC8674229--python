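"""Domain types shared by every pipeline stage.

The unit of annotation is a single clinical document (an imaging report or a
medical oncologist progress note).  Each document carries binary outcome
labels following the PRISSMM abstraction rubric: whether any cancer is
evident, whether the disease is progressing/worsening, whether it is
responding/improving, and — for imaging reports only — the presence of
disease at seven metastatic sites.  A "mixed" or stable disease status is
neither worsening nor improving, so ``progression`` and ``response`` may both
be 0; they are never both 1 on the same document.

Dates are ISO-8601 calendar days throughout.  Durations are computed in days
and converted to months with a fixed 30.44 days/month factor.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional

DAYS_PER_MONTH = 30.44

CANCER_TYPES = (
    "breast",
    "colorectal",
    "endometrial",
    "gastroesophageal",
    "head_and_neck",
    "leiomyosarcoma",
    "nsclc",
    "melanoma",
    "ovarian",
    "pancreatic",
    "prostate",
    "renal_cell",
    "urothelial",
)

#: Cancer types with manually labeled documents available for model training
#: (the remaining six types are annotated only by model inference).
LABELED_CANCER_TYPES = (
    "breast",
    "colorectal",
    "nsclc",
    "pancreatic",
    "prostate",
    "renal_cell",
    "urothelial",
)

METASTATIC_SITES = ("brain", "bone", "adrenal", "liver", "lung", "node", "peritoneum")

DOCUMENT_KINDS = ("imaging", "oncologist_note")

#: Outcomes modeled per document kind.  Site outcomes apply to imaging only.
CORE_OUTCOMES = ("any_cancer", "progression", "response")
SITE_OUTCOMES = tuple(f"site_{s}" for s in METASTATIC_SITES)

TMB_HIGH_CUTOFF = 20.0  # mutations/megabase


def outcomes_for_kind(kind: str, include_sites: bool = True) -> tuple[str, ...]:
    """Outcome names defined for a document kind."""
    if kind == "imaging":
        return CORE_OUTCOMES + (SITE_OUTCOMES if include_sites else ())
    if kind == "oncologist_note":
        return CORE_OUTCOMES
    raise ValueError(f"unknown document kind {kind!r}")


def days_to_months(days: float) -> float:
    return days / DAYS_PER_MONTH


def months_to_days(months: float) -> float:
    return months * DAYS_PER_MONTH


class ValidationError(ValueError):
    """A record violated a structural invariant; message names the record."""


def parse_date(value) -> _dt.date:
    """Parse an ISO-8601 calendar day; reject anything else."""
    if isinstance(value, _dt.date) and not isinstance(value, _dt.datetime):
        return value
    if isinstance(value, str):
        try:
            return _dt.date.fromisoformat(value)
        except ValueError as exc:
            raise ValidationError(f"malformed date {value!r}") from exc
    raise ValidationError(f"malformed date {value!r}")


@dataclass(frozen=True)
class TreatmentLine:
    """One systemic therapy line for a patient."""

    start_date: _dt.date
    intent: str  # palliative | curative
    contains_ici: bool
    line_number: int

    def __post_init__(self):
        if self.intent not in ("palliative", "curative"):
            raise ValidationError(f"treatment intent {self.intent!r} not recognized")
        if self.line_number < 1:
            raise ValidationError("line_number must be a positive integer")


@dataclass
class PatientRecord:
    patient_id: str
    cancer_type: str
    sex: str
    age_group: str
    ngs_date: _dt.date
    tmb: float
    last_contact_date: _dt.date
    death_date: Optional[_dt.date] = None
    treatment_lines: list[TreatmentLine] = field(default_factory=list)

    def __post_init__(self):
        if self.cancer_type not in CANCER_TYPES:
            raise ValidationError(
                f"patient {self.patient_id}: unknown cancer type {self.cancer_type!r}"
            )
        if not (self.tmb >= 0) or math.isnan(self.tmb):
            raise ValidationError(f"patient {self.patient_id}: tmb must be >= 0")
        starts = [t.start_date for t in self.treatment_lines]
        if starts != sorted(starts):
            raise ValidationError(
                f"patient {self.patient_id}: treatment lines not sorted by start date"
            )
        numbers = [t.line_number for t in self.treatment_lines]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValidationError(
                f"patient {self.patient_id}: line numbers not strictly increasing"
            )

    @property
    def tmb_high(self) -> bool:
        return self.tmb >= TMB_HIGH_CUTOFF

    @property
    def terminal_date(self) -> _dt.date:
        """Death date if observed, otherwise the censoring date."""
        return self.death_date if self.death_date is not None else self.last_contact_date

    def first_palliative_line(self) -> Optional[TreatmentLine]:
        for line in self.treatment_lines:
            if line.intent == "palliative":
                return line
        return None

    def ici_lines(self) -> list[TreatmentLine]:
        return [t for t in self.treatment_lines if t.contains_ici and t.intent == "palliative"]


@dataclass
class ClinicalDocument:
    doc_id: str
    patient_id: str
    date: _dt.date
    kind: str
    text: str

    def __post_init__(self):
        if self.kind not in DOCUMENT_KINDS:
            raise ValidationError(f"document {self.doc_id}: unknown kind {self.kind!r}")
        if not self.text:
            raise ValidationError(f"document {self.doc_id}: text must be non-empty")


@dataclass
class DocumentLabel:
    """Ground-truth binary PRISSMM outcomes for one document.

    Site flags are meaningful only for imaging documents; for notes they are
    ``None``.  Consistency: any positive outcome implies ``any_cancer``.
    """

    doc_id: str
    any_cancer: int
    progression: int
    response: int
    sites: Optional[dict[str, int]] = None

    def __post_init__(self):
        for name in ("any_cancer", "progression", "response"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValidationError(f"label {self.doc_id}: {name} must be 0 or 1")
        if (self.progression or self.response) and not self.any_cancer:
            raise ValidationError(
                f"label {self.doc_id}: progression/response requires any_cancer = 1"
            )
        if self.sites is not None:
            extra = set(self.sites) - set(METASTATIC_SITES)
            if extra:
                raise ValidationError(f"label {self.doc_id}: unknown sites {sorted(extra)}")
            if any(v not in (0, 1) for v in self.sites.values()):
                raise ValidationError(f"label {self.doc_id}: site flags must be 0 or 1")
            if any(self.sites.values()) and not self.any_cancer:
                raise ValidationError(
                    f"label {self.doc_id}: site flag requires any_cancer = 1"
                )

    def value(self, outcome: str) -> int:
        if outcome in CORE_OUTCOMES:
            return getattr(self, outcome)
        if outcome.startswith("site_"):
            if self.sites is None:
                raise KeyError(f"label {self.doc_id} has no site flags")
            return self.sites[outcome[len("site_"):]]
        raise KeyError(outcome)


@dataclass(frozen=True)
class DocumentPrediction:
    """Continuous model output for one (document, outcome) pair.

    ``score`` is the log odds that the outcome is present; ``probability``
    is its logistic transform.  ``provenance`` records whether the score came
    from the 10-model ensemble or from the single cross-validation member
    that excluded the document's patient from training.
    """

    doc_id: str
    outcome: str
    score: float
    probability: float
    provenance: str  # cv_excluded_fold | ensemble

    def __post_init__(self):
        if self.provenance not in ("cv_excluded_fold", "ensemble"):
            raise ValidationError(
                f"prediction {self.doc_id}/{self.outcome}: bad provenance {self.provenance!r}"
            )
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(
                f"prediction {self.doc_id}/{self.outcome}: probability outside [0, 1]"
            )
        expected = 1.0 / (1.0 + math.exp(-self.score))
        if abs(expected - self.probability) > 1e-9:
            raise ValidationError(
                f"prediction {self.doc_id}/{self.outcome}: probability != logistic(score)"
            )


@dataclass
class Corpus:
    """Linked patients, documents and (optionally) labels."""

    patients: dict[str, PatientRecord]
    documents: list[ClinicalDocument]
    labels: dict[str, DocumentLabel] = field(default_factory=dict)

    def __post_init__(self):
        errors = []
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                errors.append(f"duplicate doc_id {doc.doc_id}")
            seen.add(doc.doc_id)
            if doc.patient_id not in self.patients:
                errors.append(f"document {doc.doc_id}: unknown patient {doc.patient_id}")
        for doc_id in self.labels:
            if doc_id not in seen:
                errors.append(f"label for unknown document {doc_id}")
        for pat in self.patients.values():
            if pat.death_date is not None:
                late = [
                    d.doc_id
                    for d in self.documents
                    if d.patient_id == pat.patient_id and d.date > pat.death_date
                ]
                if late:
                    errors.append(
                        f"patient {pat.patient_id}: documents dated after death: {late}"
                    )
        if errors:
            raise ValidationError("; ".join(errors))

    def documents_of_kind(self, kind: str) -> list[ClinicalDocument]:
        return [d for d in self.documents if d.kind == kind]

    def documents_for_patient(self, patient_id: str) -> list[ClinicalDocument]:
        return [d for d in self.documents if d.patient_id == patient_id]

    @property
    def n_patients(self) -> int:
        return len(self.patients)
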