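"""Per-outcome model training with cross-validation ensembling.

One model family exists per (outcome, document kind).  The any-cancer model
has a single output; every other model is dual-output, sharing an auxiliary
any-cancer head with the outcome of interest.  The training split is cut
into ``n_folds`` patient-level folds; one member is trained per held-out
fold.  Inference routing:

* validation/test documents (and unlabeled patients) are scored by the
  ensemble — the arithmetic mean of the members' pre-sigmoid log-odds
  outputs, passed once through the logistic function;
* training-split documents are scored only by the single member whose
  held-out fold contains the document's patient, so no document is ever
  scored by a model that saw its patient during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ClinicalDocument, Corpus, DocumentPrediction
from .splits import SplitAssignment
from .textcnn import ConvTextClassifier, _sigmoid

PAD, UNK = 0, 1


@dataclass
class OutcomeModelSpec:
    """Configuration for one (outcome, document kind) model family."""

    outcome: str
    kind: str  # imaging | oncologist_note
    min_count: int = 2
    max_len: int = 128
    embed_dim: int = 16
    conv_widths: tuple = (2, 3, 4, 5)
    n_filters: int = 8
    dropout: float = 0.5
    epochs: int = 3
    batch_size: int = 64
    lr: float = 1e-2
    seed: int = 0

    @property
    def topology(self) -> str:
        return "single" if self.outcome == "any_cancer" else "dual"

    @property
    def n_outputs(self) -> int:
        return 1 if self.topology == "single" else 2

    @property
    def outcome_column(self) -> int:
        """Column of the outcome of interest in the model output."""
        return 0 if self.topology == "single" else 1

    def label_columns(self) -> tuple[str, ...]:
        if self.topology == "single":
            return (self.outcome,)
        return ("any_cancer", self.outcome)


class Vocabulary:
    """Token -> index map with reserved padding (0) and unknown (1) slots."""

    def __init__(self, index: dict[str, int]):
        self.index = index

    def __len__(self):
        return len(self.index) + 2

    def __contains__(self, token):
        return token in self.index

    @classmethod
    def build(cls, texts, min_count: int = 2) -> "Vocabulary":
        counts: dict[str, int] = {}
        for text in texts:
            for tok in text.lower().split():
                counts[tok] = counts.get(tok, 0) + 1
        index = {}
        for tok in sorted(counts):
            if counts[tok] >= min_count:
                index[tok] = len(index) + 2
        return cls(index)

    def encode(self, text: str, max_len: int) -> np.ndarray:
        ids = [self.index.get(t, UNK) for t in text.lower().split()[:max_len]]
        out = np.full(max_len, PAD, dtype=np.int64)
        out[: len(ids)] = ids
        return out


def vectorize(text: str, vocab: Vocabulary, max_len: int) -> np.ndarray:
    """Padded token-index sequence (truncate tail, pad end)."""
    return vocab.encode(text, max_len)


def _member_seed(spec_seed: int, fold: int) -> int:
    return int(np.random.SeedSequence((spec_seed, fold)).generate_state(1)[0] >> 1)


@dataclass
class FoldEnsemble:
    """The trained members for one outcome plus their fold membership map."""

    spec: OutcomeModelSpec
    vocab: Vocabulary
    members: list  # ConvTextClassifier per held-out fold, index = fold
    fold_of_patient: dict  # patient_id -> fold index (training split only)
    #: patients whose documents each member saw in training (leakage audits)
    training_patients: list = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.members)

    def _matrix(self, docs, texts) -> np.ndarray:
        return np.stack(
            [vectorize(texts[d.doc_id], self.vocab, self.spec.max_len) for d in docs]
        )

    def save(self, path) -> None:
        """Serialize spec + vocabulary + fold map + member weights as one
        versioned bundle."""
        import pickle

        bundle = {
            "format_version": 1,
            "spec": self.spec,
            "vocab_index": self.vocab.index,
            "fold_of_patient": self.fold_of_patient,
            "training_patients": self.training_patients,
            "members": [
                {"params": m.params_, "get_params": m.get_params()}
                for m in self.members
            ],
        }
        with open(path, "wb") as fh:
            pickle.dump(bundle, fh)

    @classmethod
    def load(cls, path) -> "FoldEnsemble":
        import pickle

        with open(path, "rb") as fh:
            bundle = pickle.load(fh)
        if bundle.get("format_version") != 1:
            raise ValueError(f"unsupported model bundle version in {path}")
        members = []
        for m in bundle["members"]:
            clf = ConvTextClassifier(**m["get_params"])
            clf.params_ = m["params"]
            members.append(clf)
        return cls(
            spec=bundle["spec"],
            vocab=Vocabulary(bundle["vocab_index"]),
            members=members,
            fold_of_patient=bundle["fold_of_patient"],
            training_patients=bundle["training_patients"],
        )

    def member_scores(self, docs, texts) -> np.ndarray:
        """(n_members, n_docs) pre-sigmoid outputs for the spec's outcome."""
        X = self._matrix(docs, texts)
        col = self.spec.outcome_column
        return np.stack([m.decision_function(X)[:, col] for m in self.members])


def _training_documents(corpus: Corpus, spec: OutcomeModelSpec, split: SplitAssignment):
    docs = [
        d
        for d in corpus.documents
        if d.kind == spec.kind
        and d.doc_id in corpus.labels
        and split.partition.get(d.patient_id) == "train"
    ]
    return docs


def _label_matrix(corpus: Corpus, docs, spec: OutcomeModelSpec) -> np.ndarray:
    cols = spec.label_columns()
    return np.array(
        [[corpus.labels[d.doc_id].value(c) for c in cols] for d in docs],
        dtype=np.float32,
    )


def train_fold_ensemble(
    corpus: Corpus,
    texts: dict[str, str],
    spec: OutcomeModelSpec,
    split: SplitAssignment,
    docs=None,
) -> FoldEnsemble:
    """Train one member per held-out fold on the training split.

    ``texts`` maps doc_id to the model input text (full report for imaging,
    extracted assessment/plan for notes).  ``docs`` may pre-filter the
    training documents (used by the exclusion/temporal retraining modes).
    """
    if docs is None:
        docs = _training_documents(corpus, spec, split)
    if not docs:
        raise ValueError("no labeled training documents for this spec")
    n_folds = split.n_folds
    train_patients = {d.patient_id for d in docs}
    missing = [p for p in train_patients if p not in split.fold]
    if missing:
        raise ValueError(f"patients without fold assignment: {sorted(missing)[:5]}")
    vocab = Vocabulary.build((texts[d.doc_id] for d in docs), spec.min_count)
    X = np.stack([vectorize(texts[d.doc_id], vocab, spec.max_len) for d in docs])
    Y = _label_matrix(corpus, docs, spec)
    folds = np.array([split.fold[d.patient_id] for d in docs])
    members = []
    training_patients = []
    for f in range(n_folds):
        mask = folds != f
        if mask.sum() == 0:
            raise ValueError(f"fold {f}: empty training set")
        for j, name in enumerate(spec.label_columns()):
            col = Y[mask, j]
            if col.min() == col.max():
                raise ValueError(
                    f"fold {f}: single-class training data for output {name!r}"
                )
        clf = ConvTextClassifier(
            vocab_size=len(vocab),
            n_outputs=spec.n_outputs,
            embed_dim=spec.embed_dim,
            conv_widths=spec.conv_widths,
            n_filters=spec.n_filters,
            dropout=spec.dropout,
            epochs=spec.epochs,
            batch_size=spec.batch_size,
            lr=spec.lr,
            seed=_member_seed(spec.seed, f),
        )
        clf.fit(X[mask], Y[mask])
        members.append(clf)
        training_patients.append({d.patient_id for d, m in zip(docs, mask) if m})
    fold_of_patient = {p: split.fold[p] for p in train_patients}
    return FoldEnsemble(
        spec=spec,
        vocab=vocab,
        members=members,
        fold_of_patient=fold_of_patient,
        training_patients=training_patients,
    )


def ensemble_predict(
    ensemble: FoldEnsemble, docs, texts: dict[str, str]
) -> list[DocumentPrediction]:
    """Mean-pool the members' linear outputs, then one logistic transform."""
    if not ensemble.members:
        raise ValueError("empty ensemble")
    docs = [d for d in docs if d.kind == ensemble.spec.kind]
    if not docs:
        return []
    scores = ensemble.member_scores(docs, texts).mean(axis=0)
    return [
        DocumentPrediction(
            doc_id=d.doc_id,
            outcome=ensemble.spec.outcome,
            score=float(s),
            probability=float(_sigmoid(np.float64(s))),
            provenance="ensemble",
        )
        for d, s in zip(docs, scores)
    ]


def crossval_inference(
    ensemble: FoldEnsemble, docs, texts: dict[str, str]
) -> list[DocumentPrediction]:
    """Score each training-split document with the one member whose held-out
    fold contains the document's patient."""
    docs = [d for d in docs if d.kind == ensemble.spec.kind]
    missing = [d.doc_id for d in docs if d.patient_id not in ensemble.fold_of_patient]
    if missing:
        raise ValueError(
            f"documents whose patients have no fold assignment: {missing[:5]}"
        )
    X = ensemble._matrix(docs, texts)
    col = ensemble.spec.outcome_column
    member_idx = np.array([ensemble.fold_of_patient[d.patient_id] for d in docs])
    scores = np.empty(len(docs), dtype=np.float64)
    for f in np.unique(member_idx):
        mask = member_idx == f
        scores[mask] = ensemble.members[int(f)].decision_function(X[mask])[:, col]
    return [
        DocumentPrediction(
            doc_id=d.doc_id,
            outcome=ensemble.spec.outcome,
            score=float(s),
            probability=float(_sigmoid(np.float64(s))),
            provenance="cv_excluded_fold",
        )
        for d, s in zip(docs, scores)
    ]


def train_excluding_cancer_type(
    corpus: Corpus,
    texts: dict[str, str],
    excluded_type: str,
    spec: OutcomeModelSpec,
    split: SplitAssignment,
) -> FoldEnsemble:
    """Retrain with every document of ``excluded_type`` removed from training,
    simulating absence of labeled data for that cancer type."""
    types = {p.cancer_type for p in corpus.patients.values()}
    if len(types) < 2 and excluded_type in types:
        raise ValueError("cannot exclude the only cancer type in the corpus")
    docs = [
        d
        for d in _training_documents(corpus, spec, split)
        if corpus.patients[d.patient_id].cancer_type != excluded_type
    ]
    return train_fold_ensemble(corpus, texts, spec, split, docs=docs)


def train_temporal_split(
    corpus: Corpus,
    texts: dict[str, str],
    spec: OutcomeModelSpec,
    split: SplitAssignment,
    cutoff_year: int,
) -> tuple[FoldEnsemble, list[ClinicalDocument]]:
    """Train on documents dated within ``cutoff_year`` or earlier; return the
    ensemble and the labeled post-cutoff documents for evaluation."""
    train_docs = [
        d
        for d in _training_documents(corpus, spec, split)
        if d.date.year <= cutoff_year
    ]
    eval_docs = [
        d
        for d in corpus.documents
        if d.kind == spec.kind and d.doc_id in corpus.labels and d.date.year > cutoff_year
    ]
    if not train_docs:
        raise ValueError(f"no labeled training documents dated <= {cutoff_year}")
    if not eval_docs:
        raise ValueError(f"no labeled documents dated > {cutoff_year} to evaluate")
    ensemble = train_fold_ensemble(corpus, texts, spec, split, docs=train_docs)
    return ensemble, eval_docs


def prepare_model_texts(corpus: Corpus, sectioner_model=None) -> dict[str, str]:
    """Model input text per document: the full report for imaging, the
    extracted assessment/plan for oncologist notes."""
    from .sectioner import extract_assessment_plan

    texts = {}
    for d in corpus.documents:
        if d.kind == "oncologist_note":
            texts[d.doc_id] = extract_assessment_plan(d.text, sectioner_model)
        else:
            texts[d.doc_id] = d.text
    return texts


def default_model_specs(
    kinds=("imaging", "oncologist_note"),
    outcomes=("any_cancer", "progression", "response"),
    seed: int = 0,
    **overrides,
) -> list[OutcomeModelSpec]:
    """One spec per (kind, outcome) cell with a distinct derived seed."""
    specs = []
    for i, kind in enumerate(kinds):
        for j, outcome in enumerate(outcomes):
            kw = dict(overrides)
            # note inputs are short extracted A/P spans; imaging uses the
            # full report text
            kw.setdefault("max_len", 64 if kind == "oncologist_note" else 128)
            specs.append(
                OutcomeModelSpec(
                    outcome=outcome,
                    kind=kind,
                    seed=int(np.random.SeedSequence((seed, i, j)).generate_state(1)[0] >> 1),
                    **kw,
                )
            )
    return specs
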