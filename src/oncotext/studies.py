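"""Prepackaged synthetic replication studies.

These compose the pipeline stages into the study designs the package is
validated against: document-level discrimination, generalization to a
cancer type held out of training, the association between time-varying
outcome annotations and overall survival, TMB vs PFS on ICI lines, censored
correlation recovery, and type-I-error calibration of the whole chain.
All randomness flows from explicit seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CORE_OUTCOMES, Corpus
from .evaluation import auroc, pick_operating_point
from .models import (
    FoldEnsemble,
    crossval_inference,
    default_model_specs,
    ensemble_predict,
    prepare_model_texts,
    train_excluding_cancer_type,
    train_fold_ensemble,
)
from .sectioner import train_sectioner
from .simulate import GeneratorConfig, SimulationTruth, simulate_cohort
from .splits import SplitAssignment, assign_splits
from .survival import (
    build_timelines,
    first_palliative_index_dates,
    os_association_analysis,
    survival_correlation,
    tmb_pfs_analysis,
)

#: Reduced cancer-type mix for replicate-based calibration studies: few
#: types with solid support keeps every per-type dummy estimable at small n.
REPLICATE_CANCER_WEIGHTS = {
    "nsclc": 0.4,
    "breast": 0.3,
    "colorectal": 0.2,
    "pancreatic": 0.1,
}


@dataclass
class DiscriminationStudy:
    """Trained artifacts plus per-cell test-set AUROCs."""

    corpus: Corpus
    truth: SimulationTruth
    texts: dict
    split: SplitAssignment
    ensembles: dict  # (kind, outcome) -> FoldEnsemble
    test_auroc: dict  # (kind, outcome) -> float
    thresholds: dict = field(default_factory=dict)  # (kind, outcome) -> best-F1 prob


def run_discrimination_study(
    seed: int,
    n_patients: int = 1000,
    label_noise: float = 0.05,
    outcomes=CORE_OUTCOMES,
    use_rnn_sectioner: bool = True,
    **model_overrides,
) -> DiscriminationStudy:
    """Simulate, section, train the per-outcome fold ensembles, and score
    the held-out test split against the generator's document labels."""
    gen = GeneratorConfig(n_patients=n_patients, seed=seed, label_noise=label_noise)
    corpus, truth = simulate_cohort(gen)
    split = assign_splits(corpus.patients.keys(), (0.8, 0.1, 0.1), 10, seed=seed + 1)
    tagger = None
    if use_rnn_sectioner:
        train_notes = [
            d.text
            for d in corpus.documents
            if d.kind == "oncologist_note" and split.partition[d.patient_id] == "train"
        ][:400]
        tagger = train_sectioner(train_notes, seed=seed + 2)
    texts = prepare_model_texts(corpus, tagger)
    specs = default_model_specs(outcomes=outcomes, seed=seed + 3, **model_overrides)
    ensembles, test_auroc, thresholds = {}, {}, {}
    for spec in specs:
        ens = train_fold_ensemble(corpus, texts, spec, split)
        ensembles[(spec.kind, spec.outcome)] = ens
        for part, store in (("test", test_auroc), ("validation", None)):
            docs = [
                d
                for d in corpus.documents
                if d.kind == spec.kind and split.partition[d.patient_id] == part
            ]
            preds = ensemble_predict(ens, docs, texts)
            y = np.array([corpus.labels[p.doc_id].value(spec.outcome) for p in preds])
            if store is not None:
                store[(spec.kind, spec.outcome)] = auroc(
                    np.array([p.score for p in preds]), y
                )
            else:
                probs = np.array([p.probability for p in preds])
                thresholds[(spec.kind, spec.outcome)] = pick_operating_point(
                    probs, y, "best_f1"
                ).threshold
    return DiscriminationStudy(
        corpus=corpus,
        truth=truth,
        texts=texts,
        split=split,
        ensembles=ensembles,
        test_auroc=test_auroc,
        thresholds=thresholds,
    )


def leave_one_type_out_comparison(
    study: DiscriminationStudy,
    excluded_type: str,
    kind: str = "imaging",
    outcome: str = "progression",
) -> dict:
    """Retrain without one cancer type; evaluate both the all-type and the
    exclusion-trained ensemble on the excluded type's test documents."""
    spec = dataclasses.replace(study.ensembles[(kind, outcome)].spec)
    excl = train_excluding_cancer_type(
        study.corpus, study.texts, excluded_type, spec, study.split
    )
    docs = [
        d
        for d in study.corpus.documents
        if d.kind == kind
        and study.split.partition[d.patient_id] == "test"
        and study.corpus.patients[d.patient_id].cancer_type == excluded_type
    ]
    y = np.array([study.corpus.labels[d.doc_id].value(outcome) for d in docs])
    out = {}
    for name, ens in (("all_types", study.ensembles[(kind, outcome)]), ("excluded", excl)):
        preds = ensemble_predict(ens, docs, texts=study.texts)
        out[name] = auroc(np.array([p.score for p in preds]), y)
    return out


def score_cohort(
    study: DiscriminationStudy, corpus: Corpus, texts: dict, outcome: str
) -> dict:
    """doc_id -> ensemble probability for one outcome on a fresh cohort."""
    probs = {}
    for kind in ("imaging", "oncologist_note"):
        ens = study.ensembles[(kind, outcome)]
        docs = [d for d in corpus.documents if d.kind == kind]
        for p in ensemble_predict(ens, docs, texts):
            probs[p.doc_id] = p.probability
    return probs


def survival_association_study(
    study: DiscriminationStudy, seed: int, n_patients: int = 2000
) -> dict:
    """Score a fresh cohort with the trained ensembles, binarize at the
    frozen best-F1 thresholds, and fit the time-varying Cox models."""
    gen = GeneratorConfig(n_patients=n_patients, seed=seed)
    corpus, _ = simulate_cohort(gen)
    texts = prepare_model_texts(corpus)  # rules-based A/P extraction
    calls = {}
    for outcome in ("progression", "response"):
        probs = score_cohort(study, corpus, texts, outcome)
        by_doc = {d.doc_id: d for d in corpus.documents}
        calls[outcome] = {
            doc_id: int(p > study.thresholds[(by_doc[doc_id].kind, outcome)])
            for doc_id, p in probs.items()
        }
    results = {}
    for kind in ("imaging", "oncologist_note"):
        results[kind] = os_association_analysis(
            corpus, calls["progression"], calls["response"], kind
        )
    return results


def tmb_recovery_study(seed: int, n_patients: int = 2200, **generator_overrides):
    """Label-level TMB vs PFS-I-and-M recovery on ICI lines."""
    gen = GeneratorConfig(n_patients=n_patients, seed=seed, **generator_overrides)
    corpus, _ = simulate_cohort(gen, render_text=False)
    prog = {d: l.progression for d, l in corpus.labels.items()}
    resp = {d: l.response for d, l in corpus.labels.items()}
    return tmb_pfs_analysis(corpus, prog, resp)


def tmb_null_coverage(seed: int, n_replicates: int = 100, n_patients: int = 400) -> int:
    """Replicates with the ICI TMB multiplier at 1: count CIs covering 1."""
    covered = 0
    for r in range(n_replicates):
        res = tmb_recovery_study(
            seed * 100_003 + r,
            n_patients=n_patients,
            hr_tmb_high_progression_on_ici=1.0,
            cancer_type_weights=dict(REPLICATE_CANCER_WEIGHTS),
        )
        lo = res.hr_dichotomized.loc["tmb_high", "hr_lower"]
        hi = res.hr_dichotomized.loc["tmb_high", "hr_upper"]
        covered += int(lo <= 1.0 <= hi)
    return covered


def chain_type1_coverage(
    seed: int, n_replicates: int = 100, n_patients: int = 500, kind: str = "imaging"
) -> dict:
    """Null chain (all effect multipliers 1) from generator labels through
    counting process and Cox; counts replicates whose CIs cover 1."""
    covered = {"progressed_yet": 0, "responded_yet": 0}
    for r in range(n_replicates):
        gen = GeneratorConfig(
            n_patients=n_patients,
            seed=seed * 7_919 + r,
            hr_progression_death=1.0,
            hr_response_death=1.0,
            hr_tmb_high_progression_on_ici=1.0,
            cancer_type_weights=dict(REPLICATE_CANCER_WEIGHTS),
        )
        corpus, _ = simulate_cohort(gen, render_text=False)
        prog = {d: l.progression for d, l in corpus.labels.items()}
        resp = {d: l.response for d, l in corpus.labels.items()}
        res = os_association_analysis(corpus, prog, resp, kind)
        for cov in covered:
            covered[cov] += int(
                res.loc[cov, "hr_lower"] <= 1.0 <= res.loc[cov, "hr_upper"]
            )
    return covered


def copula_survival_pairs(rho: float, n: int, censoring_scale: float, rng) -> pd.DataFrame:
    """Bivariate exponential times linked by a normal copula with latent
    correlation ``rho``, independently right-censored."""
    from scipy.stats import norm

    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    t1 = -np.log(norm.sf(z[:, 0]))
    t2 = -np.log(norm.sf(z[:, 1]))
    c1 = rng.exponential(censoring_scale, n)
    c2 = rng.exponential(censoring_scale, n)
    return pd.DataFrame(
        {
            "pfs_time": np.minimum(t1, c1),
            "pfs_event": (t1 <= c1).astype(int),
            "os_time": np.minimum(t2, c2),
            "os_event": (t2 <= c2).astype(int),
        }
    )


def correlation_recovery(seed: int, rho: float, n: int = 1000,
                         censoring_scale: float = 1.5):
    """Point estimate and CI for one synthetic draw at latent ``rho``.

    ``censoring_scale`` = 1.5 yields roughly 40% censoring per margin for
    unit-mean exponential event times.
    """
    rng = np.random.default_rng(seed)
    pairs = copula_survival_pairs(rho, n, censoring_scale, rng)
    return survival_correlation(pairs)


def correlation_coverage(seed: int, rho: float = 0.5, n: int = 1000,
                         n_replicates: int = 100) -> int:
    covered = 0
    for r in range(n_replicates):
        est, (lo, hi) = correlation_recovery(seed * 65_537 + r, rho, n)
        covered += int(lo <= rho <= hi)
    return covered
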