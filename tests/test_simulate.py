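import numpy as np
import pytest

from oncotext.data_model import TMB_HIGH_CUTOFF
from oncotext.simulate import (
    GeneratorConfig,
    simulate_cohort,
    truth_timelines,
)
from oncotext.survival import build_counting_process, fit_cox_tv


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(n_patients=0)
    with pytest.raises(ValueError):
        GeneratorConfig(n_patients=10, label_noise=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(n_patients=10, cancer_type_weights={"breast": 0.4})


def test_zero_visit_rate_yields_no_documents():
    cfg = GeneratorConfig(
        n_patients=1, seed=0, visit_rate={"imaging": 0.0, "oncologist_note": 0.0}
    )
    corpus, _ = simulate_cohort(cfg)
    assert corpus.n_patients == 1
    assert corpus.documents == []


def test_same_seed_is_byte_identical():
    a, _ = simulate_cohort(GeneratorConfig(n_patients=40, seed=5))
    b, _ = simulate_cohort(GeneratorConfig(n_patients=40, seed=5))
    assert [(d.doc_id, d.date, d.text) for d in a.documents] == [
        (d.doc_id, d.date, d.text) for d in b.documents
    ]
    assert a.labels == b.labels


def test_noise_free_labels_match_latent_state(clean_small_corpus):
    corpus, truth = clean_small_corpus
    for doc in corpus.documents:
        lab = corpus.labels[doc.doc_id]
        traj = truth.trajectories[doc.patient_id]
        m = truth.doc_months[doc.doc_id]
        state, present = traj.at(m)
        assert lab.any_cancer == int(present)
        assert lab.progression == int(present and state == "progressing")
        assert lab.response == int(present and state == "responding")
        if doc.kind == "imaging":
            assert lab.sites == traj.sites_at(m)


def test_noisy_labels_respect_consistency_rules(small_corpus):
    corpus, _ = small_corpus
    for lab in corpus.labels.values():
        assert not (lab.progression and lab.response)
        if lab.progression or lab.response:
            assert lab.any_cancer == 1
        if lab.sites is not None and any(lab.sites.values()):
            assert lab.any_cancer == 1


def test_visit_rate_does_not_perturb_trajectories_or_survival():
    base = GeneratorConfig(n_patients=60, seed=123)
    dense = GeneratorConfig(
        n_patients=60, seed=123, visit_rate={"imaging": 1.5, "oncologist_note": 2.5}
    )
    _, t1 = simulate_cohort(base, render_text=False)
    _, t2 = simulate_cohort(dense, render_text=False)
    for pid in t1.trajectories:
        a, b = t1.trajectories[pid], t2.trajectories[pid]
        assert a.segments == b.segments
        assert a.death_month == b.death_month
        assert a.site_onsets == b.site_onsets


def test_tmb_high_fraction_matches_config(label_corpus):
    corpus, _ = label_corpus
    frac = np.mean([p.tmb >= TMB_HIGH_CUTOFF for p in corpus.patients.values()])
    n = corpus.n_patients
    target = GeneratorConfig().tmb_distribution.high_fraction
    se = np.sqrt(target * (1 - target) / n)
    assert abs(frac - target) < 4 * se


def test_site_onsets_monotone_and_document_dates_bounded(small_corpus):
    corpus, truth = small_corpus
    for doc in corpus.documents:
        pat = corpus.patients[doc.patient_id]
        if pat.death_date is not None:
            assert doc.date <= pat.death_date
        assert doc.date <= pat.last_contact_date
    for traj in truth.trajectories.values():
        for onset in traj.site_onsets.values():
            assert 0.0 <= onset <= traj.terminal_month + 1e-9


def test_true_progression_covariate_recovers_death_hazard_ratio():
    """Time-varying Cox on the exact latent first-progression times recovers
    the generator's progression->death multiplier of 2."""
    cfg = GeneratorConfig(n_patients=3000, seed=1)
    corpus, truth = simulate_cohort(cfg, render_text=False)
    tls = truth_timelines(corpus, truth)
    rows = build_counting_process(tls, corpus.patients, sources=("truth",))
    res = fit_cox_tv(rows, ["progressed_yet", "responded_yet", "cancer_type"])
    assert 1.8 <= res.loc["progressed_yet", "hr"] <= 2.2
    assert res.loc["responded_yet", "hr"] < 1.0
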