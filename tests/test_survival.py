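import datetime as dt

import numpy as np
import pandas as pd
import pytest

from oncotext.survival import (
    AnnotationEvent,
    PatientAnnotationTimeline,
    build_counting_process,
    derive_pfs,
    fit_cox_tv,
    km_estimate,
    survival_correlation,
    tmb_pfs_analysis,
)
from oncotext.simulate import GeneratorConfig, simulate_cohort
from oncotext.survival import PFS_VARIANTS, build_timelines, first_palliative_index_dates

D0 = dt.date(2016, 1, 1)


def _tl(events, death=None, censor=365, index=D0):
    return PatientAnnotationTimeline(
        patient_id="p",
        index_date=index,
        events=events,
        censor_date=index + dt.timedelta(days=censor),
        death_date=None if death is None else index + dt.timedelta(days=death),
    )


def _ev(day, source, outcome="progression"):
    return AnnotationEvent(D0 + dt.timedelta(days=day), source, outcome)


# ------------------------------------------------------------- PFS variants


def test_death_dominates_all_variants():
    tl = _tl([], death=100)
    for variant in PFS_VARIANTS:
        r = derive_pfs(tl, variant)
        assert (r.time, r.event) == (100.0, 1)


def test_single_source_progression():
    tl = _tl([_ev(30, "imaging")], censor=200)
    assert (derive_pfs(tl, "PFS_I").time, derive_pfs(tl, "PFS_I").event) == (30.0, 1)
    assert (derive_pfs(tl, "PFS_M").time, derive_pfs(tl, "PFS_M").event) == (200.0, 0)
    assert (derive_pfs(tl, "PFS_I_or_M").time, derive_pfs(tl, "PFS_I_or_M").event) == (30.0, 1)
    assert (derive_pfs(tl, "PFS_I_and_M").time, derive_pfs(tl, "PFS_I_and_M").event) == (200.0, 0)


def test_and_variant_takes_later_of_both_sources():
    tl = _tl([_ev(30, "imaging"), _ev(80, "note")], censor=200)
    assert derive_pfs(tl, "PFS_I_and_M").time == 80.0
    assert derive_pfs(tl, "PFS_I_or_M").time == 30.0


def test_events_before_index_are_ignored():
    tl = _tl([_ev(-10, "imaging")], censor=120)
    assert derive_pfs(tl, "PFS_I").event == 0


def test_index_after_death_is_an_error():
    with pytest.raises(ValueError, match="index date after death"):
        PatientAnnotationTimeline(
            patient_id="p", index_date=D0, events=[],
            censor_date=D0, death_date=D0 - dt.timedelta(days=2),
        )


def pfs_bruteforce(events, death_day, censor_day, variant):
    """Independent scan over the event set."""
    terminal = death_day if death_day is not None else censor_day
    img = sorted(d for d, s, o in events if s == "imaging" and o == "progression" and d >= 0)
    note = sorted(d for d, s, o in events if s == "note" and o == "progression" and d >= 0)
    if variant == "PFS_I":
        prog = img[0] if img else None
    elif variant == "PFS_M":
        prog = note[0] if note else None
    elif variant == "PFS_I_or_M":
        cand = ([img[0]] if img else []) + ([note[0]] if note else [])
        prog = min(cand) if cand else None
    else:
        prog = max(img[0], note[0]) if img and note else None
    if prog is not None and prog > terminal:
        prog = None
    cand = [c for c in (prog, death_day) if c is not None]
    if cand:
        return float(min(cand)), 1
    return float(censor_day), 0


@pytest.mark.parametrize("seed", range(4))
def test_pfs_variants_match_bruteforce_on_random_timelines(seed):
    rng = np.random.default_rng(seed)
    for _ in range(250):
        n_ev = rng.integers(0, 6)
        events = [
            (
                int(rng.integers(-30, 300)),
                rng.choice(["imaging", "note"]),
                rng.choice(["progression", "response"]),
            )
            for _ in range(n_ev)
        ]
        death = int(rng.integers(1, 400)) if rng.random() < 0.5 else None
        censor = int(rng.integers(1, 400)) if death is None else death
        tl = _tl([_ev(d, s, o) for d, s, o in events], death=death, censor=censor)
        prog_events = [(d, s, o) for d, s, o in events if o == "progression"]
        for variant in PFS_VARIANTS:
            got = derive_pfs(tl, variant)
            exp_t, exp_e = pfs_bruteforce(prog_events, death, censor, variant)
            assert (got.time, got.event) == (exp_t, exp_e)


def test_ordering_invariant_across_variants(label_corpus):
    corpus, _ = label_corpus
    prog = {d: l.progression for d, l in corpus.labels.items()}
    resp = {d: l.response for d, l in corpus.labels.items()}
    idx = first_palliative_index_dates(corpus)
    for tl in build_timelines(corpus, prog, resp, idx):
        res = {v: derive_pfs(tl, v) for v in PFS_VARIANTS}
        assert res["PFS_I_or_M"].time <= min(res["PFS_I"].time, res["PFS_M"].time)
        assert res["PFS_I_and_M"].time >= res["PFS_I_or_M"].time


# ------------------------------------------------------ counting process


def make_patient(pid="p", ngs_offset=-10, death=None, censor=365, cancer="breast"):
    from oncotext.data_model import PatientRecord, TreatmentLine

    return PatientRecord(
        patient_id=pid,
        cancer_type=cancer,
        sex="female",
        age_group="60-69",
        ngs_date=D0 + dt.timedelta(days=ngs_offset),
        tmb=5.0,
        death_date=None if death is None else D0 + dt.timedelta(days=death),
        last_contact_date=D0 + dt.timedelta(days=death if death is not None else censor),
        treatment_lines=[
            TreatmentLine(start_date=D0, intent="palliative", contains_ici=False,
                          line_number=1)
        ],
    )


def test_simple_death_no_annotations():
    pat = make_patient(death=50)
    tl = _tl([], death=50)
    rows = build_counting_process([tl], {"p": pat})
    assert len(rows) == 1
    r = rows.iloc[0]
    assert (r.start, r.stop, r.event, r.progressed_yet, r.responded_yet) == (
        0.0, 50.0, 1, 0, 0,
    )


def test_progression_cuts_interval():
    pat = make_patient(death=50)
    tl = _tl([_ev(20, "imaging")], death=50)
    rows = build_counting_process([tl], {"p": pat})
    assert [(r.start, r.stop, r.event, r.progressed_yet) for r in rows.itertuples()] == [
        (0.0, 20.0, 0, 0),
        (20.0, 50.0, 1, 1),
    ]


def test_left_truncation_delays_entry_and_drops_dead_before_ngs():
    pat = make_patient(ngs_offset=30, death=50)
    tl = _tl([], death=50)
    rows = build_counting_process([tl], {"p": pat})
    assert rows.iloc[0].start == 30.0
    pat2 = make_patient(ngs_offset=60, death=50)
    assert len(build_counting_process([_tl([], death=50)], {"p": pat2})) == 0


def test_at_risk_time_conserved_on_cohort(label_corpus):
    corpus, _ = label_corpus
    prog = {d: l.progression for d, l in corpus.labels.items()}
    resp = {d: l.response for d, l in corpus.labels.items()}
    idx = first_palliative_index_dates(corpus)
    tls = build_timelines(corpus, prog, resp, idx)
    rows = build_counting_process(tls, corpus.patients)
    follow = rows.groupby("patient_id").apply(
        lambda g: (g.stop - g.start).sum(), include_groups=False
    )
    events = rows.groupby("patient_id")["event"].sum()
    for tl in tls:
        pat = corpus.patients[tl.patient_id]
        expected = (tl.terminal_date - tl.index_date).days - max(
            0, (pat.ngs_date - tl.index_date).days
        )
        if expected <= 0:
            assert tl.patient_id not in follow.index
            continue
        assert follow[tl.patient_id] == expected
        assert events[tl.patient_id] == int(tl.death_date is not None)
    # covariates are absorbing within patient
    for _, g in rows.groupby("patient_id"):
        assert (g.progressed_yet.diff().dropna() >= 0).all()
        assert (g.responded_yet.diff().dropna() >= 0).all()


# -------------------------------------------------------------- Cox and KM


def test_cox_matches_two_sample_rate_ratio_in_exponential_limit():
    rng = np.random.default_rng(0)
    n = 4000
    x = rng.integers(0, 2, n)
    lam = 0.1 * np.exp(np.log(2.0) * x)
    t = rng.exponential(1 / lam)
    rows = pd.DataFrame(
        {"patient_id": [str(i) for i in range(n)], "start": 0.0, "stop": t,
         "event": 1, "x": x}
    )
    res = fit_cox_tv(rows, ["x"])
    mle_ratio = ((x == 1).sum() / t[x == 1].sum()) / ((x == 0).sum() / t[x == 0].sum())
    assert abs(res.loc["x", "hr"] - mle_ratio) / mle_ratio < 0.02


def test_cox_requires_events():
    rows = pd.DataFrame(
        {"patient_id": ["a", "b"], "start": [0.0, 0.0], "stop": [1.0, 2.0],
         "event": [0, 0], "x": [0, 1]}
    )
    with pytest.raises(ValueError, match="no events"):
        fit_cox_tv(rows, ["x"])


def test_km_no_events_flat_median_undefined():
    step, median = km_estimate([5, 6, 7], [0, 0, 0])
    assert np.allclose(step.survival, 1.0)
    assert np.isnan(median)


def test_km_distinct_events_drop_by_one_over_n():
    times = [1.0, 2.0, 3.0, 4.0]
    step, median = km_estimate(times, [1, 1, 1, 1])
    surv = step.set_index("time").survival
    assert np.allclose(surv.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0])
    assert median == 2.0


def km_bruteforce_delayed_entry(times, events, entries):
    """Risk-set recomputation at each event time with delayed entry."""
    times, events, entries = map(np.asarray, (times, events, entries))
    s = 1.0
    out = {}
    for t in sorted(set(times[events == 1])):
        at_risk = np.sum((entries < t) & (times >= t))
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / at_risk
        out[t] = s
    return out


def test_km_with_delayed_entry_matches_bruteforce():
    rng = np.random.default_rng(1)
    n = 200
    entries = rng.uniform(0, 2, n)
    times = entries + rng.exponential(3, n)
    events = rng.integers(0, 2, n)
    step, _ = km_estimate(times, events, entry=entries)
    expected = km_bruteforce_delayed_entry(times, events, entries)
    surv = step.set_index("time").survival
    for t, s in expected.items():
        assert np.isclose(surv.loc[t], s, atol=1e-10)


# ------------------------------------------------- censored correlation


def _copula_pairs(rho, n, cens_scale, rng):
    from scipy.stats import norm

    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    t1 = -np.log(norm.sf(z[:, 0]))
    t2 = -np.log(norm.sf(z[:, 1]))
    c1 = rng.exponential(cens_scale, n)
    c2 = rng.exponential(cens_scale, n)
    return pd.DataFrame(
        {
            "pfs_time": np.minimum(t1, c1),
            "pfs_event": (t1 <= c1).astype(int),
            "os_time": np.minimum(t2, c2),
            "os_event": (t2 <= c2).astype(int),
        }
    )


def test_identical_times_give_rho_near_one():
    rng = np.random.default_rng(0)
    t = rng.exponential(1, 500)
    pairs = pd.DataFrame(
        {"pfs_time": t, "pfs_event": 1, "os_time": t, "os_event": 1}
    )
    rho, _ = survival_correlation(pairs)
    assert rho > 0.99


def test_independent_pairs_ci_covers_zero():
    rng = np.random.default_rng(2)
    pairs = _copula_pairs(0.0, 400, 1.5, rng)
    rho, (lo, hi) = survival_correlation(pairs)
    assert lo < 0.0 < hi


def test_requires_events_and_enough_pairs():
    pairs = pd.DataFrame(
        {"pfs_time": [1.0] * 12, "pfs_event": [0] * 12,
         "os_time": [1.0] * 12, "os_event": [0] * 12}
    )
    with pytest.raises(ValueError):
        survival_correlation(pairs)
    with pytest.raises(ValueError, match="10 pairs"):
        survival_correlation(pairs.head(5))


# --------------------------------------------------------------- TMB design


def test_tmb_line_events_match_per_line_pfs(label_corpus):
    corpus, _ = label_corpus
    prog = {d: l.progression for d, l in corpus.labels.items()}
    resp = {d: l.response for d, l in corpus.labels.items()}
    res = tmb_pfs_analysis(corpus, prog, resp)
    events_by_patient = {}
    for d in corpus.documents:
        if prog.get(d.doc_id):
            src = "imaging" if d.kind == "imaging" else "note"
            events_by_patient.setdefault(d.patient_id, []).append(
                AnnotationEvent(d.date, src, "progression")
            )
    for row in res.line_table.itertuples():
        pat = corpus.patients[row.patient_id]
        line = next(
            t for t in pat.treatment_lines if t.line_number == row.line_number
        )
        tl = PatientAnnotationTimeline(
            patient_id=row.patient_id,
            index_date=line.start_date,
            events=events_by_patient.get(row.patient_id, []),
            censor_date=max(pat.last_contact_date, line.start_date),
            death_date=pat.death_date,
        )
        check = derive_pfs(tl, "PFS_I_and_M")
        assert row.pfs_event == check.event
        assert row.pfs_days == max(check.time, 0.5)


def test_tmb_requires_ici_lines(label_corpus):
    corpus, _ = label_corpus
    import dataclasses

    patients = {
        pid: dataclasses.replace(
            p,
            treatment_lines=[
                dataclasses.replace(t, contains_ici=False) for t in p.treatment_lines
            ],
        )
        for pid, p in corpus.patients.items()
    }
    stripped = dataclasses.replace(corpus, patients=patients, labels=corpus.labels)
    with pytest.raises(ValueError, match="ICI"):
        tmb_pfs_analysis(stripped, {}, {})
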