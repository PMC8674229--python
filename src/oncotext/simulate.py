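"""Synthetic clinico-genomic cohort generator.

Every downstream stage of the pipeline is exercised on data from this
module, which simulates, per patient:

* a latent disease trajectory — a continuous-time Markov process over
  ``{responding, stable, progressing}`` with treatment-modulated transition
  intensities, plus a "disease present" indicator (disease may clear while
  responding and later relapse) and per-site metastasis onset times;
* palliative/curative treatment lines, some containing an immune checkpoint
  inhibitor (ICI); during ICI lines the intensity into ``progressing`` is
  multiplied by ``hr_tmb_high_progression_on_ici`` for TMB-high patients;
* a death time drawn from a piecewise-constant hazard equal to
  ``death_hazard_base`` times ``hr_progression_death`` once the patient has
  ever progressed and times ``hr_response_death`` once the patient has ever
  responded (both effects absorbing and multiplicative, matching the
  downstream time-varying covariate encoding);
* observation times for imaging reports and oncologist notes (Poisson
  processes), template-rendered text, and document labels derived from the
  latent state at the document date, then flipped with probability
  ``label_noise`` to emulate annotator error.

Each patient consumes two independent random substreams derived from the
master seed: one for the trajectory (and all patient-level attributes), one
for observations (document times, text, label noise).  Changing the
observation process therefore never alters any patient's trajectory or
survival.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .data_model import (
    CANCER_TYPES,
    DAYS_PER_MONTH,
    METASTATIC_SITES,
    TMB_HIGH_CUTOFF,
    ClinicalDocument,
    Corpus,
    DocumentLabel,
    PatientRecord,
    TreatmentLine,
)
from . import lexicons

STATES = ("stable", "responding", "progressing")

#: Default cancer-type mix, loosely following the relative frequencies of
#: the thirteen solid-tumor types in a large academic precision-oncology
#: cohort (lung and breast most common, leiomyosarcoma rare).
DEFAULT_CANCER_WEIGHTS = {
    "breast": 0.15,
    "colorectal": 0.15,
    "endometrial": 0.04,
    "gastroesophageal": 0.07,
    "head_and_neck": 0.04,
    "leiomyosarcoma": 0.01,
    "nsclc": 0.22,
    "melanoma": 0.06,
    "ovarian": 0.06,
    "pancreatic": 0.06,
    "prostate": 0.05,
    "renal_cell": 0.04,
    "urothelial": 0.05,
}

DEFAULT_TRANSITION_RATES = {
    ("stable", "progressing"): 0.15,
    ("stable", "responding"): 0.10,
    ("responding", "stable"): 0.03,
    ("responding", "progressing"): 0.03,
    ("progressing", "stable"): 0.02,
    ("progressing", "responding"): 0.01,
}


@dataclass
class TmbMixture:
    """TMB (mutations/megabase) as a two-component mixture around the
    20 mut/Mb dichotomization cutoff."""

    high_fraction: float = 0.15
    low_log_mean: float = 1.8  # lognormal median ~6 mut/Mb
    low_log_sd: float = 0.5
    high_excess_scale: float = 15.0  # TMB-high = cutoff + Exponential(scale)


@dataclass
class GeneratorConfig:
    n_patients: int = 100
    seed: int = 0
    cancer_type_weights: dict = field(default_factory=lambda: dict(DEFAULT_CANCER_WEIGHTS))
    #: documents per month by kind
    visit_rate: dict = field(
        default_factory=lambda: {"imaging": 0.4, "oncologist_note": 0.8}
    )
    #: per-month intensities among latent states
    state_transition_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_TRANSITION_RATES)
    )
    #: for ``treatment_effect_duration_months`` after each line start,
    #: intensities into responding are multiplied by this factor and
    #: intensities into progressing divided by it
    treatment_effect: float = 2.0
    treatment_effect_duration_months: float = 6.0
    death_hazard_base: float = 0.015  # per month while never progressed/responded
    hr_progression_death: float = 2.0
    hr_response_death: float = 0.4
    tmb_distribution: TmbMixture = field(default_factory=TmbMixture)
    hr_tmb_high_progression_on_ici: float = 0.6
    label_noise: float = 0.05
    lexicon_overlap: float = 0.1
    # disease clearance/relapse (drives any-cancer-negative documents)
    clearance_rate: float = 1.0  # per month while responding with no metastatic sites
    relapse_rate: float = 0.03  # per month while disease absent
    # metastatic site onsets
    site_initial_prob: float = 0.05
    site_onset_rate: float = 0.005  # per site-month while disease present
    site_progression_multiplier: float = 6.0
    # treatment line structure: a next line starts only after progression,
    # following a restaging/washout delay
    ici_line_prob: float = 0.4
    switch_delay_min_months: float = 1.0
    switch_delay_mean_months: float = 4.0
    #: probability that the progression triggering a switch is captured by a
    #: dedicated restaging imaging report + oncologist note just before the
    #: new line starts
    restaging_doc_prob: float = 0.9
    max_lines: int = 3
    curative_first_line_prob: float = 0.1
    #: starting a new line re-baselines the disease assessment: a patient in
    #: the progressing state returns to stable at line start (absorbing
    #: death-hazard effects of past progression are unaffected)
    reset_state_at_line_start: bool = True
    # follow-up and calendar placement
    followup_months: float = 36.0
    diagnosis_start: str = "2013-01-01"
    diagnosis_end: str = "2019-06-30"
    study_end: str = "2021-01-31"

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        w = sum(self.cancer_type_weights.values())
        if abs(w - 1.0) > 1e-6:
            raise ValueError("cancer_type_weights must sum to 1")
        if set(self.cancer_type_weights) - set(CANCER_TYPES):
            raise ValueError("unknown cancer type in weights")
        for rate in self.state_transition_rates.values():
            if rate < 0:
                raise ValueError("transition rates must be >= 0")
        for p in (self.label_noise, self.lexicon_overlap, self.ici_line_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.death_hazard_base, self.hr_progression_death, self.hr_response_death) < 0:
            raise ValueError("hazard parameters must be >= 0")
        if isinstance(self.tmb_distribution, dict):
            self.tmb_distribution = TmbMixture(**self.tmb_distribution)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["state_transition_rates"] = {
            f"{a}->{b}": v for (a, b), v in self.state_transition_rates.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "state_transition_rates" in d and d["state_transition_rates"]:
            first_key = next(iter(d["state_transition_rates"]))
            if isinstance(first_key, str):
                d["state_transition_rates"] = {
                    tuple(k.split("->")): v for k, v in d["state_transition_rates"].items()
                }
        return cls(**d)


@dataclass
class TrajectoryState:
    """Latent ground truth for one patient (times in months from index)."""

    patient_id: str
    #: piecewise-constant path: list of (start_month, state, disease_present);
    #: right-continuous, effective until the next entry's start
    segments: list
    site_onsets: dict  # site -> onset month (absent if never)
    first_progression: Optional[float]
    first_response: Optional[float]
    death_month: Optional[float]
    censor_month: float

    def at(self, t: float) -> tuple[str, bool]:
        """(state, disease_present) effective at month ``t``."""
        state, present = self.segments[0][1], self.segments[0][2]
        for start, s, p in self.segments:
            if start <= t:
                state, present = s, p
            else:
                break
        return state, present

    def sites_at(self, t: float) -> dict[str, int]:
        return {s: int(self.site_onsets.get(s, np.inf) <= t) for s in METASTATIC_SITES}

    @property
    def terminal_month(self) -> float:
        return self.death_month if self.death_month is not None else self.censor_month


@dataclass
class SimulationTruth:
    trajectories: dict  # patient_id -> TrajectoryState
    true_labels: dict  # doc_id -> DocumentLabel (before annotation noise)
    ap_text: dict  # doc_id -> ground-truth assessment/plan text (notes only)
    doc_months: dict  # doc_id -> months from index


def _true_label(doc_id, traj: TrajectoryState, month: float, kind: str) -> DocumentLabel:
    state, present = traj.at(month)
    return DocumentLabel(
        doc_id=doc_id,
        any_cancer=int(present),
        progression=int(present and state == "progressing"),
        response=int(present and state == "responding"),
        sites=traj.sites_at(month) if kind == "imaging" else None,
    )


def _apply_label_noise(label: DocumentLabel, noise: float, rng) -> DocumentLabel:
    """Flip labels independently with probability ``noise`` while preserving
    the PRISSMM consistency rules (any positive flag implies any-cancer;
    progression and response never both set)."""
    if noise <= 0:
        return label
    any_cancer = label.any_cancer ^ int(rng.random() < noise)
    if not any_cancer:
        prog = resp = 0
        sites = None if label.sites is None else {s: 0 for s in label.sites}
    else:
        prog = label.progression ^ int(rng.random() < noise)
        resp = label.response ^ int(rng.random() < noise)
        if prog and resp:
            # a noise flip produced an impossible pair; revert the flipped one
            if label.progression == 0:
                prog = 0
            else:
                resp = 0
        sites = None
        if label.sites is not None:
            sites = {
                s: v ^ int(rng.random() < noise) for s, v in label.sites.items()
            }
    return DocumentLabel(
        doc_id=label.doc_id,
        any_cancer=any_cancer,
        progression=prog,
        response=resp,
        sites=sites,
    )


def _outcome_category(state: str, present: bool) -> str:
    if not present:
        return "no_cancer"
    if state == "progressing":
        return "progression"
    if state == "responding":
        return "response"
    return "stable"


def _distractor_sentence(category: str, rng) -> str:
    # a cue phrase from a *different* outcome's bank, in historical context
    other = "response" if category == "progression" else "progression"
    phrase = lexicons.outcome_phrase_bank(other)[
        rng.integers(len(lexicons.outcome_phrase_bank(other)))
    ]
    wrapper = lexicons.DISTRACTOR_WRAPPERS[rng.integers(len(lexicons.DISTRACTOR_WRAPPERS))]
    return wrapper.format(phrase=phrase)


def _pick(bank, rng) -> str:
    return bank[rng.integers(len(bank))]


def _pad_to_min_tokens(sentences: list[str], rng, minimum: int = 50) -> list[str]:
    def count():
        return sum(len(s.split()) for s in sentences)

    while count() < minimum:
        sentences.append(_pick(lexicons.NOTE_FILLER, rng))
    return sentences


def render_document(
    state: str,
    present: bool,
    sites: dict[str, int],
    kind: str,
    cancer_type: str,
    rng,
    lexicon_overlap: float = 0.0,
) -> tuple[str, str]:
    """Render one document; returns ``(text, assessment_plan_truth)``.

    For imaging reports the outcome-bearing sentences live in the
    findings/impression sections; for oncologist notes they live in a
    header-delimited assessment/plan section preceded by boilerplate that
    may contain historical distractor phrases with probability
    ``lexicon_overlap``.  The assessment/plan ground truth is returned for
    notes (empty string for imaging).
    """
    category = _outcome_category(state, present)
    cancer_name = cancer_type.replace("_", " ")
    distract = rng.random() < lexicon_overlap

    if kind == "imaging":
        history = [f"HISTORY: {cancer_name} cancer, status post systemic therapy."]
        if distract:
            history.append(_distractor_sentence(category, rng))
        findings = []
        for site, flag in sites.items():
            if flag:
                findings.append(lexicons.SITE_PHRASES[site] + ".")
        n_filler = int(rng.integers(3, 6))
        for _ in range(n_filler):
            findings.append(_pick(lexicons.IMAGING_FILLER, rng))
        impression = _pick(lexicons.outcome_phrase_bank(category), rng)
        parts = [
            f"EXAM: {_pick(lexicons.IMAGING_EXAMS, rng)}.",
            " ".join(history),
            "COMPARISON: comparison made with the prior cross sectional study.",
            "FINDINGS: " + " ".join(findings),
            f"IMPRESSION: {impression}.",
        ]
        text = "\n".join(parts)
        words = text.split()
        if len(words) < 50:
            parts[3] += " " + " ".join(
                _pick(lexicons.IMAGING_FILLER, rng) for _ in range(3)
            )
            text = "\n".join(parts)
        return text, ""

    # oncologist note
    interval = [_pick(lexicons.NOTE_FILLER, rng) for _ in range(int(rng.integers(2, 5)))]
    if distract:
        interval.insert(int(rng.integers(len(interval) + 1)), _distractor_sentence(category, rng))
    exam = [_pick(lexicons.NOTE_FILLER, rng) for _ in range(int(rng.integers(1, 3)))]
    labs = [_pick(lexicons.NOTE_FILLER, rng)]
    ap_header = _pick(lexicons.AP_HEADERS, rng).upper()
    ap_sentences = [
        _pick(lexicons.outcome_phrase_bank(category), rng) + ".",
        _pick(lexicons.PLAN_PHRASES, rng) + ".",
    ]
    ap_text = " ".join(ap_sentences)
    parts = [
        f"CHIEF COMPLAINT: follow up of {cancer_name} cancer.",
        "INTERVAL HISTORY: " + " ".join(_pad_to_min_tokens(interval, rng, 25)),
        "PHYSICAL EXAM: " + " ".join(exam),
        "LABS: " + " ".join(labs),
        f"{ap_header}: {ap_text}",
    ]
    if rng.random() < 0.3:
        parts.append("FOLLOW UP: return to clinic in three weeks.")
    text = "\n".join(parts)
    if len(text.split()) < 50:
        parts[1] += " " + " ".join(_pick(lexicons.NOTE_FILLER, rng) for _ in range(4))
        text = "\n".join(parts)
    return text, ap_text


def _simulate_trajectory(pid: str, cfg: GeneratorConfig, rng, tmb_high: bool,
                         intents, ici_flags, censor_month: float):
    """Event-driven simulation of the latent process for one patient.

    Treatment switching is progression-triggered: when the disease starts
    progressing while a next line remains available, the next line begins
    after a short restaging delay, re-baselining the assessment (the
    progressing state returns to stable at line start).  The active line's
    ICI flag governs the TMB modulation of intensities into progressing.

    Returns ``(TrajectoryState, line_start_months)``.
    """
    te_dur = cfg.treatment_effect_duration_months
    line_starts = [0.0]
    pending_start: Optional[float] = None

    def schedule_switch(now: float):
        nonlocal pending_start
        if pending_start is None and len(line_starts) < len(intents):
            delay = cfg.switch_delay_min_months + rng.exponential(
                max(cfg.switch_delay_mean_months - cfg.switch_delay_min_months, 0.1)
            )
            pending_start = now + delay

    state = "stable"
    present = True
    sites = {s: 0.0 for s in METASTATIC_SITES if rng.random() < cfg.site_initial_prob}
    ever_prog: Optional[float] = None
    ever_resp: Optional[float] = None
    segments = [(0.0, state, present)]
    death: Optional[float] = None
    t = 0.0

    while t < censor_month:
        # assemble active transition rates at time t
        rates: list[tuple[str, object, float]] = []
        current_line_start = line_starts[-1]
        tw = current_line_start <= t < current_line_start + te_dur
        ici_tmb = tmb_high and bool(ici_flags[len(line_starts) - 1])
        if present:
            for (a, b), r in cfg.state_transition_rates.items():
                if a != state or r <= 0:
                    continue
                if tw:
                    if b == "responding":
                        r *= cfg.treatment_effect
                    elif b == "progressing":
                        r /= cfg.treatment_effect
                if b == "progressing" and ici_tmb:
                    r *= cfg.hr_tmb_high_progression_on_ici
                rates.append(("jump", b, r))
            if state == "responding" and not sites and cfg.clearance_rate > 0:
                rates.append(("clear", None, cfg.clearance_rate))
            for s in METASTATIC_SITES:
                if s not in sites:
                    r = cfg.site_onset_rate
                    if state == "progressing":
                        r *= cfg.site_progression_multiplier
                    if r > 0:
                        rates.append(("site", s, r))
        else:
            if cfg.relapse_rate > 0:
                r = cfg.relapse_rate
                if ici_tmb:
                    r *= cfg.hr_tmb_high_progression_on_ici
                rates.append(("relapse", None, r))
        hazard = cfg.death_hazard_base
        if ever_prog is not None:
            hazard *= cfg.hr_progression_death
        if ever_resp is not None:
            hazard *= cfg.hr_response_death
        if hazard > 0:
            rates.append(("death", None, hazard))

        total = sum(r for _, _, r in rates)
        # next deterministic rate change: treatment window close, a pending
        # line start, or administrative censoring
        break_candidates = [censor_month]
        if t < current_line_start + te_dur:
            break_candidates.append(current_line_start + te_dur)
        if pending_start is not None and pending_start > t:
            break_candidates.append(pending_start)
        next_break = min(b for b in break_candidates if b > t)
        if total <= 0 or t + (wait := rng.exponential(1.0 / total)) >= next_break:
            t = next_break
            if pending_start is not None and t >= pending_start and t < censor_month:
                line_starts.append(t)
                pending_start = None
                if cfg.reset_state_at_line_start and present and state == "progressing":
                    state = "stable"
                    segments.append((t, state, present))
            continue
        t = t + wait
        u = rng.random() * total
        acc = 0.0
        for kind_, target, r in rates:
            acc += r
            if u <= acc:
                break
        if kind_ == "death":
            death = t
            break
        if kind_ == "jump":
            state = target  # type: ignore[assignment]
            if state == "progressing":
                if ever_prog is None:
                    ever_prog = t
                schedule_switch(t)
            if state == "responding" and ever_resp is None:
                ever_resp = t
            segments.append((t, state, present))
        elif kind_ == "clear":
            present = False
            state = "stable"
            segments.append((t, state, present))
        elif kind_ == "relapse":
            present = True
            state = "progressing"
            if ever_prog is None:
                ever_prog = t
            schedule_switch(t)
            segments.append((t, state, present))
        elif kind_ == "site":
            sites[target] = t  # type: ignore[index]

    traj = TrajectoryState(
        patient_id=pid,
        segments=segments,
        site_onsets=dict(sites),
        first_progression=ever_prog,
        first_response=ever_resp,
        death_month=death,
        censor_month=censor_month,
    )
    return traj, line_starts


def _draw_tmb(mix: TmbMixture, rng) -> float:
    if rng.random() < mix.high_fraction:
        return TMB_HIGH_CUTOFF + rng.exponential(mix.high_excess_scale)
    for _ in range(100):
        v = float(np.exp(rng.normal(mix.low_log_mean, mix.low_log_sd)))
        if v < TMB_HIGH_CUTOFF:
            return v
    return TMB_HIGH_CUTOFF * 0.5


def simulate_cohort(
    config: GeneratorConfig, render_text: bool = True
) -> tuple[Corpus, SimulationTruth]:
    """Simulate the full cohort; deterministic given ``config.seed``.

    With ``render_text=False`` the documents carry a one-token placeholder
    text; trajectories, dates and labels are identical to a rendered run
    (rendering draws from a dedicated substream), which keeps label-level
    analyses fast.
    """
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.n_patients)

    diag_start = _dt.date.fromisoformat(cfg.diagnosis_start)
    diag_end = _dt.date.fromisoformat(cfg.diagnosis_end)
    study_end = _dt.date.fromisoformat(cfg.study_end)
    diag_span = (diag_end - diag_start).days

    cancer_names = list(cfg.cancer_type_weights)
    cancer_probs = np.array([cfg.cancer_type_weights[c] for c in cancer_names])
    cancer_probs = cancer_probs / cancer_probs.sum()

    patients: dict[str, PatientRecord] = {}
    documents: list[ClinicalDocument] = []
    labels: dict[str, DocumentLabel] = {}
    trajectories: dict[str, TrajectoryState] = {}
    true_labels: dict[str, DocumentLabel] = {}
    ap_text: dict[str, str] = {}
    doc_months: dict[str, float] = {}

    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        traj_ss, obs_ss = children[i].spawn(3)[:2]
        traj_rng = np.random.default_rng(traj_ss)
        obs_rng = np.random.default_rng(obs_ss)

        cancer_type = cancer_names[traj_rng.choice(len(cancer_names), p=cancer_probs)]
        sex = "female" if traj_rng.random() < 0.55 else "male"
        age_group = ("<50", "50-59", "60-69", "70+")[traj_rng.choice(4, p=[0.15, 0.25, 0.35, 0.25])]
        tmb = _draw_tmb(cfg.tmb_distribution, traj_rng)
        tmb_high = tmb >= TMB_HIGH_CUTOFF

        diagnosis_date = diag_start + _dt.timedelta(
            days=int(traj_rng.integers(0, diag_span + 1))
        )
        max_follow = min(
            cfg.followup_months, (study_end - diagnosis_date).days / DAYS_PER_MONTH
        )

        # candidate treatment lines: line 1 at month 0; later lines start
        # only when triggered by progression inside the trajectory
        intents = ["palliative"] * cfg.max_lines
        if traj_rng.random() < cfg.curative_first_line_prob:
            intents[0] = "curative"
        ici_flags = [
            intent == "palliative" and traj_rng.random() < cfg.ici_line_prob
            for intent in intents
        ]

        traj, line_starts = _simulate_trajectory(
            pid, cfg, traj_rng, tmb_high, intents, ici_flags, max_follow
        )
        trajectories[pid] = traj
        terminal = traj.terminal_month

        ngs_month = float(traj_rng.uniform(-3.0, 6.0))
        ngs_month = min(ngs_month, terminal)

        death_day = (
            None
            if traj.death_month is None
            else int(round(traj.death_month * DAYS_PER_MONTH))
        )
        terminal_day = (
            death_day
            if death_day is not None
            else int(round(traj.censor_month * DAYS_PER_MONTH))
        )

        lines = [
            TreatmentLine(
                start_date=diagnosis_date
                + _dt.timedelta(days=min(int(round(s * DAYS_PER_MONTH)), terminal_day)),
                intent=intent,
                contains_ici=ici,
                line_number=k + 1,
            )
            for k, (s, intent, ici) in enumerate(zip(line_starts, intents, ici_flags))
            if s <= terminal
        ]

        patients[pid] = PatientRecord(
            patient_id=pid,
            cancer_type=cancer_type,
            sex=sex,
            age_group=age_group,
            ngs_date=diagnosis_date
            + _dt.timedelta(days=int(round(ngs_month * DAYS_PER_MONTH))),
            tmb=tmb,
            death_date=None
            if death_day is None
            else diagnosis_date + _dt.timedelta(days=death_day),
            last_contact_date=diagnosis_date + _dt.timedelta(days=terminal_day),
            treatment_lines=lines,
        )

        # restaging documents: a treatment switch is triggered by documented
        # progression, so each later line start is preceded by an imaging
        # report and an oncologist note dated shortly before the switch
        restaging: dict[str, list[float]] = {"imaging": [], "oncologist_note": []}
        for prev_s, s in zip(line_starts[:-1], line_starts[1:]):
            if obs_rng.random() < cfg.restaging_doc_prob:
                img_m = s - float(obs_rng.uniform(0.3, 1.2))
                note_m = s - float(obs_rng.uniform(0.05, 0.3))
                lo = prev_s + 0.05
                restaging["imaging"].append(min(max(img_m, lo), terminal))
                restaging["oncologist_note"].append(min(max(note_m, lo), terminal))

        # observation process: document times per kind, then labels and text
        for kind in ("imaging", "oncologist_note"):
            rate = cfg.visit_rate.get(kind, 0.0)
            if rate <= 0 or terminal <= 0:
                continue
            n_docs = obs_rng.poisson(rate * terminal)
            months = np.sort(
                np.concatenate(
                    [obs_rng.uniform(0.0, terminal, size=n_docs), restaging[kind]]
                )
            )
            for j, m in enumerate(months):
                doc_id = f"{pid}-{'img' if kind == 'imaging' else 'note'}-{j:03d}"
                day = min(int(m * DAYS_PER_MONTH), terminal_day)
                state, present = traj.at(m)
                sites = traj.sites_at(m)
                truth = _true_label(doc_id, traj, m, kind)
                observed = _apply_label_noise(truth, cfg.label_noise, obs_rng)
                if render_text:
                    text, ap = render_document(
                        state,
                        present,
                        sites if kind == "imaging" else {},
                        kind,
                        cancer_type,
                        obs_rng,
                        cfg.lexicon_overlap,
                    )
                else:
                    text, ap = "[unrendered]", ""
                documents.append(
                    ClinicalDocument(
                        doc_id=doc_id,
                        patient_id=pid,
                        date=diagnosis_date + _dt.timedelta(days=day),
                        kind=kind,
                        text=text,
                    )
                )
                labels[doc_id] = observed
                true_labels[doc_id] = truth
                doc_months[doc_id] = float(m)
                if kind == "oncologist_note":
                    ap_text[doc_id] = ap

    corpus = Corpus(patients=patients, documents=documents, labels=labels)
    truth = SimulationTruth(
        trajectories=trajectories,
        true_labels=true_labels,
        ap_text=ap_text,
        doc_months=doc_months,
    )
    return corpus, truth


def truth_timelines(corpus: Corpus, truth: SimulationTruth, index_dates=None):
    """Annotation timelines built from the exact latent first-progression /
    first-response times (source tag ``truth``), for parameter-recovery
    oracles that bypass the document observation process."""
    from .survival import AnnotationEvent, PatientAnnotationTimeline

    if index_dates is None:
        from .survival import first_palliative_index_dates

        index_dates = first_palliative_index_dates(corpus)
    timelines = []
    for pid, idx in index_dates.items():
        pat = corpus.patients[pid]
        traj = truth.trajectories[pid]
        origin = pat.treatment_lines[0].start_date  # month 0 of the simulation
        events = []
        for month, outcome in (
            (traj.first_progression, "progression"),
            (traj.first_response, "response"),
        ):
            if month is not None:
                events.append(
                    AnnotationEvent(
                        origin + _dt.timedelta(days=int(round(month * DAYS_PER_MONTH))),
                        "truth",
                        outcome,
                    )
                )
        timelines.append(
            PatientAnnotationTimeline(
                patient_id=pid,
                index_date=idx,
                events=events,
                censor_date=max(pat.last_contact_date, idx),
                death_date=pat.death_date,
            )
        )
    return timelines
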