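"""Patient-level time-to-event endpoints and survival analyses.

Per-document binary progression/response calls become patient timelines;
timelines become

* progression-free survival (PFS) variants — PFS-I (imaging), PFS-M
  (oncologist note), PFS-I-or-M (either source), PFS-I-and-M (both sources
  must have documented progression), each composited with death;
* counting-process rows ``(start, stop]`` with absorbing time-varying
  covariates (``progressed_yet``, ``responded_yet``) and delayed entry at
  genomic testing (left truncation: person-time before NGS is not at risk,
  since cohort eligibility requires testing);
* Cox proportional-hazards fits on start-stop data (Efron ties, optional
  clustered robust variance for patients contributing several treatment
  lines), Kaplan-Meier estimates honoring delayed entry, and a censored
  bivariate correlation between PFS and OS based on a Gaussian copula over
  normal scores with censored-pair likelihood contributions.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import optimize, stats

from .data_model import TMB_HIGH_CUTOFF, Corpus, PatientRecord

logger = logging.getLogger(__name__)

PFS_VARIANTS = ("PFS_I", "PFS_M", "PFS_I_or_M", "PFS_I_and_M")

COUNTING_COLUMNS = (
    "patient_id",
    "start",
    "stop",
    "event",
    "progressed_yet",
    "responded_yet",
    "cancer_type",
)


@dataclass(frozen=True)
class AnnotationEvent:
    date: _dt.date
    source: str  # imaging | note
    outcome: str  # progression | response


@dataclass
class PatientAnnotationTimeline:
    """Binary outcome calls over time for one patient, anchored at an index
    treatment start."""

    patient_id: str
    index_date: _dt.date
    events: list  # AnnotationEvent, sorted by date
    censor_date: _dt.date
    death_date: Optional[_dt.date] = None

    def __post_init__(self):
        if self.death_date is not None and self.index_date > self.death_date:
            raise ValueError(
                f"patient {self.patient_id}: index date after death"
            )
        if self.censor_date < self.index_date:
            raise ValueError(
                f"patient {self.patient_id}: censor date before index"
            )
        self.events = sorted(self.events, key=lambda e: e.date)
        n_before = sum(1 for e in self.events if e.date < self.index_date)
        if n_before:
            logger.debug(
                "patient %s: ignoring %d events dated before index",
                self.patient_id,
                n_before,
            )

    def _first(self, outcome: str, sources) -> Optional[_dt.date]:
        for e in self.events:
            if e.outcome == outcome and e.source in sources and e.date >= self.index_date:
                return e.date
        return None

    @property
    def terminal_date(self) -> _dt.date:
        return self.death_date if self.death_date is not None else self.censor_date


@dataclass(frozen=True)
class PfsResult:
    patient_id: str
    variant: str
    time: float  # days from index
    event: int


def derive_pfs(timeline: PatientAnnotationTimeline, variant: str) -> PfsResult:
    """Time to the variant's defining progression event or death, else
    censoring.  For PFS-I-and-M the defining time is the *later* of the
    first imaging and first note progression (both must have occurred)."""
    if variant not in PFS_VARIANTS:
        raise ValueError(f"unknown PFS variant {variant!r}")
    idx = timeline.index_date
    first_i = timeline._first("progression", ("imaging",))
    first_m = timeline._first("progression", ("note",))
    if variant == "PFS_I":
        prog = first_i
    elif variant == "PFS_M":
        prog = first_m
    elif variant == "PFS_I_or_M":
        dates = [d for d in (first_i, first_m) if d is not None]
        prog = min(dates) if dates else None
    else:  # PFS_I_and_M
        prog = max(first_i, first_m) if first_i is not None and first_m is not None else None
    candidates = []
    if prog is not None and prog <= timeline.terminal_date:
        candidates.append(prog)
    if timeline.death_date is not None:
        candidates.append(timeline.death_date)
    if candidates:
        t = min(candidates)
        return PfsResult(timeline.patient_id, variant, float((t - idx).days), 1)
    return PfsResult(
        timeline.patient_id, variant, float((timeline.censor_date - idx).days), 0
    )


def derive_all_pfs(timelines) -> pd.DataFrame:
    rows = []
    for tl in timelines:
        for variant in PFS_VARIANTS:
            r = derive_pfs(tl, variant)
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "variant": r.variant,
                    "time_days": r.time,
                    "event": r.event,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# counting-process construction


def build_counting_process(
    timelines, patients: dict[str, PatientRecord], sources=("imaging", "note")
) -> pd.DataFrame:
    """(start, stop] rows with absorbing covariates, entry at genomic testing.

    Patients whose NGS date is on/after their terminal date contribute no
    at-risk time.  Covariate change points are the first binarized
    progression and first response from the given sources.
    """
    rows = []
    for tl in timelines:
        pat = patients[tl.patient_id]
        idx = tl.index_date
        terminal = float((tl.terminal_date - idx).days)
        entry = max(0.0, float((pat.ngs_date - idx).days))
        if terminal <= entry:
            continue
        first_prog = tl._first("progression", sources)
        first_resp = tl._first("response", sources)
        cp = None if first_prog is None else float((first_prog - idx).days)
        cr = None if first_resp is None else float((first_resp - idx).days)
        cuts = sorted(
            {c for c in (cp, cr) if c is not None and entry < c < terminal}
        )
        bounds = [entry] + cuts + [terminal]
        died = tl.death_date is not None
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b <= a:
                continue
            rows.append(
                {
                    "patient_id": tl.patient_id,
                    "start": a,
                    "stop": b,
                    "event": int(died and b == terminal),
                    "progressed_yet": int(cp is not None and cp <= a),
                    "responded_yet": int(cr is not None and cr <= a),
                    "cancer_type": pat.cancer_type,
                }
            )
    df = pd.DataFrame(rows, columns=COUNTING_COLUMNS)
    if len(df):
        assert (df["stop"] > df["start"]).all()
    return df


# ---------------------------------------------------------------------------
# model fits


def _design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design columns; categorical covariates expand to dummies
    (first level dropped)."""
    out = {}
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            for c in dummies:
                out[c] = dummies[c].astype(float)
        else:
            out[cov] = col.astype(float)
    return pd.DataFrame(out, index=df.index)


def fit_cox_tv(
    rows: pd.DataFrame,
    covariates,
    cluster: Optional[str] = None,
    start_col: str = "start",
    stop_col: str = "stop",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox partial-likelihood fit on start-stop rows (Andersen-Gill form:
    each row is a subject with delayed entry at ``start``).  Efron ties.
    With ``cluster`` set, a robust sandwich variance groups rows by that
    column.  Returns one row per design column with HR and 95% CI."""
    if rows[event_col].sum() < 1:
        raise ValueError("no events in counting-process data")
    X = _design(rows, covariates)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=constant)
    df = pd.concat(
        [rows[[start_col, stop_col, event_col]].reset_index(drop=True),
         X.reset_index(drop=True)],
        axis=1,
    )
    kwargs = {}
    if cluster is not None:
        df["_cluster"] = rows[cluster].values
        kwargs = {"cluster_col": "_cluster"}
    cph = CoxPHFitter()
    try:
        cph.fit(
            df,
            duration_col=stop_col,
            entry_col=start_col,
            event_col=event_col,
            robust=cluster is not None,
            **kwargs,
        )
    except Exception as exc:  # lifelines raises various convergence errors
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    summary = cph.summary
    out = pd.DataFrame(
        {
            "covariate": summary.index,
            "coef": summary["coef"].values,
            "se": summary["se(coef)"].values,
            "hr": summary["exp(coef)"].values,
            "hr_lower": summary["exp(coef) lower 95%"].values,
            "hr_upper": summary["exp(coef) upper 95%"].values,
            "p": summary["p"].values,
        }
    ).set_index("covariate")
    out.attrs["n_events"] = int(rows[event_col].sum())
    out.attrs["n_rows"] = len(rows)
    return out


def km_estimate(times, events, entry=None):
    """Product-limit estimator with optional delayed entry.

    Returns ``(step_df, median)`` where ``step_df`` has columns
    ``time``/``survival`` and ``median`` is the earliest time at which
    survival drops to <= 0.5 (NaN if never reached)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int),
            entry=None if entry is None else np.asarray(entry, dtype=float))
    sf = kmf.survival_function_
    step = pd.DataFrame({"time": sf.index.values, "survival": sf.iloc[:, 0].values})
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = float("nan")
    return step, median


# ---------------------------------------------------------------------------
# censored bivariate correlation (Gaussian copula over normal scores)


def _normal_scores(times, events):
    """Latent-normal scores per observation from the KM margin.

    Events map to the probit of the midpoint of the KM jump (reducing the
    bias of plugging in a discontinuous F); censored observations map to
    the probit of F(t), a lower bound on the latent score."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    grid = sf.index.values
    surv = sf.iloc[:, 0].values

    def s_at(t):
        i = np.searchsorted(grid, t, side="right") - 1
        return surv[max(i, 0)]

    def s_before(t):
        i = np.searchsorted(grid, t, side="left") - 1
        return surv[i] if i >= 0 else 1.0

    n = len(times)
    eps = 0.5 / n
    z = np.empty(n)
    for i, (t, d) in enumerate(zip(times, events)):
        if d:
            f = 1.0 - 0.5 * (s_at(t) + s_before(t))
        else:
            f = 1.0 - s_at(t)
        z[i] = stats.norm.ppf(np.clip(f, eps, 1.0 - eps))
    return z


def survival_correlation(pairs: pd.DataFrame, alpha: float = 0.05):
    """Correlation between two possibly right-censored times.

    ``pairs`` needs columns ``pfs_time, pfs_event, os_time, os_event``.
    A latent bivariate normal links the normal scores of the two margins;
    censored coordinates contribute tail probabilities to the likelihood.
    The CI is computed on Fisher's z scale from the observed information.

    Returns ``(rho, (lower, upper))``.
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs")
    dx = pairs["pfs_event"].to_numpy(dtype=int)
    dy = pairs["os_event"].to_numpy(dtype=int)
    if dx.sum() == 0 or dy.sum() == 0:
        raise ValueError("need events on both axes")
    a = _normal_scores(pairs["pfs_time"], dx)
    b = _normal_scores(pairs["os_time"], dy)

    both = (dx == 1) & (dy == 1)
    x_only = (dx == 1) & (dy == 0)
    y_only = (dx == 0) & (dy == 1)
    neither = (dx == 0) & (dy == 0)

    def negloglik_z(z):
        rho = np.tanh(z)
        r2 = 1.0 - rho**2
        ll = 0.0
        if both.any():
            aa, bb = a[both], b[both]
            ll += np.sum(
                -0.5 * np.log(r2)
                - (rho**2 * (aa**2 + bb**2) - 2 * rho * aa * bb) / (2 * r2)
            )
        if x_only.any():
            cond = (b[x_only] - rho * a[x_only]) / np.sqrt(r2)
            ll += np.sum(stats.norm.logsf(cond))
        if y_only.any():
            cond = (a[y_only] - rho * b[y_only]) / np.sqrt(r2)
            ll += np.sum(stats.norm.logsf(cond))
        if neither.any():
            aa, bb = a[neither], b[neither]
            mvn = stats.multivariate_normal(
                mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
            )
            joint = mvn.cdf(np.column_stack([aa, bb]))
            p = 1.0 - stats.norm.cdf(aa) - stats.norm.cdf(bb) + np.atleast_1d(joint)
            ll += np.sum(np.log(np.clip(p, 1e-300, None)))
        return -ll

    res = optimize.minimize_scalar(
        negloglik_z, bounds=(-4.0, 4.0), method="bounded",
        options={"xatol": 1e-5},
    )
    z_hat = float(res.x)
    h = 0.02
    d2 = (negloglik_z(z_hat + h) - 2 * negloglik_z(z_hat) + negloglik_z(z_hat - h)) / h**2
    se_z = 1.0 / np.sqrt(max(d2, 1e-12))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    rho = float(np.tanh(z_hat))
    ci = (float(np.tanh(z_hat - zcrit * se_z)), float(np.tanh(z_hat + zcrit * se_z)))
    return rho, ci


# ---------------------------------------------------------------------------
# document calls -> timelines, and the composite analyses


def binarize_predictions(predictions, threshold: float) -> dict[str, int]:
    """doc_id -> 0/1 call at a probability threshold."""
    return {p.doc_id: int(p.probability > threshold) for p in predictions}


def build_timelines(
    corpus: Corpus,
    prog_calls: dict[str, int],
    resp_calls: dict[str, int],
    index_dates: dict[str, _dt.date],
) -> list[PatientAnnotationTimeline]:
    """One timeline per patient in ``index_dates``; events are the documents
    whose binarized progression/response call is positive."""
    events_by_patient: dict[str, list[AnnotationEvent]] = {
        pid: [] for pid in index_dates
    }
    for d in corpus.documents:
        if d.patient_id not in events_by_patient:
            continue
        source = "imaging" if d.kind == "imaging" else "note"
        if prog_calls.get(d.doc_id):
            events_by_patient[d.patient_id].append(
                AnnotationEvent(d.date, source, "progression")
            )
        if resp_calls.get(d.doc_id):
            events_by_patient[d.patient_id].append(
                AnnotationEvent(d.date, source, "response")
            )
    timelines = []
    for pid, idx in index_dates.items():
        pat = corpus.patients[pid]
        timelines.append(
            PatientAnnotationTimeline(
                patient_id=pid,
                index_date=idx,
                events=events_by_patient[pid],
                censor_date=max(pat.last_contact_date, idx),
                death_date=pat.death_date,
            )
        )
    return timelines


def first_palliative_index_dates(corpus: Corpus) -> dict[str, _dt.date]:
    """Index at first palliative-intent line; patients without one (or dying
    before it) are excluded."""
    out = {}
    for pid, pat in corpus.patients.items():
        line = pat.first_palliative_line()
        if line is None:
            continue
        if pat.death_date is not None and line.start_date > pat.death_date:
            continue
        out[pid] = line.start_date
    return out


def os_association_analysis(
    corpus: Corpus,
    prog_calls: dict[str, int],
    resp_calls: dict[str, int],
    kind: str,
    adjust_cancer_type: bool = True,
) -> pd.DataFrame:
    """Association between time-varying progression/response annotations
    from one document kind and overall survival, indexed at first palliative
    line with left truncation at genomic testing."""
    source = "imaging" if kind == "imaging" else "note"
    index_dates = first_palliative_index_dates(corpus)
    timelines = build_timelines(corpus, prog_calls, resp_calls, index_dates)
    rows = build_counting_process(timelines, corpus.patients, sources=(source,))
    covs = ["progressed_yet", "responded_yet"]
    if adjust_cancer_type and rows["cancer_type"].nunique() > 1:
        covs.append("cancer_type")
    return fit_cox_tv(rows, covs)


@dataclass
class TmbPfsResult:
    line_table: pd.DataFrame
    hr_continuous: pd.DataFrame
    hr_dichotomized: pd.DataFrame
    median_pfs_months: dict
    median_os_months: dict
    km_pfs: dict = field(default_factory=dict)  # group -> step DataFrame
    km_os: dict = field(default_factory=dict)


def tmb_pfs_analysis(
    corpus: Corpus,
    prog_calls: dict[str, int],
    resp_calls: dict[str, int],
    tmb_cutoff: float = TMB_HIGH_CUTOFF,
) -> TmbPfsResult:
    """TMB vs progression-free survival among ICI treatment lines.

    Every palliative ICI line is an observation indexed at its start; the
    event is PFS-I-and-M.  Cox models (continuous TMB and dichotomized at
    the cutoff) adjust for cancer type and line number and cluster on
    patient.  Kaplan-Meier PFS curves are unadjusted and not left-truncated
    (progression can be documented before genomic testing); OS medians are
    computed with left truncation at NGS.
    """
    from .data_model import DAYS_PER_MONTH

    records = []
    for pid, pat in corpus.patients.items():
        for line in pat.ici_lines():
            if pat.death_date is not None and line.start_date > pat.death_date:
                continue
            records.append((pid, pat, line))
    if not records:
        raise ValueError("no palliative ICI treatment lines in cohort")

    timelines = []
    meta = []
    for pid, pat, line in records:
        timelines.append(
            PatientAnnotationTimeline(
                patient_id=pid,
                index_date=line.start_date,
                events=[],  # filled below from calls
                censor_date=max(pat.last_contact_date, line.start_date),
                death_date=pat.death_date,
            )
        )
        meta.append((pid, pat, line))
    # attach events per line (documents are shared across a patient's lines)
    events_by_patient: dict[str, list[AnnotationEvent]] = {}
    for d in corpus.documents:
        source = "imaging" if d.kind == "imaging" else "note"
        if prog_calls.get(d.doc_id):
            events_by_patient.setdefault(d.patient_id, []).append(
                AnnotationEvent(d.date, source, "progression")
            )
        if resp_calls.get(d.doc_id):
            events_by_patient.setdefault(d.patient_id, []).append(
                AnnotationEvent(d.date, source, "response")
            )
    rows = []
    for tl, (pid, pat, line) in zip(timelines, meta):
        tl.events = sorted(
            events_by_patient.get(pid, []), key=lambda e: e.date
        )
        pfs = derive_pfs(tl, "PFS_I_and_M")
        # same-day events would yield zero-length at-risk intervals
        pfs_days = max(pfs.time, 0.5)
        os_days = max(float((tl.terminal_date - tl.index_date).days), 0.5)
        rows.append(
            {
                "patient_id": pid,
                "line_number": line.line_number,
                "cancer_type": pat.cancer_type,
                "tmb": pat.tmb,
                "tmb_high": int(pat.tmb >= tmb_cutoff),
                "pfs_days": pfs_days,
                "pfs_event": pfs.event,
                "os_days": os_days,
                "os_event": int(pat.death_date is not None),
                "os_entry": max(0.0, float((pat.ngs_date - tl.index_date).days)),
            }
        )
    table = pd.DataFrame(rows)

    def _cox(tmb_col):
        covs = [tmb_col, "line_number"]
        if table["cancer_type"].nunique() > 1:
            covs.append("cancer_type")
        return fit_cox_tv(
            table.assign(start=0.0),
            covs,
            cluster="patient_id",
            start_col="start",
            stop_col="pfs_days",
            event_col="pfs_event",
        )

    hr_cont = _cox("tmb")
    hr_dich = _cox("tmb_high")

    median_pfs, median_os, km_pfs, km_os = {}, {}, {}, {}
    for name, mask in (("high", table.tmb_high == 1), ("low", table.tmb_high == 0)):
        sub = table[mask]
        if not len(sub):
            continue
        step, med = km_estimate(sub.pfs_days, sub.pfs_event)
        km_pfs[name] = step
        median_pfs[name] = med / DAYS_PER_MONTH
        os_sub = sub[sub.os_days > sub.os_entry]
        step_os, med_os = km_estimate(os_sub.os_days, os_sub.os_event, entry=os_sub.os_entry)
        km_os[name] = step_os
        median_os[name] = med_os / DAYS_PER_MONTH
    return TmbPfsResult(
        line_table=table,
        hr_continuous=hr_cont,
        hr_dichotomized=hr_dich,
        median_pfs_months=median_pfs,
        median_os_months=median_os,
        km_pfs=km_pfs,
        km_os=km_os,
    )


def plot_km(step_frames: dict, path, title: str = "", xlabel: str = "days"):
    """Write a step-plot of one or more KM curves to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, step in step_frames.items():
        ax.step(step["time"], step["survival"], where="post", label=str(name))
    ax.set_xlabel(xlabel)
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
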