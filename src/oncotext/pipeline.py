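"""End-to-end orchestration: simulate → section → train → predict →
evaluate → endpoints → survival, as one reproducible recipe.

Every artifact is written under a single output directory together with the
serialized run configuration and its hash; rerunning with the same
configuration reproduces identical tabular outputs.  A master seed fans out
to per-stage sub-seeds through ``numpy.random.SeedSequence(master, stage)``
so stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as otio
from .data_model import CORE_OUTCOMES
from .evaluation import (
    InsufficientVariationError,
    auprc,
    auroc,
    evaluate_by_group,
    pick_operating_point,
)
from .models import (
    crossval_inference,
    default_model_specs,
    ensemble_predict,
    prepare_model_texts,
    train_fold_ensemble,
)
from .sectioner import train_sectioner
from .simulate import GeneratorConfig, simulate_cohort
from .splits import assign_splits
from .survival import (
    build_counting_process,
    build_timelines,
    derive_all_pfs,
    first_palliative_index_dates,
    os_association_analysis,
    plot_km,
    survival_correlation,
    tmb_pfs_analysis,
)

logger = logging.getLogger(__name__)

STAGE_SEEDS = {"simulate": 1, "splits": 2, "sectioner": 3, "train": 4}


def stage_seed(master: int, stage: str) -> int:
    return int(
        np.random.SeedSequence((master, STAGE_SEEDS[stage])).generate_state(1)[0] >> 1
    )


@dataclass
class RunConfig:
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    split_proportions: tuple = (0.8, 0.1, 0.1)
    n_folds: int = 10
    outcomes: tuple = CORE_OUTCOMES
    model_overrides: dict = field(default_factory=dict)
    threshold_criterion: str = "best_f1"
    #: dataset on which binarization thresholds are selected
    threshold_split: str = "validation"
    use_rnn_sectioner: bool = True
    run_tmb_analysis: bool = True
    run_leave_one_type_out: bool = False
    leave_out_type: str = "breast"
    run_temporal_split: bool = False
    temporal_cutoff_year: int = 2017
    out_dir: str = "run_output"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        d["split_proportions"] = list(self.split_proportions)
        d["outcomes"] = list(self.outcomes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "split_proportions" in d:
            d["split_proportions"] = tuple(d["split_proportions"])
        if "outcomes" in d:
            d["outcomes"] = tuple(d["outcomes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a manifest of artifact paths.

    Any stage failure halts the run with the stage name; artifacts written
    by earlier stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}, "artifacts": {}}
    with open(out / "run_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("section", _stage_section),
        ("train", _stage_train),
        ("predict", _stage_predict),
        ("evaluate", _stage_evaluate),
        ("generalization", _stage_generalization),
        ("endpoints", _stage_endpoints),
        ("survival", _stage_survival),
    ]
    for name, fn in stages:
        t0 = time.time()
        try:
            fn(config, state, out, manifest)
        except Exception:
            logger.error("stage %r failed; partial artifacts kept in %s", name, out)
            raise
        wall = time.time() - t0
        manifest["stages"][name] = {"wall_seconds": round(wall, 2)}
        logger.info("stage %s finished in %.1fs", name, wall)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# --------------------------------------------------------------------- stages


def _stage_simulate(config, state, out, manifest):
    gen = dataclasses.replace(config.generator, seed=stage_seed(config.seed, "simulate"))
    corpus, truth = simulate_cohort(gen)
    state["corpus"], state["truth"] = corpus, truth
    paths = otio.write_corpus(corpus, out)
    manifest["artifacts"].update({k: str(v) for k, v in paths.items()})


def _stage_section(config, state, out, manifest):
    corpus = state["corpus"]
    split = assign_splits(
        corpus.patients.keys(),
        config.split_proportions,
        config.n_folds,
        seed=stage_seed(config.seed, "splits"),
    )
    state["split"] = split
    split.to_frame().to_csv(out / "splits.csv", index=False, lineterminator="\n")
    manifest["artifacts"]["splits"] = str(out / "splits.csv")

    tagger = None
    if config.use_rnn_sectioner:
        train_notes = [
            d.text
            for d in corpus.documents
            if d.kind == "oncologist_note"
            and split.partition[d.patient_id] == "train"
        ][:400]
        tagger = train_sectioner(
            train_notes, seed=stage_seed(config.seed, "sectioner")
        )
    state["texts"] = prepare_model_texts(corpus, tagger)
    sectioned = out / "notes_sectioned.jsonl"
    with open(sectioned, "w", encoding="utf-8", newline="\n") as fh:
        for d in sorted(corpus.documents, key=lambda d: d.doc_id):
            if d.kind != "oncologist_note":
                continue
            fh.write(
                json.dumps(
                    {"doc_id": d.doc_id, "assessment_plan": state["texts"][d.doc_id]},
                    ensure_ascii=False,
                )
                + "\n"
            )
    manifest["artifacts"]["notes_sectioned"] = str(sectioned)


def _stage_train(config, state, out, manifest):
    corpus, texts, split = state["corpus"], state["texts"], state["split"]
    specs = default_model_specs(
        outcomes=config.outcomes,
        seed=stage_seed(config.seed, "train"),
        **config.model_overrides,
    )
    ensembles = {}
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    for spec in specs:
        ens = train_fold_ensemble(corpus, texts, spec, split)
        ensembles[(spec.kind, spec.outcome)] = ens
        ens.save(model_dir / f"{spec.kind}_{spec.outcome}.bundle")
    state["ensembles"] = ensembles
    manifest["artifacts"]["models"] = str(model_dir)


def _stage_predict(config, state, out, manifest):
    corpus, texts, split = state["corpus"], state["texts"], state["split"]
    preds = []
    for (kind, outcome), ens in state["ensembles"].items():
        train_docs = [
            d
            for d in corpus.documents
            if d.kind == kind and split.partition[d.patient_id] == "train"
        ]
        other_docs = [
            d
            for d in corpus.documents
            if d.kind == kind and split.partition[d.patient_id] != "train"
        ]
        preds.extend(crossval_inference(ens, train_docs, texts))
        preds.extend(ensemble_predict(ens, other_docs, texts))
    state["predictions"] = preds
    otio.write_predictions(preds, out / "predictions.csv")
    manifest["artifacts"]["predictions"] = str(out / "predictions.csv")


def _collect(state, kind, outcome, partitions):
    """(scores, probabilities, labels, patient_ids) for one cell."""
    corpus, split = state["corpus"], state["split"]
    by_doc = {d.doc_id: d for d in corpus.documents}
    rows = [
        p
        for p in state["predictions"]
        if p.outcome == outcome
        and by_doc[p.doc_id].kind == kind
        and split.partition[by_doc[p.doc_id].patient_id] in partitions
    ]
    scores = np.array([p.score for p in rows])
    probs = np.array([p.probability for p in rows])
    labels = np.array([corpus.labels[p.doc_id].value(outcome) for p in rows])
    pids = np.array([by_doc[p.doc_id].patient_id for p in rows])
    return scores, probs, labels, pids


def _stage_evaluate(config, state, out, manifest):
    corpus = state["corpus"]
    metric_rows, op_rows = [], []
    thresholds = {}
    for (kind, outcome) in state["ensembles"]:
        s, p, y, pids = _collect(state, kind, outcome, ("test",))
        try:
            cell_auroc, cell_auprc = auroc(s, y), auprc(s, y)
        except InsufficientVariationError:
            cell_auroc = cell_auprc = np.nan
        metric_rows.append(
            {
                "kind": kind,
                "outcome": outcome,
                "group": "all",
                "n": len(y),
                "auroc": cell_auroc,
                "auprc": cell_auprc,
            }
        )
        types = np.array([corpus.patients[pid].cancer_type for pid in pids])
        by_type = evaluate_by_group(s, y, types)
        for r in by_type.itertuples(index=False):
            metric_rows.append(
                {
                    "kind": kind,
                    "outcome": outcome,
                    "group": r.group,
                    "n": r.n,
                    "auroc": r.auroc,
                    "auprc": np.nan,
                }
            )
        # operating points frozen on the threshold split
        sv, pv, yv, _ = _collect(state, kind, outcome, (config.threshold_split,))
        for criterion in ("best_f1", "best_youden"):
            op = pick_operating_point(pv, yv, criterion)
            op_rows.append(
                {
                    "kind": kind,
                    "outcome": outcome,
                    "criterion": criterion,
                    "threshold": op.threshold,
                    "sensitivity": op.sensitivity,
                    "specificity": op.specificity,
                    "ppv": op.ppv,
                    "npv": op.npv,
                }
            )
            if criterion == config.threshold_criterion:
                thresholds[(kind, outcome)] = op.threshold
    pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False, lineterminator="\n")
    pd.DataFrame(op_rows).to_csv(out / "operating_points.csv", index=False, lineterminator="\n")
    state["thresholds"] = thresholds
    manifest["artifacts"]["metrics"] = str(out / "metrics.csv")
    manifest["artifacts"]["operating_points"] = str(out / "operating_points.csv")


def _stage_generalization(config, state, out, manifest):
    """Optional retraining analyses: leave-one-cancer-type-out and the
    temporal (train-through-cutoff-year) sensitivity design, each
    demonstrated on the imaging progression cell."""
    corpus, texts, split = state["corpus"], state["texts"], state["split"]
    if config.run_leave_one_type_out:
        from .models import train_excluding_cancer_type

        ens_all = state["ensembles"][("imaging", "progression")]
        ens_excl = train_excluding_cancer_type(
            corpus, texts, config.leave_out_type, ens_all.spec, split
        )
        docs = [
            d
            for d in corpus.documents
            if d.kind == "imaging"
            and split.partition[d.patient_id] == "test"
            and corpus.patients[d.patient_id].cancer_type == config.leave_out_type
        ]
        y = np.array([corpus.labels[d.doc_id].progression for d in docs])
        rows = []
        for name, ens in (("all_types", ens_all), ("excluded", ens_excl)):
            preds = ensemble_predict(ens, docs, texts)
            try:
                value = auroc(np.array([p.score for p in preds]), y)
            except InsufficientVariationError:
                value = np.nan
            rows.append(
                {"model": name, "excluded_type": config.leave_out_type,
                 "n_documents": len(docs), "auroc": value}
            )
        pd.DataFrame(rows).to_csv(
            out / "leave_one_type_out.csv", index=False, lineterminator="\n"
        )
        manifest["artifacts"]["leave_one_type_out"] = str(out / "leave_one_type_out.csv")
    if config.run_temporal_split:
        from .models import train_temporal_split

        spec = state["ensembles"][("imaging", "progression")].spec
        ens, eval_docs = train_temporal_split(
            corpus, texts, spec, split, config.temporal_cutoff_year
        )
        preds = ensemble_predict(ens, eval_docs, texts)
        y = np.array([corpus.labels[p.doc_id].progression for p in preds])
        try:
            value = auroc(np.array([p.score for p in preds]), y)
        except InsufficientVariationError:
            value = np.nan
        pd.DataFrame(
            [{"cutoff_year": config.temporal_cutoff_year,
              "n_post_cutoff_documents": len(eval_docs), "auroc": value}]
        ).to_csv(out / "temporal_split.csv", index=False, lineterminator="\n")
        manifest["artifacts"]["temporal_split"] = str(out / "temporal_split.csv")


def _binary_calls(state, outcome):
    """doc_id -> call using the per-(kind, outcome) frozen thresholds."""
    corpus = state["corpus"]
    by_doc = {d.doc_id: d for d in corpus.documents}
    calls = {}
    for p in state["predictions"]:
        if p.outcome != outcome:
            continue
        kind = by_doc[p.doc_id].kind
        thr = state["thresholds"][(kind, outcome)]
        calls[p.doc_id] = int(p.probability > thr)
    return calls


def _stage_endpoints(config, state, out, manifest):
    corpus = state["corpus"]
    prog = _binary_calls(state, "progression")
    resp = _binary_calls(state, "response")
    state["prog_calls"], state["resp_calls"] = prog, resp
    index_dates = first_palliative_index_dates(corpus)
    timelines = build_timelines(corpus, prog, resp, index_dates)
    state["timelines"] = timelines
    pfs = derive_all_pfs(timelines)
    pfs.to_csv(out / "pfs_endpoints.csv", index=False, lineterminator="\n")
    rows = build_counting_process(timelines, corpus.patients)
    rows.to_csv(out / "counting_process.csv", index=False, lineterminator="\n")
    manifest["artifacts"]["pfs_endpoints"] = str(out / "pfs_endpoints.csv")
    manifest["artifacts"]["counting_process"] = str(out / "counting_process.csv")


def _stage_survival(config, state, out, manifest):
    corpus = state["corpus"]
    prog, resp = state["prog_calls"], state["resp_calls"]
    hr_rows = []
    for kind in ("imaging", "oncologist_note"):
        res = os_association_analysis(corpus, prog, resp, kind)
        for cov in ("progressed_yet", "responded_yet"):
            hr_rows.append(
                {
                    "kind": kind,
                    "covariate": cov,
                    "hr": res.loc[cov, "hr"],
                    "hr_lower": res.loc[cov, "hr_lower"],
                    "hr_upper": res.loc[cov, "hr_upper"],
                    "n_events": res.attrs["n_events"],
                }
            )
    pd.DataFrame(hr_rows).to_csv(out / "os_association.csv", index=False, lineterminator="\n")
    manifest["artifacts"]["os_association"] = str(out / "os_association.csv")

    # censored PFS-OS correlation per variant
    pfs = derive_all_pfs(state["timelines"])
    by_pid = {
        tl.patient_id: (
            max(float((tl.terminal_date - tl.index_date).days), 0.5),
            int(tl.death_date is not None),
        )
        for tl in state["timelines"]
    }
    corr_rows = []
    for variant in sorted(pfs.variant.unique()):
        sub = pfs[pfs.variant == variant]
        pairs = pd.DataFrame(
            {
                "pfs_time": np.maximum(sub.time_days.values, 0.5),
                "pfs_event": sub.event.values,
                "os_time": [by_pid[p][0] for p in sub.patient_id],
                "os_event": [by_pid[p][1] for p in sub.patient_id],
            }
        )
        try:
            rho, ci = survival_correlation(pairs)
            corr_rows.append(
                {"variant": variant, "rho": rho, "rho_lower": ci[0], "rho_upper": ci[1]}
            )
        except ValueError as exc:
            corr_rows.append(
                {"variant": variant, "rho": np.nan, "rho_lower": np.nan,
                 "rho_upper": np.nan, "note": str(exc)}
            )
    pd.DataFrame(corr_rows).to_csv(out / "pfs_os_correlation.csv", index=False, lineterminator="\n")
    manifest["artifacts"]["pfs_os_correlation"] = str(out / "pfs_os_correlation.csv")

    if config.run_tmb_analysis:
        res = tmb_pfs_analysis(corpus, prog, resp)
        res.hr_dichotomized.to_csv(out / "tmb_hr_dichotomized.csv", lineterminator="\n")
        res.hr_continuous.to_csv(out / "tmb_hr_continuous.csv", lineterminator="\n")
        medians = pd.DataFrame(
            {
                "group": list(res.median_pfs_months),
                "median_pfs_months": [res.median_pfs_months[g] for g in res.median_pfs_months],
                "median_os_months": [res.median_os_months.get(g, np.nan) for g in res.median_pfs_months],
            }
        )
        medians.to_csv(out / "tmb_medians.csv", index=False, lineterminator="\n")
        for name, frames in (("pfs", res.km_pfs), ("os", res.km_os)):
            for grp, step in frames.items():
                step.to_csv(out / f"km_{name}_tmb_{grp}.csv", index=False, lineterminator="\n")
            plot_km(frames, out / f"km_{name}_by_tmb.png", title=f"{name.upper()} by TMB group")
        manifest["artifacts"]["tmb_analysis"] = str(out / "tmb_hr_dichotomized.csv")
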