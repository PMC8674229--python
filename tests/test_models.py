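import numpy as np
import pytest

from oncotext.evaluation import auroc
from oncotext.models import (
    OutcomeModelSpec,
    Vocabulary,
    crossval_inference,
    ensemble_predict,
    prepare_model_texts,
    train_excluding_cancer_type,
    train_fold_ensemble,
    train_temporal_split,
    vectorize,
)
from oncotext.splits import assign_splits
from oncotext.textcnn import ConvTextClassifier


@pytest.fixture(scope="module")
def trained(clean_small_corpus):
    """Imaging progression ensemble on a clean 60-patient corpus (5 folds)."""
    corpus, _ = clean_small_corpus
    texts = prepare_model_texts(corpus)
    split = assign_splits(corpus.patients.keys(), n_folds=5, seed=1)
    spec = OutcomeModelSpec(outcome="progression", kind="imaging", seed=3,
                            epochs=6, batch_size=32, max_len=128)
    ens = train_fold_ensemble(corpus, texts, spec, split)
    return corpus, texts, split, ens


class TestVectorize:
    def test_empty_text_is_all_padding(self):
        v = Vocabulary.build(["alpha beta beta"], min_count=1)
        assert np.all(vectorize("", v, 8) == 0)

    def test_unknown_token_maps_to_unk_index(self):
        v = Vocabulary.build(["alpha beta beta"], min_count=1)
        seq = vectorize("alpha gamma", v, 4)
        assert seq[0] >= 2 and seq[1] == 1

    def test_truncates_tail_and_pads_end(self):
        v = Vocabulary.build(["a b c d e"], min_count=1)
        assert len(vectorize("a b c d e", v, 3)) == 3
        seq = vectorize("a", v, 5)
        assert list(seq[1:]) == [0, 0, 0, 0]

    def test_vocabulary_built_from_training_split_only(self, trained):
        corpus, texts, split, ens = trained
        test_only_tokens = set()
        train_tokens = set()
        for d in corpus.documents:
            toks = set(texts[d.doc_id].lower().split())
            if split.partition[d.patient_id] == "train":
                train_tokens |= toks
            else:
                test_only_tokens |= toks
        test_only_tokens -= train_tokens
        assert not any(t in ens.vocab for t in test_only_tokens)


class TestTraining:
    def test_each_member_separates_clean_lexicons(self, trained):
        corpus, texts, split, ens = trained
        docs = [
            d for d in corpus.documents
            if d.kind == "imaging" and split.partition[d.patient_id] != "train"
        ]
        y = np.array([corpus.labels[d.doc_id].progression for d in docs])
        scores = ens.member_scores(docs, texts)
        for member_scores in scores:
            assert auroc(member_scores, y) >= 0.99

    def test_dual_topology_loss_decreases_on_both_outputs(self, trained):
        _, _, _, ens = trained
        for m in ens.members:
            hist = np.array(m.loss_history_)
            assert hist.shape[1] == 2
            assert (hist[-1] < hist[0]).all()

    def test_training_is_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 50, size=(40, 16))
        Y = rng.integers(0, 2, size=(40, 1))
        a = ConvTextClassifier(vocab_size=50, epochs=2, seed=9).fit(X, Y)
        b = ConvTextClassifier(vocab_size=50, epochs=2, seed=9).fit(X, Y)
        assert np.array_equal(a.decision_function(X), b.decision_function(X))

    def test_batch_order_invariance_of_scores(self, trained):
        corpus, texts, split, ens = trained
        docs = [d for d in corpus.documents if d.kind == "imaging"][:40]
        s1 = ens.member_scores(docs, texts)
        perm = list(reversed(range(len(docs))))
        s2 = ens.member_scores([docs[i] for i in perm], texts)
        assert np.allclose(s1[:, perm], s2)

    def test_single_class_fold_raises_naming_fold(self, clean_small_corpus):
        corpus, _ = clean_small_corpus
        texts = prepare_model_texts(corpus)
        split = assign_splits(corpus.patients.keys(), n_folds=5, seed=1)
        import dataclasses

        # force the any-cancer output single-class everywhere
        labels = {
            k: dataclasses.replace(lab, any_cancer=1)
            for k, lab in corpus.labels.items()
        }
        broken = dataclasses.replace(corpus, labels=labels)
        spec = OutcomeModelSpec(outcome="any_cancer", kind="imaging", epochs=1)
        with pytest.raises(ValueError, match="fold 0"):
            train_fold_ensemble(broken, texts, spec, split)


class TestEnsembleInference:
    def test_score_is_mean_of_member_logits(self, trained):
        corpus, texts, split, ens = trained
        docs = [d for d in corpus.documents if d.kind == "imaging"][:5]
        preds = ensemble_predict(ens, docs, texts)
        col = ens.spec.outcome_column
        X = np.stack([vectorize(texts[d.doc_id], ens.vocab, ens.spec.max_len) for d in docs])
        manual = np.mean(
            [m.decision_function(X)[:, col] for m in ens.members], axis=0
        )
        assert np.allclose([p.score for p in preds], manual, atol=1e-6)
        for p in preds:
            assert np.isclose(p.probability, 1 / (1 + np.exp(-p.score)))

    def test_member_permutation_leaves_scores_unchanged(self, trained):
        corpus, texts, split, ens = trained
        docs = [d for d in corpus.documents if d.kind == "imaging"][:5]
        base = [p.score for p in ensemble_predict(ens, docs, texts)]
        import dataclasses

        shuffled = dataclasses.replace(
            ens, members=list(reversed(ens.members))
        )
        again = [p.score for p in ensemble_predict(shuffled, docs, texts)]
        assert np.allclose(base, again, atol=1e-6)

    def test_mean_pooling_logits_differs_from_mean_pooling_probabilities(self, trained):
        corpus, texts, split, ens = trained
        docs = [d for d in corpus.documents if d.kind == "imaging"][:50]
        preds = ensemble_predict(ens, docs, texts)
        col = ens.spec.outcome_column
        X = np.stack([vectorize(texts[d.doc_id], ens.vocab, ens.spec.max_len) for d in docs])
        member_probs = np.stack(
            [1 / (1 + np.exp(-m.decision_function(X)[:, col])) for m in ens.members]
        )
        prob_pooled = member_probs.mean(axis=0)
        logit_pooled = np.array([p.probability for p in preds])
        assert not np.allclose(prob_pooled, logit_pooled, atol=1e-6)

    def test_empty_ensemble_is_an_error(self, trained):
        corpus, texts, _, ens = trained
        import dataclasses

        empty = dataclasses.replace(ens, members=[])
        with pytest.raises(ValueError, match="empty"):
            ensemble_predict(empty, corpus.documents[:2], texts)


class TestCrossvalInference:
    def test_document_scored_by_excluded_fold_member(self, trained):
        corpus, texts, split, ens = trained
        docs = [
            d for d in corpus.documents
            if d.kind == "imaging" and split.partition[d.patient_id] == "train"
        ]
        preds = crossval_inference(ens, docs, texts)
        by_doc = {d.doc_id: d for d in docs}
        col = ens.spec.outcome_column
        for p in preds[:30]:
            d = by_doc[p.doc_id]
            f = split.fold[d.patient_id]
            X = vectorize(texts[d.doc_id], ens.vocab, ens.spec.max_len)[None, :]
            expected = ens.members[f].decision_function(X)[0, col]
            assert np.isclose(p.score, expected, atol=1e-6)
            assert p.provenance == "cv_excluded_fold"

    def test_no_scoring_model_saw_its_patient(self, trained):
        corpus, texts, split, ens = trained
        for pid, f in ens.fold_of_patient.items():
            assert pid not in ens.training_patients[f]

    def test_patient_without_fold_assignment_is_an_error(self, trained):
        corpus, texts, split, ens = trained
        docs = [
            d for d in corpus.documents
            if d.kind == "imaging" and split.partition[d.patient_id] == "test"
        ][:1]
        with pytest.raises(ValueError, match="fold"):
            crossval_inference(ens, docs, texts)


class TestRetrainingModes:
    def test_excluded_type_absent_from_training(self, trained):
        corpus, texts, split, ens = trained
        types = {p.cancer_type for p in corpus.patients.values()}
        excluded = sorted(types)[0]
        spec = OutcomeModelSpec(outcome="progression", kind="imaging", epochs=1)
        ens2 = train_excluding_cancer_type(corpus, texts, excluded, spec, split)
        for fold_patients in ens2.training_patients:
            for pid in fold_patients:
                assert corpus.patients[pid].cancer_type != excluded

    def test_excluding_absent_type_is_identity_on_training_set(self, trained):
        corpus, texts, split, ens = trained
        spec = OutcomeModelSpec(outcome="progression", kind="imaging", epochs=1, seed=5)
        a = train_excluding_cancer_type(corpus, texts, "leiomyosarcoma", spec, split) \
            if not any(p.cancer_type == "leiomyosarcoma" for p in corpus.patients.values()) \
            else None
        if a is None:
            pytest.skip("corpus happens to contain the rare type")
        b = train_fold_ensemble(corpus, texts, spec, split)
        assert [sorted(x) for x in a.training_patients] == [
            sorted(x) for x in b.training_patients
        ]

    def test_temporal_split_has_no_post_cutoff_leakage(self, small_corpus):
        corpus, _ = small_corpus
        texts = prepare_model_texts(corpus)
        split = assign_splits(corpus.patients.keys(), n_folds=5, seed=2)
        years = sorted({d.date.year for d in corpus.documents})
        cutoff = years[len(years) // 2]
        spec = OutcomeModelSpec(outcome="any_cancer", kind="imaging", epochs=1)
        ens, eval_docs = train_temporal_split(corpus, texts, spec, split, cutoff)
        assert all(d.date.year > cutoff for d in eval_docs)
        post_tokens = set()
        pre_tokens = set()
        for d in corpus.documents:
            if d.kind != "imaging" or split.partition[d.patient_id] != "train":
                continue
            toks = set(texts[d.doc_id].lower().split())
            (post_tokens if d.date.year > cutoff else pre_tokens).update(toks)
        for t in post_tokens - pre_tokens:
            assert t not in ens.vocab

    def test_all_documents_on_one_side_is_an_error(self, small_corpus):
        corpus, _ = small_corpus
        texts = prepare_model_texts(corpus)
        split = assign_splits(corpus.patients.keys(), n_folds=5, seed=2)
        spec = OutcomeModelSpec(outcome="any_cancer", kind="imaging", epochs=1)
        with pytest.raises(ValueError):
            train_temporal_split(corpus, texts, spec, split, 2050)
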