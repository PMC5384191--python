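import math

import pytest

from trajmine import (
    CLASSES,
    FeatureVector,
    classify_mention,
    compute_idf,
    extract_features,
    forward_select,
    pairwise_f1,
    train_nb,
)
from trajmine.context_classifier import cv_macro_f1
from trajmine.vocab_annotator import AlignmentResult, Mention


def _mention(doc: str, surface: str) -> Mention:
    start = doc.index(surface)
    aln = AlignmentResult(2 * len(surface), len(surface), 0, 0,
                          (0, len(surface)), (0, len(surface)))
    return Mention("d1", (start, start + len(surface)), surface, "C1",
                   "disease", aln)


def fv(*feats: str) -> FeatureVector:
    return FeatureVector(frozenset(feats))


class TestExtractFeatures:
    def test_window_words_enumerated(self):
        doc = "No sign of cancer today."
        f = extract_features(doc, _mention(doc, "cancer"))
        window = {x for x in f.features if x.startswith("window=")}
        assert window == {"window=no", "window=sign", "window=of",
                          "window=today"}

    def test_mention_at_document_start_has_no_pre_para(self):
        doc = "cancer found in scan."
        f = extract_features(doc, _mention(doc, "cancer"))
        assert not any(x.startswith("pre_para=") for x in f.features)
        assert any(x.startswith("sent=") for x in f.features)

    def test_single_block_doc_has_equal_para_and_sent_sets(self):
        doc = "note mentions cancer and nausea"
        f = extract_features(doc, _mention(doc, "cancer"))
        para = {x.split("=", 1)[1] for x in f.features if x.startswith("para=")}
        sent = {x.split("=", 1)[1] for x in f.features if x.startswith("sent=")}
        assert para == sent

    def test_pre_para_words_come_from_previous_block(self):
        doc = "one two three four\n\nfever cancer here"
        f = extract_features(doc, _mention(doc, "cancer"))
        pre = {x for x in f.features if x.startswith("pre_para=")}
        assert pre == {"pre_para=two", "pre_para=three", "pre_para=four"}
        assert "para=one" not in f.features

    def test_term_excluded_from_context_classes(self):
        doc = "severe cancer today"
        f = extract_features(doc, _mention(doc, "cancer"))
        assert not any(x.endswith("=cancer") for x in f.features)

    def test_span_outside_document_rejected(self):
        m = Mention("d1", (50, 56), "cancer", "C1", "disease",
                    AlignmentResult(12, 6, 0, 0, (0, 6), (0, 6)))
        with pytest.raises(ValueError):
            extract_features("short", m)


class TestIdf:
    def test_ubiquitous_feature_zero_everywhere_else_scaled(self):
        vecs = [fv("window=a", f"window=u{i}") for i in range(10)]
        idf = compute_idf(vecs)
        assert idf["window=a"] == 0.0
        assert idf["window=u3"] == pytest.approx(math.log(10))
        assert "window=absent" not in idf

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            compute_idf([])


class TestTrainNB:
    def test_balanced_priors(self):
        data = [(fv("window=a"), "current"), (fv("window=b"), "history"),
                (fv("window=c"), "noise")]
        model = train_nb(data)
        for c in CLASSES:
            assert model.log_priors[c] == pytest.approx(math.log(1 / 3))

    def test_separable_classes_perfect_on_training_set(self):
        data = []
        for i in range(4):
            data.append((fv("window=now", f"para=x{i}"), "current"))
            data.append((fv("window=past", f"para=y{i}"), "history"))
            data.append((fv("window=deny", f"para=z{i}"), "noise"))
        model = train_nb(data)
        assert all(classify_mention(model, v)[0] == lab for v, lab in data)

    def test_laplace_unseen_feature_likelihood(self):
        # feature "window=b" never occurs in class history (n=2 examples);
        # with smoothing 1 and V features its likelihood is 1/(n+V)
        data = [(fv("window=a"), "history"), (fv("window=a"), "history"),
                (fv("window=b"), "current"), (fv("window=b"), "current")]
        model = train_nb(data, smoothing=1.0)
        V = model.n_features
        assert model.log_likelihoods[("window=b", "history")] == pytest.approx(
            math.log(1 / (2 + V)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_nb([(fv("window=a"), "current"), (fv("window=b"), "current")])


class TestClassify:
    def test_uniform_tie_resolves_to_current(self):
        data = [(fv("window=a"), "current"), (fv("window=b"), "history"),
                (fv("window=c"), "noise")]
        model = train_nb(data)
        label, post = classify_mention(model, fv())
        assert label == "current"
        assert post["current"] == pytest.approx(post["noise"])

    def test_noise_only_evidence_yields_noise(self):
        data = []
        for i in range(2):
            data.append((fv("window=now"), "current"))
            data.append((fv("window=past"), "history"))
            data.append((fv("window=deny", "window=letter"), "noise"))
        model = train_nb(data)
        label, _ = classify_mention(model, fv("window=deny", "window=letter"))
        assert label == "noise"

    def test_posteriors_normalized(self):
        data = [(fv("window=a"), "current"), (fv("window=b"), "noise")]
        model = train_nb(data)
        _, post = classify_mention(model, fv("window=a"))
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_absent_feature_cannot_change_prediction(self):
        # selecting an extra feature must not move posteriors of vectors
        # that do not contain it
        data = [(fv("window=a", "window=q"), "current"),
                (fv("window=b"), "history"),
                (fv("window=a"), "current"), (fv("window=b", "window=q"), "history")]
        m_small = train_nb(data, selected_features=["window=a", "window=b"])
        m_big = train_nb(data, selected_features=["window=a", "window=b",
                                                  "window=q"])
        probe = fv("window=a")
        assert classify_mention(m_small, probe)[1] == pytest.approx(
            classify_mention(m_big, probe)[1])


class TestForwardSelect:
    def _toy(self):
        # one feature perfectly separates current from noise: present on all
        # current examples, and the noise majority prior settles the
        # signal-absent case (feature presence is the only evidence used).
        # All other features are singleton distractors with low tf-idf mass.
        data = []
        for i in range(10):
            lab = "current" if i < 4 else "noise"
            feats = [f"window=junk{i}"]
            if lab == "current":
                feats.append("window=signal")
            data.append((fv(*feats), lab))
        return data

    def test_perfect_feature_selected_alone(self):
        selected = forward_select(self._toy(), folds=5, seed=3)
        assert selected == ["window=signal"]

    def test_deterministic_under_seed(self):
        data = self._toy()
        assert forward_select(data, folds=5, seed=7) == forward_select(
            data, folds=5, seed=7)

    def test_no_candidate_features_rejected(self):
        data = [(fv(), "current"), (fv(), "noise")] * 3
        with pytest.raises(ValueError):
            forward_select(data, folds=2, seed=0)

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            forward_select(self._toy(), folds=1, seed=0)

    def test_selected_features_separate_both_classes(self):
        data = self._toy()
        selected = forward_select(data, folds=5, seed=3)
        idf = compute_idf([v for v, _ in data])
        model = train_nb(data, selected_features=selected, idf_table=idf)
        assert all(classify_mention(model, v)[0] == lab for v, lab in data)
        baseline = cv_macro_f1(data, [], 5, 3, 1.0, idf)
        assert cv_macro_f1(data, selected, 5, 3, 1.0, idf) > baseline


class TestPairwiseF1:
    def _model_and_data(self, perfect: bool):
        data = []
        for i in range(6):
            data.append((fv("window=now"), "current"))
            data.append((fv("window=past"), "history"))
            data.append((fv("window=deny"), "noise"))
        model = train_nb(data)
        if not perfect:
            # degenerate test set where evidence always says "current"
            test = [(fv("window=now"), "current"), (fv("window=now"), "noise")] * 3
            return model, test
        return model, data

    def test_perfect_predictions(self):
        model, test = self._model_and_data(perfect=True)
        out = pairwise_f1(model, test)
        assert out["current-noise"] == out["history-noise"] == 1.0
        assert out["macro"] == 1.0

    def test_one_sided_predictions_on_balanced_pair(self):
        model, test = self._model_and_data(perfect=False)
        out = pairwise_f1(model, test)
        # all predicted positive on a balanced pair: precision 1/2, recall 1
        assert out["current-noise"] == pytest.approx(2 / 3)

    def test_absent_pair_reported_as_none(self):
        model, _ = self._model_and_data(perfect=True)
        test = [(fv("window=now"), "current")] * 4
        assert pairwise_f1(model, test)["history-noise"] is None

    def test_empty_test_set_rejected(self):
        model, _ = self._model_and_data(perfect=True)
        with pytest.raises(ValueError):
            pairwise_f1(model, [])
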