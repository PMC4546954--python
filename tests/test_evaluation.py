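"""Setting construction, stratified folds, metrics, and the experiment grid."""
import logging

import numpy as np
import pytest

import medrelex as m
from medrelex.evaluation import ConfusionCounts, confusion_from_predictions
from medrelex.exceptions import ConfigurationError
from medrelex.features import FeatureLevel


def record(label, text="the patient affects the dose.", rid="r"):
    return m.CorpusRecord(label=label, text=text, id=rid)


class TestSettingSpec:
    def test_nine_rows(self):
        seen = set()
        for sid in (1, 2, 3):
            for rel in ("cure", "prevent", "side_effect"):
                spec = m.setting_spec(sid, rel)
                seen.add((sid, rel))
                assert spec.positive_classes & spec.negative_classes == frozenset()
        assert len(seen) == 9

    def test_setting1_negatives(self):
        spec = m.setting_spec(1, "cure")
        assert spec.negative_classes == {"DisOnly", "TreatOnly"}

    def test_setting3_pairings(self):
        assert m.setting_spec(3, "cure").negative_classes == {"Prevent", "SideEffect"}
        assert m.setting_spec(3, "prevent").negative_classes == {"SideEffect"}
        assert m.setting_spec(3, "side_effect").negative_classes == {"Prevent"}

    def test_unknown_setting_rejected(self):
        with pytest.raises(ConfigurationError):
            m.setting_spec(4, "cure")
        with pytest.raises(ConfigurationError):
            m.setting_spec(1, "treat")


class TestBuildSettingInstances:
    def test_setting1_excludes_vague(self):
        records = [record("Cure"), record("Cure"), record("DisOnly"), record("Vague")]
        texts, labels = m.build_setting_instances(records, m.setting_spec(1, "cure"))
        assert labels == [1, 1, -1]

    def test_setting3_prevent_vs_side_effect(self):
        records = [record("Prevent"), record("SideEffect")]
        _, labels = m.build_setting_instances(records, m.setting_spec(3, "prevent"))
        assert labels == [1, -1]

    def test_empty_negative_side_rejected(self):
        records = [record("Cure"), record("DisOnly")]
        with pytest.raises(ValueError, match="negative"):
            m.build_setting_instances(records, m.setting_spec(2, "cure"))


class TestStratifiedKFold:
    def test_exact_stratification(self):
        labels = [1] * 10 + [-1] * 10
        folds = m.stratified_kfold(labels, k=10, seed=0)
        assert len(folds) == 10
        for _, test in folds:
            assert len(test) == 2
            assert sorted(np.sign([labels[i] for i in test])) == [-1, 1]

    def test_deterministic_under_seed(self):
        labels = [1] * 15 + [-1] * 25
        a = m.stratified_kfold(labels, k=10, seed=3)
        b = m.stratified_kfold(labels, k=10, seed=3)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_k_reduced_to_min_class_count(self, caplog):
        labels = [1] * 10 + [-1] * 5
        with caplog.at_level(logging.WARNING):
            folds = m.stratified_kfold(labels, k=10, seed=0)
        assert len(folds) == 5
        assert any("reducing k" in msg for msg in caplog.messages)

    def test_too_few_instances_rejected(self):
        with pytest.raises(ValueError):
            m.stratified_kfold([1, 1, -1], k=10, seed=0)

    def test_partition_property(self):
        labels = ([1] * 23 + [-1] * 31)
        folds = m.stratified_kfold(labels, k=10, seed=9)
        all_test = sorted(i for _, test in folds for i in test)
        assert all_test == list(range(len(labels)))
        for train, test in folds:
            assert set(train) | set(test) == set(range(len(labels)))
            assert not set(train) & set(test)


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((8, 2, 2, 8), (80.0, 80.0, 80.0, 80.0)),
            ((0, 0, 5, 5), (50.0, 0.0, 0.0, 0.0)),
            ((10, 10, 0, 0), (50.0, 50.0, 100.0, 66.67)),
        ],
    )
    def test_closed_forms(self, counts, expected):
        got = m.compute_metrics(ConfusionCounts(*counts))
        assert (got.accuracy, got.precision, got.recall, round(got.f_score, 2)) == expected

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            m.compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_f_between_precision_and_recall(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 20, size=4))
            if tp + fp + fn + tn == 0:
                continue
            got = m.compute_metrics(ConfusionCounts(tp, fp, fn, tn))
            if got.precision > 0 and got.recall > 0:
                lo, hi = sorted([got.precision, got.recall])
                assert lo - 1e-9 <= got.f_score <= hi + 1e-9

    def test_label_flip_swaps_precision_and_recall_roles(self):
        y_true = [1, 1, 1, -1, -1]
        y_pred = [1, -1, 1, 1, -1]
        pos = m.compute_metrics(confusion_from_predictions(y_true, y_pred, positive=1))
        neg = m.compute_metrics(confusion_from_predictions(y_true, y_pred, positive=-1))
        # flipping the positive class swaps the tp/tn and fp/fn roles
        assert pos.accuracy == neg.accuracy
        cp = confusion_from_predictions(y_true, y_pred, positive=1)
        cn = confusion_from_predictions(y_true, y_pred, positive=-1)
        assert (cp.tp, cp.fp, cp.fn, cp.tn) == (cn.tn, cn.fn, cn.fp, cn.tp)


@pytest.fixture(scope="module")
def tiny_corpus():
    cfg = m.default_corpus_config(seed=5, n_per_class=12)
    return m.generate_corpus(cfg), m.load_lexicon(m.generate_lexicon(cfg))


class TestExperimentGrid:
    def test_separable_corpus_scores_100(self, tiny_corpus):
        records, lexicon = tiny_corpus
        report = m.run_experiment_grid(
            records, lexicon, [(1, "cure")], [FeatureLevel.BOW], ["nb"], k=10, seed=1
        )
        mean = report.rows[0]["mean"]
        assert mean == {"accuracy": 100.0, "precision": 100.0,
                        "recall": 100.0, "f_score": 100.0}

    def test_report_shape_one_cell(self, tiny_corpus):
        records, lexicon = tiny_corpus
        report = m.run_experiment_grid(
            records, lexicon, [(2, "prevent")], [FeatureLevel.BOW], ["nb"], k=5, seed=1
        )
        assert len(report.rows) == 1
        row = report.rows[0]
        assert (row["relation"], row["setting"], row["classifier"]) == ("prevent", 2, "nb")
        assert len(row["folds"]) == 5

    def test_fixed_seed_reports_byte_identical(self, tiny_corpus):
        records, lexicon = tiny_corpus
        kwargs = dict(k=5, seed=7)
        a = m.run_experiment_grid(records, lexicon, [(1, "cure")],
                                  [FeatureLevel.BOW_NLP], ["nb", "svm-linear"], **kwargs)
        b = m.run_experiment_grid(records, lexicon, [(1, "cure")],
                                  [FeatureLevel.BOW_NLP], ["nb", "svm-linear"], **kwargs)
        assert a.to_json() == b.to_json()
        assert a.to_tsv() == b.to_tsv()

    def test_umls_level_without_lexicon_rejected(self, tiny_corpus):
        records, _ = tiny_corpus
        with pytest.raises(ConfigurationError):
            m.run_experiment_grid(records, None, [(1, "cure")],
                                  [FeatureLevel.BOW_NLP_UMLS_NP], ["nb"])
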