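"""Experimental settings, stratified cross-validation, and metric reporting.

Nine binary tasks are defined, three per relation (cure, prevent,
side_effect):

* setting 1 — relation vs. sentences mentioning only a disease or only a
  treatment (DisOnly + TreatOnly);
* setting 2 — relation vs. Vague sentences;
* setting 3 — relation vs. the other meaningful relations (cure vs.
  prevent + side_effect; prevent vs. side_effect; side_effect vs. prevent).

Each task is evaluated by stratified k-fold cross-validation (default k=10,
seeded): the vocabulary is rebuilt from the training folds only, the
classifier is fit per fold, and accuracy / precision / recall / F-score for
the positive class are averaged arithmetically over folds and reported on
the percent scale with two decimals.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .classifiers import make_classifier
from .concept_ranking import Lexicon, RankerConfig
from .exceptions import ConfigurationError
from .features import (
    FeatureLevel,
    build_vocabulary,
    extract_instance_features,
    vectorize_all,
)
from .preprocess import preprocess_text

logger = logging.getLogger(__name__)

RELATIONS = ("cure", "prevent", "side_effect")

_RELATION_LABEL = {"cure": "Cure", "prevent": "Prevent", "side_effect": "SideEffect"}

_SETTING3_NEGATIVES = {
    "cure": frozenset({"Prevent", "SideEffect"}),
    "prevent": frozenset({"SideEffect"}),
    "side_effect": frozenset({"Prevent"}),
}


@dataclass(frozen=True)
class SettingSpec:
    setting_id: int
    relation: str
    positive_classes: frozenset[str]
    negative_classes: frozenset[str]


def setting_spec(setting_id: int, relation: str) -> SettingSpec:
    """One of the nine documented binary task constructions."""
    if relation not in RELATIONS:
        raise ConfigurationError(f"unknown relation {relation!r}; choose from {RELATIONS}")
    positive = frozenset({_RELATION_LABEL[relation]})
    if setting_id == 1:
        negative = frozenset({"DisOnly", "TreatOnly"})
    elif setting_id == 2:
        negative = frozenset({"Vague"})
    elif setting_id == 3:
        negative = _SETTING3_NEGATIVES[relation]
    else:
        raise ConfigurationError(f"unknown setting id {setting_id}; must be 1, 2 or 3")
    return SettingSpec(setting_id, relation, positive, negative)


def build_setting_instances(
    records: Sequence, spec: SettingSpec
) -> tuple[list[str], list[int]]:
    """Texts and ±1 labels for one setting; out-of-setting records are excluded."""
    texts: list[str] = []
    labels: list[int] = []
    for rec in records:
        if rec.label in spec.positive_classes:
            texts.append(rec.text)
            labels.append(+1)
        elif rec.label in spec.negative_classes:
            texts.append(rec.text)
            labels.append(-1)
    if +1 not in labels:
        raise ValueError(
            f"setting {spec.setting_id}/{spec.relation}: no positive instances"
        )
    if -1 not in labels:
        raise ValueError(
            f"setting {spec.setting_id}/{spec.relation}: no negative instances"
        )
    return texts, labels


def stratified_kfold(
    labels: Sequence[int], k: int = 10, seed: int = 42
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified folds: per class, shuffle then deal round-robin.

    If the smallest class has fewer than k members, k is reduced to that
    count (with a logged warning); fewer than 2 per class is an error.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError("each class needs at least 2 instances for cross-validation")
    k_eff = min(k, min_count)
    if k_eff < k:
        logger.warning(
            "reducing k from %d to %d (smallest class has %d instances)",
            k, k_eff, min_count,
        )
    rng = np.random.default_rng(seed)
    test_folds: list[list[int]] = [[] for _ in range(k_eff)]
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            test_folds[j % k_eff].append(int(i))
    all_idx = set(range(len(y)))
    out = []
    for fold in test_folds:
        test = np.array(sorted(fold), dtype=int)
        train = np.array(sorted(all_idx - set(fold)), dtype=int)
        out.append((train, test))
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f_score: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
        }


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall, F for the positive class, on the percent scale.

    Zero denominators yield 0 (including F when P + R = 0).
    """
    if counts.total < 1:
        raise ValueError("cannot compute metrics from all-zero confusion counts")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / counts.total
    return Metrics(100 * accuracy, 100 * precision, 100 * recall, 100 * f)


def confusion_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int], positive: int = +1
) -> ConfusionCounts:
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if p == positive:
            if t == positive:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


@dataclass
class EvalReport:
    """Per-cell fold metrics and means, plus the reproducibility context."""

    rows: list[dict] = field(default_factory=list)
    seed: int = 42
    k: int = 10
    config: dict = field(default_factory=dict)
    fold_assignments: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "k": self.k,
            "config": self.config,
            "fold_assignments": self.fold_assignments,
            "rows": self.rows,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        header = [
            "relation", "setting", "feature_set", "classifier",
            "f_score", "precision", "recall", "accuracy",
        ]
        lines = ["\t".join(header)]
        for row in self.rows:
            mean = row["mean"]
            lines.append(
                "\t".join(
                    [
                        row["relation"],
                        str(row["setting"]),
                        row["feature_set"],
                        row["classifier"],
                        f"{mean['f_score']:.2f}",
                        f"{mean['precision']:.2f}",
                        f"{mean['recall']:.2f}",
                        f"{mean['accuracy']:.2f}",
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def run_experiment_grid(
    records: Sequence,
    lexicon: Optional[Lexicon],
    settings: Sequence[tuple[int, str]],
    levels: Sequence[FeatureLevel],
    classifiers: Sequence[str],
    k: int = 10,
    seed: int = 42,
    ranker_config: Optional[RankerConfig] = None,
    config_echo: Optional[Mapping] = None,
) -> EvalReport:
    """Cross-validate every (setting, feature level, classifier) cell.

    Feature bags are computed once per record and level; the vocabulary is
    rebuilt from the training folds of each split.
    """
    umls_levels = {FeatureLevel.BOW_NLP_UMLS_NP, FeatureLevel.BOW_NLP_UMLS_NP_VP}
    if lexicon is None and any(lv in umls_levels for lv in levels):
        raise ConfigurationError("UMLS feature levels require a concept lexicon")

    # preprocess each record once, reuse across levels
    sentences = [preprocess_text(rec.text, source_id=rec.id) for rec in records]
    bags_by_level: dict[FeatureLevel, list[list[str]]] = {}
    for level in levels:
        bags = []
        for sents in sentences:
            bag: list[str] = []
            for s in sents:
                bag.extend(
                    extract_instance_features(s, level, lexicon, ranker_config)
                )
            bags.append(bag)
        bags_by_level[level] = bags

    report = EvalReport(seed=seed, k=k, config=dict(config_echo or {}))
    for setting_id, relation in settings:
        spec = setting_spec(setting_id, relation)
        indices: list[int] = []
        labels: list[int] = []
        for i, rec in enumerate(records):
            if rec.label in spec.positive_classes:
                indices.append(i)
                labels.append(+1)
            elif rec.label in spec.negative_classes:
                indices.append(i)
                labels.append(-1)
        if +1 not in labels or -1 not in labels:
            raise ValueError(
                f"setting {setting_id}/{relation}: needs both positive and "
                "negative instances"
            )
        folds = stratified_kfold(labels, k=k, seed=seed)
        report.fold_assignments[f"setting{setting_id}:{relation}"] = [
            [indices[i] for i in test.tolist()] for _, test in folds
        ]
        y = np.asarray(labels)
        for level in levels:
            bags = [bags_by_level[level][i] for i in indices]
            for clf_kind in classifiers:
                fold_metrics: list[Metrics] = []
                for train_idx, test_idx in folds:
                    vocab = build_vocabulary([bags[i] for i in train_idx])
                    X_train = vectorize_all([bags[i] for i in train_idx], vocab)
                    X_test = vectorize_all([bags[i] for i in test_idx], vocab)
                    clf = make_classifier(clf_kind)
                    clf.fit(X_train, y[train_idx])
                    y_pred = clf.predict(X_test)
                    counts = confusion_from_predictions(y[test_idx], y_pred)
                    fold_metrics.append(compute_metrics(counts))
                mean = {
                    name: round(
                        float(np.mean([getattr(m, name) for m in fold_metrics])), 2
                    )
                    for name in ("accuracy", "precision", "recall", "f_score")
                }
                report.rows.append(
                    {
                        "relation": relation,
                        "setting": setting_id,
                        "feature_set": level.name,
                        "classifier": clf_kind,
                        "folds": [
                            {k2: round(v, 2) for k2, v in m.as_dict().items()}
                            for m in fold_metrics
                        ],
                        "mean": mean,
                    }
                )
    return report
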