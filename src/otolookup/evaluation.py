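"""Stratified k-fold retrieval evaluation harness.

Protocol: the database is split into k stratified folds; per fold, ~1/k
of the images (stratified by class) are held out as test queries and the
remainder is split 70/30 into train and validation sets.  The training
images are class-balanced by augmentation, the classification head is
fitted, a lookup table is built from the *original* training images
only, and every test image is queried at k ∈ {1,3,5,7,9} under both
Chebyshev and cosine distance.  Accuracy at k is the pooled fraction of
retrieved items whose label matches the query's; per-category precision,
recall and F1 are pooled over folds; accuracies are aggregated as
mean ± SD across folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .backbone import FeatureVector, TinyCNN, TrainConfig, fit_head
from .handcrafted import (
    HandcraftedConfig,
    HandcraftedScaler,
    baseline_score_table,
    compose_f1,
)
from .images import LabeledImage
from .preprocess import AugmentationSpec, balance_classes
from .retrieval import METRICS, LookupTable, build_lookup, retrieve

DEFAULT_KS = (1, 3, 5, 7, 9)


@dataclass(frozen=True)
class FoldSplit:
    """One fold: disjoint test / train / validation id sets."""

    fold: int
    test_ids: tuple[str, ...]
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.test_ids), set(self.train_ids), set(self.val_ids)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("test/train/validation sets must be pairwise disjoint")


def stratified_kfold(
    ids: list[str],
    labels: list[str],
    n_folds: int = 10,
    seed: int = 0,
    val_fraction: float = 0.3,
) -> list[FoldSplit]:
    """Stratified folds with a 70/30 train/validation split of the remainder.

    Across folds the test sets are disjoint and cover the database.
    Raises if any class has fewer members than ``n_folds``.
    """
    ids = list(ids)
    labels = list(labels)
    counts = pd.Series(labels).value_counts()
    too_small = counts[counts < n_folds]
    if not too_small.empty:
        raise ValueError(
            f"classes smaller than n_folds={n_folds}: {dict(too_small)}"
        )
    ids_arr = np.array(ids)
    labels_arr = np.array(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = []
    for fold, (rest_idx, test_idx) in enumerate(skf.split(ids_arr, labels_arr)):
        rest_ids = ids_arr[rest_idx]
        rest_labels = labels_arr[rest_idx]
        sub_seed = (seed * 1009 + fold) % (2**31 - 1)
        train_ids, val_ids = train_test_split(
            rest_ids,
            test_size=val_fraction,
            random_state=sub_seed,
            stratify=rest_labels,
        )
        splits.append(
            FoldSplit(
                fold,
                tuple(str(i) for i in ids_arr[test_idx]),
                tuple(str(i) for i in train_ids),
                tuple(str(i) for i in val_ids),
                seed,
            )
        )
    return splits


def retrieval_accuracy(results, query_labels: list[str]) -> float:
    """Pooled fraction of retrieved items matching their query's label."""
    if not results:
        raise ValueError("no query results")
    correct = 0
    total = 0
    for res, qlabel in zip(results, query_labels):
        if len(res.items) == 0:
            raise ValueError(f"query {res.query_id} retrieved nothing")
        correct += sum(1 for it in res.items if it.label == qlabel)
        total += len(res.items)
    return correct / total


def precision_recall(
    results,
    query_labels: list[str],
    database_labels: list[str],
    k: int,
    cap_recall_at_k: bool = False,
) -> dict[str, dict[str, float]]:
    """Per-category retrieval precision and recall at k.

    Precision for category c: correct retrievals for class-c queries over
    all items retrieved for class-c queries.  Recall: same numerator over
    the number of relevant database images (class-c database count per
    class-c query; with ``cap_recall_at_k`` the per-query denominator is
    capped at min(k, class count)).  Categories with no queries are
    omitted (undefined, not zero).
    """
    db_counts = pd.Series(list(database_labels)).value_counts().to_dict()
    stats: dict[str, dict[str, float]] = {}
    per_cat = {}
    for res, qlabel in zip(results, query_labels):
        row = per_cat.setdefault(qlabel, {"correct": 0, "retrieved": 0, "relevant": 0})
        row["correct"] += sum(1 for it in res.items if it.label == qlabel)
        row["retrieved"] += len(res.items)
        n_rel = db_counts.get(qlabel, 0)
        row["relevant"] += min(k, n_rel) if cap_recall_at_k else n_rel
    for cat, row in per_cat.items():
        precision = row["correct"] / row["retrieved"] if row["retrieved"] else 0.0
        recall = row["correct"] / row["relevant"] if row["relevant"] else 0.0
        stats[cat] = {"precision": precision, "recall": recall}
    return stats


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} {v} outside [0, 1]")
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def multiclass_accuracy(
    predicted: list[str], true: list[str], average: str = "micro"
) -> float:
    """(TP + TN) / total accuracy, binarized one-vs-rest per class.

    ``micro`` (default) pools TP/TN counts over the C binary problems;
    ``macro`` averages per-class accuracies; ``fraction`` is the plain
    fraction of correct predictions.
    """
    if len(predicted) != len(true):
        raise ValueError("predicted and true label lists must align")
    pred = np.array(predicted)
    truth = np.array(true)
    n = len(truth)
    if average == "fraction":
        return float(np.mean(pred == truth))
    classes = sorted(set(truth) | set(pred))
    per_class = []
    for c in classes:
        tp = int(np.sum((pred == c) & (truth == c)))
        tn = int(np.sum((pred != c) & (truth != c)))
        per_class.append((tp, tn))
    if average == "micro":
        return sum(tp + tn for tp, tn in per_class) / (len(classes) * n)
    if average == "macro":
        return float(np.mean([(tp + tn) / n for tp, tn in per_class]))
    raise ValueError(f"unknown average {average!r}")


@dataclass
class ExperimentConfig:
    """Everything that parameterizes one cross-validated experiment."""

    method: str = "deep"  # deep | knn | svm | random
    n_folds: int = 10
    seed: int = 0
    ks: tuple[int, ...] = DEFAULT_KS
    metrics: tuple[str, ...] = METRICS
    balance: bool = True
    use_bias: bool = True
    normalize: bool = False
    train: TrainConfig = field(default_factory=TrainConfig)
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    handcrafted: HandcraftedConfig = field(default_factory=HandcraftedConfig)
    backbone_input_size: tuple[int, int] = (32, 32)
    backbone_feature_dim: int = 32
    baseline_params: dict = field(default_factory=dict)
    #: image ids discarded from the experiment (e.g. out-of-focus frames)
    exclude_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in ("deep", "knn", "svm", "random"):
            raise ValueError(f"unknown method {self.method!r}")
        if not self.ks:
            raise ValueError("ks must be non-empty")
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}")


@dataclass
class RetrievalEvalReport:
    """Cross-validated retrieval results.

    ``per_fold``: long-format accuracy per (fold, metric, k).
    ``per_category``: precision/recall/F1 per (metric, k, category),
    pooled over folds.  ``validation_accuracy``: final per-fold
    validation classification accuracy (deep method only).
    """

    method: str
    seed: int
    per_fold: pd.DataFrame
    per_category: pd.DataFrame
    validation_accuracy: list[float]

    def summary(self) -> pd.DataFrame:
        """Mean and sample SD of accuracy across folds, per (metric, k)."""
        g = self.per_fold.groupby(["metric", "k"])["accuracy"]
        out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        return out.reset_index()

    def mean_accuracy(self, metric: str, k: int) -> float:
        s = self.summary()
        row = s[(s["metric"] == metric) & (s["k"] == k)]
        if row.empty:
            raise KeyError(f"no cell for metric={metric}, k={k}")
        return float(row["mean"].iloc[0])

    def max_f1(self) -> float:
        return float(self.per_category["f1"].max())

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_fold.to_csv(out_dir / "accuracy_per_fold.csv", index=False)
        self.per_category.to_csv(out_dir / "per_category.csv", index=False)
        summary = self.summary()
        summary.to_csv(out_dir / "accuracy_summary.csv", index=False)
        payload = {
            "method": self.method,
            "seed": self.seed,
            "validation_accuracy": self.validation_accuracy,
            "summary": summary.to_dict(orient="records"),
        }
        (out_dir / "report.json").write_text(json.dumps(payload, indent=2))


def _deep_fold_tables(images_by_id, splits, config):
    """Per fold: fit the FC head, return (lookup table, query score matrix)."""
    base = TinyCNN(
        input_size=config.backbone_input_size,
        feature_dim=config.backbone_feature_dim,
        seed=config.seed,
    )
    # Conv stages are frozen and identical across folds, so pooled
    # features of the original images can be extracted once.
    feats = {iid: base.pooled_features(img.pixels) for iid, img in images_by_id.items()}
    label_idx = {c: i for i, c in enumerate(base.class_order)}
    out = []
    val_accs = []
    for split in splits:
        model = base.copy()
        train_imgs = [images_by_id[i] for i in split.train_ids]
        if config.balance:
            aug = AugmentationSpec(
                **{
                    **config.augmentation.__dict__,
                    "seed": (config.seed * 9973 + split.fold) % (2**31 - 1),
                }
            )
            train_imgs = balance_classes(train_imgs, aug)
        X_tr = np.stack(
            [
                feats[img.id] if img.id in feats else model.pooled_features(img.pixels)
                for img in train_imgs
            ]
        )
        y_tr = np.array([label_idx[img.label] for img in train_imgs])
        X_va = np.stack([feats[i] for i in split.val_ids])
        y_va = np.array([label_idx[images_by_id[i].label] for i in split.val_ids])
        cfg = TrainConfig(
            epochs=config.train.epochs,
            batch_size=config.train.batch_size,
            learning_rate=config.train.learning_rate,
            seed=(config.train.seed * 7919 + split.fold) % (2**31 - 1),
            retrain_layer_count=config.train.retrain_layer_count,
        )
        history = fit_head(model, X_tr, y_tr, X_va, y_va, cfg)
        val_accs.append(history[-1] if history else float("nan"))
        pw = model.projection()
        fvs = [FeatureVector(feats[i], i) for i in split.train_ids]
        table = build_lookup(
            fvs,
            [images_by_id[i].label for i in split.train_ids],
            pw,
            use_bias=config.use_bias,
            normalize=config.normalize,
        )
        queries = np.stack(
            [feats[i] @ pw.W + (pw.b if config.use_bias else 0.0) for i in split.test_ids]
        )
        out.append((table, queries))
    return out, val_accs


def _baseline_fold_tables(images_by_id, splits, config):
    raw = {
        iid: compose_f1(img, config.handcrafted).values
        for iid, img in images_by_id.items()
    }
    out = []
    for split in splits:
        train_imgs = [images_by_id[i] for i in split.train_ids]
        if config.balance:
            aug = AugmentationSpec(
                **{
                    **config.augmentation.__dict__,
                    "seed": (config.seed * 9973 + split.fold) % (2**31 - 1),
                }
            )
            train_imgs = balance_classes(train_imgs, aug)
        fit_vectors = np.stack(
            [
                raw[img.id]
                if img.id in raw
                else compose_f1(img, config.handcrafted).values
                for img in train_imgs
            ]
        )
        scaler = HandcraftedScaler().fit(fit_vectors)
        table_raw = np.stack([raw[i] for i in split.train_ids])
        params = dict(config.baseline_params)
        params.setdefault("seed", config.seed)
        _, score_fn = baseline_score_table(
            scaler.transform(fit_vectors),
            [img.label for img in train_imgs],
            method=config.method,
            params=params,
        )
        train_scores = score_fn(scaler.transform(table_raw))
        # Rebuild the table over the original (unaugmented) training
        # images so the retrieval database matches the deep pipeline's.
        classes = tuple(sorted({img.label for img in train_imgs}))
        table = LookupTable(
            train_scores,
            tuple(split.train_ids),
            tuple(images_by_id[i].label for i in split.train_ids),
            classes,
        )
        queries = score_fn(scaler.transform(np.stack([raw[i] for i in split.test_ids])))
        out.append((table, queries))
    return out, []


def _random_fold_tables(images_by_id, splits, config):
    """Null baseline: class scores replaced by seeded Gaussian noise."""
    out = []
    for split in splits:
        rng = np.random.default_rng((config.seed * 6151 + split.fold) % (2**31 - 1))
        classes = tuple(sorted({img.label for img in images_by_id.values()}))
        rows = rng.normal(size=(len(split.train_ids), len(classes)))
        table = LookupTable(
            rows,
            tuple(split.train_ids),
            tuple(images_by_id[i].label for i in split.train_ids),
            classes,
        )
        queries = rng.normal(size=(len(split.test_ids), len(classes)))
        out.append((table, queries))
    return out, []


def run_experiment(
    images: list[LabeledImage], config: ExperimentConfig
) -> RetrievalEvalReport:
    """Cross-validated retrieval evaluation of one method.

    Builds fold splits, fits the method per fold (deep FC head, KNN/SVM
    on handcrafted features, or the random null), queries every test
    image at each k under each metric, and aggregates accuracy and
    per-category precision/recall/F1.
    """
    if config.exclude_ids:
        dropped = set(config.exclude_ids)
        images = [img for img in images if img.id not in dropped]
    images_by_id = {img.id: img for img in images}
    if len(images_by_id) != len(images):
        raise ValueError("duplicate image ids")
    ids = [img.id for img in images]
    labels = [img.label for img in images]
    splits = stratified_kfold(ids, labels, config.n_folds, config.seed)

    builders = {
        "deep": _deep_fold_tables,
        "knn": _baseline_fold_tables,
        "svm": _baseline_fold_tables,
        "random": _random_fold_tables,
    }
    fold_tables, val_accs = builders[config.method](images_by_id, splits, config)

    per_fold_rows = []
    cat_counts: dict[tuple, dict] = {}
    for split, (table, queries) in zip(splits, fold_tables):
        q_labels = [images_by_id[i].label for i in split.test_ids]
        db_labels = list(table.labels)
        for metric in config.metrics:
            for k in config.ks:
                results = [
                    retrieve(q, table, k, metric, query_id=qid)
                    for q, qid in zip(queries, split.test_ids)
                ]
                acc = retrieval_accuracy(results, q_labels)
                per_fold_rows.append(
                    {"fold": split.fold, "metric": metric, "k": k, "accuracy": acc}
                )
                db_counts = pd.Series(db_labels).value_counts().to_dict()
                for res, ql in zip(results, q_labels):
                    key = (metric, k, ql)
                    row = cat_counts.setdefault(
                        key, {"correct": 0, "retrieved": 0, "relevant": 0}
                    )
                    row["correct"] += sum(1 for it in res.items if it.label == ql)
                    row["retrieved"] += len(res.items)
                    row["relevant"] += db_counts.get(ql, 0)

    cat_rows = []
    for (metric, k, cat), row in sorted(cat_counts.items()):
        precision = row["correct"] / row["retrieved"] if row["retrieved"] else 0.0
        recall = row["correct"] / row["relevant"] if row["relevant"] else 0.0
        cat_rows.append(
            {
                "metric": metric,
                "k": k,
                "category": cat,
                "precision": precision,
                "recall": recall,
                "f1": f1_score(precision, recall),
            }
        )

    return RetrievalEvalReport(
        method=config.method,
        seed=config.seed,
        per_fold=pd.DataFrame(per_fold_rows),
        per_category=pd.DataFrame(cat_rows),
        validation_accuracy=val_accs,
    )
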