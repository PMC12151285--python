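"""Splitting, minority augmentation, model fitting and evaluation.

Four model families are supported, mirroring a typical subtype-prediction
benchmark: one-vs-rest logistic regression, k-nearest neighbours (k=4),
random forest, and a feed-forward network (three ReLU hidden layers, softmax
output, Adam, cross-entropy loss).  Features are standardised on training
statistics only; augmentation likewise touches the training partition only —
the test rows leave the pipeline bit-identical to how they entered it.

Class imbalance is handled with ADASYN-style adaptive oversampling: synthetic
minority points are convex combinations of same-class neighbour pairs, with
more points synthesised near minority samples whose neighbourhoods are
dominated by other classes (the hard-to-learn regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from gainet.io_formats import LabelTable, OmicsMatrix

MODEL_FAMILIES = ("logistic_ovr", "knn", "random_forest", "feedforward_net")


class ClassifyError(ValueError):
    pass


@dataclass
class SplitSpec:
    """A stratified train/test partition of sample ids."""

    train_sample_ids: list[str]
    test_sample_ids: list[str]
    test_fraction: float = 0.2
    seed: int = 0
    stratified: bool = True


@dataclass
class ModelSpec:
    """A model family plus its (validated) hyperparameters."""

    model: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)

    _KNOWN = {
        "logistic_ovr": {"max_iter", "C", "seed"},
        "knn": {"knn_neighbors"},
        "random_forest": {"n_estimators", "max_depth", "seed"},
        "feedforward_net": {
            "n_hidden_layers",
            "hidden_sizes",
            "activation",
            "epochs",
            "batch_size",
            "seed",
        },
    }

    def __post_init__(self) -> None:
        if self.model not in MODEL_FAMILIES:
            raise ClassifyError(
                f"unknown model {self.model!r}; choose one of {MODEL_FAMILIES}"
            )
        unknown = set(self.hyperparameters) - self._KNOWN[self.model]
        if unknown:
            raise ClassifyError(
                f"unknown hyperparameter(s) {sorted(unknown)} for model {self.model!r}"
            )

    def build(self) -> Pipeline:
        """Instantiate the sklearn estimator behind a train-fit scaler."""
        hp = self.hyperparameters
        seed = hp.get("seed", 0)
        if self.model == "logistic_ovr":
            est = OneVsRestClassifier(
                LogisticRegression(max_iter=hp.get("max_iter", 1000), C=hp.get("C", 1.0))
            )
        elif self.model == "knn":
            est = KNeighborsClassifier(n_neighbors=hp.get("knn_neighbors", 4))
        elif self.model == "random_forest":
            est = RandomForestClassifier(
                n_estimators=hp.get("n_estimators", 100),
                max_depth=hp.get("max_depth"),
                random_state=seed,
            )
        else:  # feedforward_net: 3 ReLU hidden layers, softmax output, Adam, CE loss
            sizes = tuple(hp.get("hidden_sizes", (256, 128, 64)))
            est = MLPClassifier(
                hidden_layer_sizes=sizes,
                activation=hp.get("activation", "relu"),
                solver="adam",
                max_iter=hp.get("epochs", 200),
                batch_size=hp.get("batch_size", "auto"),
                random_state=seed,
            )
        return Pipeline([("scale", StandardScaler()), ("model", est)])


@dataclass
class EvalReport:
    """Per-class precision/recall/F1, accuracy and one-vs-rest AUROCs.

    Empty denominators follow the zero convention (an unpredicted class has
    precision and F1 of 0); the overall AUROC is the unweighted mean of the
    per-class one-vs-rest AUROCs, skipping classes that the test partition
    cannot score (no positives or no negatives).
    """

    classes: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    auroc_per_class: dict[str, float]
    auroc_macro: float
    confusion: pd.DataFrame

    @property
    def macro_f1(self) -> float:
        return float(np.mean([self.f1[c] for c in self.classes]))

    def to_frame(self) -> pd.DataFrame:
        rows = {
            c: {
                "precision": self.precision[c],
                "recall": self.recall[c],
                "f1": self.f1[c],
                "auroc": self.auroc_per_class[c],
            }
            for c in self.classes
        }
        df = pd.DataFrame(rows).T
        df.index.name = "class"
        return df

    def summary(self) -> str:
        lines = [self.to_frame().round(4).to_string()]
        lines.append(f"accuracy     {self.accuracy:.4f}")
        lines.append(f"macro F1     {self.macro_f1:.4f}")
        lines.append(f"macro AUROC  {self.auroc_macro:.4f}")
        return "\n".join(lines)


def stratified_split(
    labels: LabelTable, test_fraction: float = 0.2, seed: int = 0
) -> SplitSpec:
    """Deterministic stratified split of the labelled samples.

    Per-class test counts differ from class_count * test_fraction by at most
    one.  A class with fewer than 2 samples cannot be stratified and raises.
    """
    ids = labels.table["sample_id"].to_numpy()
    y = labels.table["class_label"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    for c, n in zip(classes, counts):
        if n < 2:
            raise ClassifyError(f"class {c!r} has {n} sample(s); cannot stratify")
    train_ids, test_ids = train_test_split(
        ids, test_size=test_fraction, random_state=seed, stratify=y
    )
    return SplitSpec(list(train_ids), list(test_ids), test_fraction, seed, True)


def augment_minority(
    train_X: np.ndarray,
    train_y: np.ndarray,
    seed: int = 0,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """ADASYN-style adaptive oversampling of the minority classes.

    For every class smaller than the majority, synthesise enough points to
    reach the majority count.  Each minority sample x_i receives a share of
    the synthetic budget proportional to the fraction of its k nearest
    neighbours (in the full training set) that belong to other classes, so
    sparse, boundary-adjacent regions are densified most.  A synthetic point
    is x_i + u * (x_z - x_i) with u ~ U(0, 1) and x_z one of x_i's k nearest
    same-class neighbours.  Original rows are returned unchanged, first.

    Classes too small for neighbour search fall back to duplication with a
    warning.  Deterministic given ``seed``.
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y)
    if X.ndim != 2 or len(X) != len(y):
        raise ClassifyError("train_X must be 2-D with one row per label")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ClassifyError("augmentation requires at least 2 classes")
    majority = counts.max()
    rng = np.random.default_rng(seed)

    new_X, new_y = [X], [y]
    if (counts == majority).all():
        return X.copy(), y.copy()

    # neighbour model over the full training set, for the density weights
    k_full = min(k_neighbors, len(X) - 1)
    nn_full = NearestNeighbors(n_neighbors=k_full + 1).fit(X)

    for c, n_c in zip(classes, counts):
        G = int(majority - n_c)
        if G <= 0:
            continue
        members = np.flatnonzero(y == c)
        Xc = X[members]
        if n_c < 2 or n_c - 1 < 1:
            warnings.warn(
                f"class {c!r} too small for neighbour interpolation; duplicating rows"
            )
            dup = rng.choice(len(Xc), size=G, replace=True)
            new_X.append(Xc[dup])
            new_y.append(np.full(G, c, dtype=y.dtype))
            continue

        # density weights: fraction of other-class points among k nearest
        _, idx = nn_full.kneighbors(Xc)
        neigh = idx[:, 1:]  # drop self
        r = (y[neigh] != c).mean(axis=1)
        if r.sum() == 0:
            weights = np.full(n_c, 1.0 / n_c)
        else:
            weights = r / r.sum()

        # integer allocation summing exactly to G, largest-weight classes first
        alloc = np.floor(weights * G).astype(int)
        remainder = G - alloc.sum()
        if remainder > 0:
            order = np.argsort(-(weights * G - alloc), kind="stable")
            alloc[order[:remainder]] += 1

        # same-class neighbours for the interpolation partner
        k_same = min(k_neighbors, n_c - 1)
        nn_same = NearestNeighbors(n_neighbors=k_same + 1).fit(Xc)
        _, same_idx = nn_same.kneighbors(Xc)
        same_idx = same_idx[:, 1:]

        synth = np.empty((G, X.shape[1]))
        pos = 0
        for i in range(n_c):
            for _ in range(alloc[i]):
                z = same_idx[i, rng.integers(0, k_same)]
                u = rng.random()
                synth[pos] = Xc[i] + u * (Xc[z] - Xc[i])
                pos += 1
        new_X.append(synth)
        new_y.append(np.full(G, c, dtype=y.dtype))

    return np.vstack(new_X), np.concatenate(new_y)


def concatenate_features(ms: list[OmicsMatrix]) -> pd.DataFrame:
    """Early-integration baseline: stack omics side by side, samples as rows.

    Feature names are prefixed with the omics kind so ids never collide.
    All matrices must share an identically ordered sample list.
    """
    if not ms:
        raise ClassifyError("no matrices to concatenate")
    ref = ms[0].sample_ids
    blocks = []
    for m in ms:
        if m.sample_ids != ref:
            raise ClassifyError("matrices are not sample-aligned; intersect them first")
        df = m.to_frame().T  # samples x features
        df.columns = [f"{m.kind.value}:{f}" for f in m.feature_ids]
        blocks.append(df)
    return pd.concat(blocks, axis=1)


def fit_predict(
    spec: ModelSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the model (scaler fit on train only) and score the test rows.

    Returns (predicted labels, class-score matrix, class order).  Score rows
    of probabilistic models sum to 1.
    """
    pipe = spec.build()
    pipe.fit(np.asarray(train_X, dtype=float), np.asarray(train_y))
    test_X = np.asarray(test_X, dtype=float)
    pred = pipe.predict(test_X)
    scores = pipe.predict_proba(test_X)
    classes = pipe.named_steps["model"].classes_
    return pred, scores, np.asarray(classes)


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
    classes: np.ndarray | None = None,
) -> EvalReport:
    """Per-class precision/recall/F1, accuracy, confusion and OvR AUROCs."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    acc = accuracy_score(y_true, y_pred)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    cm_df = pd.DataFrame(cm, index=classes, columns=classes)

    aurocs: dict[str, float] = {}
    if scores is not None:
        for j, c in enumerate(classes):
            pos = y_true == c
            if pos.all() or not pos.any():
                aurocs[str(c)] = float("nan")
            else:
                aurocs[str(c)] = float(roc_auc_score(pos.astype(int), scores[:, j]))
    else:
        aurocs = {str(c): float("nan") for c in classes}
    finite = [v for v in aurocs.values() if np.isfinite(v)]
    macro_auc = float(np.mean(finite)) if finite else float("nan")

    cls = [str(c) for c in classes]
    return EvalReport(
        classes=cls,
        precision=dict(zip(cls, prec.astype(float))),
        recall=dict(zip(cls, rec.astype(float))),
        f1=dict(zip(cls, f1.astype(float))),
        accuracy=float(acc),
        auroc_per_class=aurocs,
        auroc_macro=macro_auc,
        confusion=cm_df,
    )


def cross_validate(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    augment: bool = False,
) -> list[EvalReport]:
    """Stratified k-fold evaluation; augmentation runs inside each training fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, ytr = X[tr], y[tr]
        if augment:
            Xtr, ytr = augment_minority(Xtr, ytr, seed=seed + fold)
        pred, scores, classes = fit_predict(spec, Xtr, ytr, X[te])
        reports.append(evaluate(y[te], pred, scores, classes))
    return reports
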