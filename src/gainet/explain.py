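"""Feature-importance ranking and the gene annotation filter cascade.

Importance comes from one of two backends: ``shapley_tree`` (exact
path-dependent Shapley values over a fitted tree ensemble, the default) or
``permutation`` (model-agnostic score drop under feature shuffling).  Ranked
genes then pass through a deleteriousness cascade — SIFT in [0, 0.05] OR
PolyPhen in [0.85, 1.0], both windows inclusive, AND a haploinsufficiency
score strictly above 0 — and finally per-subtype gene lists are reduced to
their unique/shared structure by exact set algebra (Venn logic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance

from gainet._treeshap import tree_shap_values
from gainet.io_formats import AnnotationTable


class ExplainError(ValueError):
    pass


@dataclass
class ImportanceRanking:
    """Features sorted by global importance, with optional per-class scores."""

    table: pd.DataFrame  # columns: feature_id, importance[, <class> ...]
    backend: str = "shapley_tree"

    def __post_init__(self) -> None:
        imp = self.table["importance"].to_numpy(dtype=float)
        if not np.all(np.isfinite(imp)):
            raise ExplainError("importance scores must be finite")
        if np.any(np.diff(imp) > 0):
            raise ExplainError("importance table must be sorted descending")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table["feature_id"])

    def top(self, k: int) -> list[str]:
        return self.feature_ids[:k]

    def per_class_top(self, class_label: str, k: int) -> list[str]:
        if class_label not in self.table.columns:
            raise ExplainError(f"no per-class scores for {class_label!r}")
        order = self.table.sort_values(class_label, ascending=False, kind="stable")
        return list(order["feature_id"].head(k))


def rank_features(
    model,
    train_X: np.ndarray,
    train_y: np.ndarray,
    feature_ids: list[str],
    backend: str = "shapley_tree",
    top_k: int | None = None,
    seed: int = 0,
    n_repeats: int = 5,
) -> ImportanceRanking:
    """Rank features by importance for a fitted classifier.

    ``shapley_tree`` computes per-sample Shapley attributions on the training
    rows; the global importance of a feature is the mean absolute attribution
    over samples and classes, and per-class columns carry the per-class mean
    absolute attribution.  ``permutation`` uses seeded accuracy-drop
    importance (per-class columns are the drops in per-class recall).
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    if len(feature_ids) != train_X.shape[1]:
        raise ExplainError("feature_ids length must match the matrix width")

    classes = np.asarray(getattr(model, "classes_", np.unique(train_y)))
    per_class: dict[str, np.ndarray] = {}

    if backend == "shapley_tree":
        phi, _ = tree_shap_values(model, train_X)  # raises TypeError for non-trees
        abs_phi = np.abs(phi)  # (n_samples, n_features, n_classes)
        importance = abs_phi.mean(axis=(0, 2))
        if abs_phi.shape[2] == len(classes):
            for j, c in enumerate(classes):
                per_class[str(c)] = abs_phi[:, :, j].mean(axis=0)
    elif backend == "permutation":
        res = permutation_importance(
            model, train_X, train_y, n_repeats=n_repeats, random_state=seed
        )
        importance = res.importances_mean
        for c in classes:
            mask = train_y == c
            if mask.sum() == 0:
                continue
            res_c = permutation_importance(
                model, train_X[mask], train_y[mask], n_repeats=n_repeats, random_state=seed
            )
            per_class[str(c)] = res_c.importances_mean
    else:
        raise ExplainError(f"unknown importance backend {backend!r}")

    df = pd.DataFrame({"feature_id": feature_ids, "importance": importance})
    for c, v in per_class.items():
        df[c] = v
    df = df.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k).reset_index(drop=True)
    return ImportanceRanking(df, backend)


def permutation_importance_std(
    model, X: np.ndarray, y: np.ndarray, seed: int = 0, n_repeats: int = 5
) -> pd.DataFrame:
    """Mean and SD of seeded permutation importances (for noise-band checks)."""
    res = permutation_importance(model, X, y, n_repeats=n_repeats, random_state=seed)
    return pd.DataFrame({"mean": res.importances_mean, "sd": res.importances_std})


def filter_by_annotation(
    genes: list[str],
    ann: AnnotationTable,
    sift_window: tuple[float, float] = (0.0, 0.05),
    polyphen_window: tuple[float, float] = (0.85, 1.0),
    hi_threshold: float = 0.0,
    logic: str = "or",
) -> tuple[list[str], list[str]]:
    """Keep genes with a damaging variant annotation and nonzero dosage sensitivity.

    A gene passes iff (SIFT present and inside ``sift_window``) OR (PolyPhen
    present and inside ``polyphen_window``) — switchable to AND — and its
    haploinsufficiency score is present and strictly above ``hi_threshold``.
    Windows are inclusive at both ends.  Returns (passing genes in input
    order, genes dropped because every score was missing).
    """
    if logic not in ("or", "and"):
        raise ExplainError("logic must be 'or' or 'and'")
    t = ann.table.set_index("gene_id")
    kept: list[str] = []
    all_missing: list[str] = []
    for g in genes:
        if g not in t.index:
            all_missing.append(g)
            continue
        row = t.loc[g]
        sift, poly, hi = row["sift"], row["polyphen"], row["haploinsufficiency"]
        if pd.isna(sift) and pd.isna(poly) and pd.isna(hi):
            all_missing.append(g)
            continue
        sift_ok = not pd.isna(sift) and sift_window[0] <= sift <= sift_window[1]
        poly_ok = not pd.isna(poly) and polyphen_window[0] <= poly <= polyphen_window[1]
        damaging = (sift_ok or poly_ok) if logic == "or" else (sift_ok and poly_ok)
        hi_ok = not pd.isna(hi) and hi > hi_threshold
        if damaging and hi_ok:
            kept.append(g)
    return kept, all_missing


@dataclass
class SubtypeSets:
    """Unique/shared structure of per-class gene lists."""

    unique: dict[str, set[str]]
    pairwise: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    all_shared: set[str] = field(default_factory=set)
    union: set[str] = field(default_factory=set)


def subtype_unique_sets(per_class_gene_lists: dict[str, list[str]]) -> SubtypeSets:
    """Exact Venn decomposition of per-class gene lists.

    ``unique[c]`` holds genes found in class c and no other; ``pairwise``
    the pairwise intersections; ``all_shared`` the genes common to every
    class.
    """
    sets = {c: set(g) for c, g in per_class_gene_lists.items()}
    names = sorted(sets)
    union: set[str] = set().union(*sets.values()) if sets else set()
    unique = {
        c: {g for g in sets[c] if not any(g in sets[o] for o in names if o != c)}
        for c in names
    }
    pairwise = {
        (a, b): sets[a] & sets[b] for i, a in enumerate(names) for b in names[i + 1 :]
    }
    all_shared = set.intersection(*sets.values()) if sets else set()
    return SubtypeSets(unique=unique, pairwise=pairwise, all_shared=all_shared, union=union)
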