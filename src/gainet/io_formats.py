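"""Tabular input/output for omics matrices, edge tables, labels and run config.

Conventions (fixed, no auto-detection):

* Matrices are features x samples, first column = feature ids, header row =
  sample ids.  Tab-separated by default; comma via ``sep=","``.
* Missing markers are ``NA``, ``NaN`` and the empty string.  Zero is a value,
  never a missing marker — the preprocessing filters count zeros and missing
  entries separately.
* Orientation is never guessed: a matrix is read exactly as stored.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

MISSING_MARKERS = ["NA", "NaN", ""]


class OmicsKind(str, enum.Enum):
    """What a features-by-samples matrix holds; drives validation rules."""

    MRNA_COUNTS = "mrna_counts"
    MIRNA_COUNTS = "mirna_counts"
    METHYLATION_BETA = "methylation_beta"


class FormatError(ValueError):
    """Structural problem in an input file (duplicates, missing columns)."""


class ValidationError(ValueError):
    """A parsed value violates the matrix kind's contract."""


@dataclass
class OmicsMatrix:
    """A features x samples real matrix with ids and an omics kind tag.

    ``values`` is a float ndarray; missing entries are NaN.  Invariants are
    checked on construction:

    * ids unique on both axes;
    * ``methylation_beta`` values in [0, 1] where present;
    * count matrices non-negative where present.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: OmicsKind

    def __post_init__(self) -> None:
        self.kind = OmicsKind(self.kind)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        self._validate_ranges()

    def _validate_ranges(self) -> None:
        vals = self.values
        with np.errstate(invalid="ignore"):
            if self.kind is OmicsKind.METHYLATION_BETA:
                bad = (vals < 0) | (vals > 1)
            else:
                bad = vals < 0
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"value {vals[i, j]!r} at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r} violates the "
                f"{self.kind.value} range contract"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: OmicsKind | str) -> "OmicsMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), OmicsKind(kind))

    def subset(
        self,
        feature_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "OmicsMatrix":
        """Return a new matrix restricted (and reordered) to the given ids."""
        df = self.to_frame()
        if feature_ids is not None:
            df = df.loc[list(feature_ids)]
        if sample_ids is not None:
            df = df[list(sample_ids)]
        return OmicsMatrix.from_frame(df, self.kind)


def _check_unique(ids: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {axis} id {x!r}")
        seen.add(x)


def read_omics_matrix(path: str | Path, kind: OmicsKind | str, sep: str = "\t") -> OmicsMatrix:
    """Read a features x samples matrix from delimited text.

    First column holds feature ids, header row holds sample ids; ``NA``,
    ``NaN`` and empty cells are missing.  Raises :class:`FormatError` on
    duplicate ids and :class:`ValidationError` on out-of-range values,
    naming the offending cell.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=MISSING_MARKERS,
        keep_default_na=False,
        dtype=str,
    )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    return OmicsMatrix([str(i) for i in df.index], [str(c) for c in df.columns], values, kind)


def write_omics_matrix(m: OmicsMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix as delimited text; missing entries become ``NA``."""
    m.to_frame().to_csv(path, sep=sep, na_rep="NA")


@dataclass
class InteractionTable:
    """miRNA→gene edges with a raw interaction-strength score.

    TargetScan-style raw scores are negative (more negative = stronger
    repression); after :func:`gainet.graph_transform.normalize_interaction_scores`
    the optional ``is_score`` column lies in [is_floor, 1].
    """

    table: pd.DataFrame  # columns: mirna_id, gene_id, raw_score[, is_score]

    REQUIRED = ("mirna_id", "gene_id", "raw_score")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"interaction table missing column(s) {missing}")
        dup = self.table.duplicated(subset=["mirna_id", "gene_id"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise FormatError(
                f"duplicate interaction pair ({row['mirna_id']!r}, {row['gene_id']!r})"
            )
        if not np.all(np.isfinite(self.table["raw_score"].to_numpy(dtype=float))):
            raise ValidationError("interaction raw_score contains non-finite values")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PromoterMap:
    """CpG→gene promoter assignments with distance to the TSS in bp."""

    table: pd.DataFrame  # columns: cpg_id, gene_id, tss_distance_bp

    REQUIRED = ("cpg_id", "gene_id", "tss_distance_bp")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"promoter map missing column(s) {missing}")
        dup = self.table.duplicated(subset=["cpg_id", "gene_id"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise FormatError(f"duplicate promoter pair ({row['cpg_id']!r}, {row['gene_id']!r})")
        dist = self.table["tss_distance_bp"].to_numpy(dtype=float)
        if np.any(dist < 0) or np.any(dist != np.floor(dist)):
            raise ValidationError("tss_distance_bp must be a nonnegative integer")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LabelTable:
    """Per-sample class labels (e.g. intrinsic subtype names)."""

    table: pd.DataFrame  # columns: sample_id, class_label

    REQUIRED = ("sample_id", "class_label")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"label table missing column(s) {missing}")
        dup = self.table.duplicated(subset=["sample_id"])
        if dup.any():
            raise FormatError(
                f"duplicate sample id {self.table[dup].iloc[0]['sample_id']!r} in labels"
            )
        if self.table["class_label"].nunique() < 2:
            raise ValidationError("label set must contain at least 2 classes")

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        mapping = dict(zip(self.table["sample_id"], self.table["class_label"]))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValidationError(f"samples without labels: {missing[:5]}")
        return np.array([mapping[s] for s in sample_ids])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AnnotationTable:
    """Per-gene deleteriousness / dosage-sensitivity scores.

    ``sift`` (0 = deleterious end), ``polyphen`` (1 = damaging end) and
    ``haploinsufficiency`` are each in [0, 1] when present, NaN when missing.
    """

    table: pd.DataFrame  # columns: gene_id, sift, polyphen, haploinsufficiency

    REQUIRED = ("gene_id", "sift", "polyphen", "haploinsufficiency")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"annotation table missing column(s) {missing}")
        if self.table.duplicated(subset=["gene_id"]).any():
            raise FormatError("duplicate gene id in annotation table")
        for col in ("sift", "polyphen", "haploinsufficiency"):
            v = self.table[col].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if np.any((v < 0) | (v > 1)):
                    raise ValidationError(f"{col} scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.table)


def _read_table(path: str | Path, required: Sequence[str], sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, na_values=MISSING_MARKERS, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_interaction_table(path: str | Path, sep: str = "\t") -> InteractionTable:
    return InteractionTable(_read_table(path, InteractionTable.REQUIRED, sep))


def read_promoter_map(path: str | Path, sep: str = "\t") -> PromoterMap:
    return PromoterMap(_read_table(path, PromoterMap.REQUIRED, sep))


def read_labels(path: str | Path, sep: str = "\t") -> LabelTable:
    df = _read_table(path, LabelTable.REQUIRED, sep)
    return LabelTable(df.astype({"sample_id": str, "class_label": str}))


def read_annotations(path: str | Path, sep: str = "\t") -> AnnotationTable:
    return AnnotationTable(_read_table(path, AnnotationTable.REQUIRED, sep))


@dataclass
class RunConfig:
    """Every tunable of the pipeline in one flat, serialisable record.

    Unknown keys are rejected on load so silent typos cannot change a run.
    """

    # preprocessing
    max_bad_fraction: float = 0.20
    tss_window_bp: int = 1500
    beta_floor: float = 1e-3
    # transform (see graph_transform.TransformConfig)
    alpha: float = 1.5
    beta_exp: float = 1.5
    w1: float = 1.0
    w2: float = 1.0
    expr_pseudocount: float = 1.0
    is_floor: float = 0.01
    missing_partner_policy: str = "fallback"
    log2_expression: bool = False
    # classification
    model: str = "random_forest"
    test_fraction: float = 0.2
    n_folds: int = 5
    augment: bool = False
    knn_neighbors: int = 4
    hidden_sizes: tuple[int, ...] = (256, 128, 64)
    net_epochs: int = 200
    # explanation
    importance_backend: str = "shapley_tree"
    top_k: int = 50
    sift_window: tuple[float, float] = (0.0, 0.05)
    polyphen_window: tuple[float, float] = (0.85, 1.0)
    annotation_logic: str = "or"
    # survival
    alpha_level: float = 0.05
    split_quantile: float = 0.5
    # reproducibility
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("hidden_sizes", "sift_window", "polyphen_window"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
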