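"""End-to-end orchestration: preprocess → transform → classify → explain → survival.

``run_pipeline`` executes the stages in a fixed order on either an in-memory
:class:`~gainet.synthetic.FixtureBundle` or a directory of TSV inputs, writes
every stage's outputs as TSV plus a JSON run manifest, and derives each
stage's seed from the global seed as ``seed + stage_index`` so stages can be
re-run in isolation.  All stage outputs are pure functions of (inputs,
config, seed); re-running a config reproduces them byte-identically, which
the manifest digest makes checkable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import gainet
from gainet.classify import (
    ModelSpec,
    augment_minority,
    concatenate_features,
    evaluate,
    fit_predict,
    stratified_split,
)
from gainet.explain import filter_by_annotation, rank_features, subtype_unique_sets
from gainet.graph_transform import (
    TransformConfig,
    build_graphs,
    normalize_interaction_scores,
    transform_matrix,
)
from gainet.io_formats import (
    OmicsKind,
    RunConfig,
    read_annotations,
    read_interaction_table,
    read_labels,
    read_omics_matrix,
    read_promoter_map,
)
from gainet.preprocess import preprocess_all
from gainet.survival import SurvivalRecords, read_survival, screen_genes
from sklearn.model_selection import StratifiedKFold

STAGES = ("preprocess", "transform", "split", "train", "explain", "survival")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    """Auditable record of one pipeline run.

    ``digest()`` hashes the deterministic content (everything except the
    wall-clock timestamp), so two runs of the same config and seed can be
    compared byte-for-byte.
    """

    config: dict
    seeds: dict[str, int]
    input_digests: dict[str, str]
    stage_counts: dict[str, dict]
    output_paths: dict[str, str]
    version: str = gainet.__version__
    timestamp: float = field(default_factory=time.time)

    def deterministic_dict(self) -> dict:
        d = {
            "config": self.config,
            "seeds": self.seeds,
            "input_digests": self.input_digests,
            "stage_counts": self.stage_counts,
            "output_paths": self.output_paths,
            "version": self.version,
        }
        return d

    def digest(self) -> str:
        blob = json.dumps(self.deterministic_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def to_file(self, path: str | Path) -> None:
        d = self.deterministic_dict()
        d["timestamp"] = self.timestamp
        d["digest"] = self.digest()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_seed(seed: int, stage: str) -> int:
    return int(seed) + STAGES.index(stage)


def load_inputs(input_dir: str | Path) -> dict:
    """Read the standard TSV bundle layout from a directory."""
    d = Path(input_dir)
    required = ["mrna.tsv", "mirna.tsv", "meth.tsv", "interactions.tsv",
                "promoter_map.tsv", "labels.tsv"]
    missing = [f for f in required if not (d / f).exists()]
    if missing:
        raise PipelineError("preflight", f"missing input file(s): {missing}")
    inputs = {
        "mrna": read_omics_matrix(d / "mrna.tsv", OmicsKind.MRNA_COUNTS),
        "mirna": read_omics_matrix(d / "mirna.tsv", OmicsKind.MIRNA_COUNTS),
        "meth": read_omics_matrix(d / "meth.tsv", OmicsKind.METHYLATION_BETA),
        "interactions": read_interaction_table(d / "interactions.tsv"),
        "promoter_map": read_promoter_map(d / "promoter_map.tsv"),
        "labels": read_labels(d / "labels.tsv"),
        "annotations": None,
        "survival": None,
    }
    if (d / "annotations.tsv").exists():
        inputs["annotations"] = read_annotations(d / "annotations.tsv")
    if (d / "survival.tsv").exists():
        inputs["survival"] = read_survival(d / "survival.tsv")
    return inputs


def pooled_cv_report(spec: ModelSpec, X, y, n_folds: int, seed: int, augment: bool = False):
    """Stratified k-fold CV with predictions pooled into one evaluation.

    Pooling the held-out predictions of every fold gives one confusion
    matrix over all samples, a lower-variance summary than averaging
    per-fold metrics on small classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    classes = np.unique(y)
    pred = np.empty(len(y), dtype=y.dtype)
    scores = np.zeros((len(y), len(classes)))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, ytr = X[tr], y[tr]
        if augment:
            Xtr, ytr = augment_minority(Xtr, ytr, seed=seed + fold)
        p, s, cls = fit_predict(spec, Xtr, ytr, X[te])
        pred[te] = p
        order = [list(cls).index(c) for c in classes]
        scores[te] = s[:, order]
    return evaluate(y, pred, scores, classes)


def run_pipeline(
    cfg: RunConfig,
    inputs: dict | None = None,
    input_dir: str | Path | None = None,
    out_dir: str | Path = "gainet_run",
) -> RunManifest:
    """Execute the full pipeline and write all outputs under ``out_dir``.

    ``inputs`` is a dict as produced by :func:`load_inputs` (or assembled
    from a :class:`~gainet.synthetic.FixtureBundle`); alternatively pass
    ``input_dir``.  Any stage failure raises :class:`PipelineError` naming
    the stage; partial outputs written before the failure are recorded in a
    ``FAILED`` marker file rather than silently kept.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_digests: dict[str, str] = {}
    if inputs is None:
        if input_dir is None:
            raise PipelineError("preflight", "either inputs or input_dir is required")
        input_digests = {
            p.name: _sha256(p) for p in sorted(Path(input_dir).glob("*.tsv"))
        }
        inputs = load_inputs(input_dir)

    seeds = {s: stage_seed(cfg.seed, s) for s in STAGES}
    counts: dict[str, dict] = {}
    paths: dict[str, str] = {}

    def _write_frame(df: pd.DataFrame, name: str, index: bool = True) -> None:
        p = out / name
        df.to_csv(p, sep="\t", na_rep="NA", index=index)
        paths[name] = str(p)

    try:
        # ---- stage 1: preprocess ------------------------------------------
        mrna, mirna, meth, pmap, report = preprocess_all(
            inputs["mrna"],
            inputs["mirna"],
            inputs["meth"],
            inputs["promoter_map"],
            max_bad_fraction=cfg.max_bad_fraction,
            tss_window_bp=cfg.tss_window_bp,
            beta_floor=cfg.beta_floor,
        )
        counts["preprocess"] = {
            "features_in": report.n_features_before,
            "features_out": report.n_features_after,
            "samples_in": report.n_samples_before,
            "samples_retained": len(report.samples_retained),
        }
        filt = pd.DataFrame(
            [
                {"omics": k, "axis": "feature", "removed_id": f}
                for k, v in report.features_removed.items()
                for f in v
            ]
            + [
                {"omics": k, "axis": "sample", "removed_id": s}
                for k, v in report.samples_removed.items()
                for s in v
            ]
        )
        _write_frame(filt, "filter_report.tsv", index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc

    try:
        # ---- stage 2: transform -------------------------------------------
        tcfg = TransformConfig(
            alpha=cfg.alpha,
            beta_exp=cfg.beta_exp,
            w1=cfg.w1,
            w2=cfg.w2,
            expr_pseudocount=cfg.expr_pseudocount,
            is_floor=cfg.is_floor,
            missing_partner_policy=cfg.missing_partner_policy,
            log2_expression=cfg.log2_expression,
        )
        inter = inputs["interactions"]
        if "is_score" not in inter.table.columns:
            inter = normalize_interaction_scores(inter, cfg.is_floor)
        graphs = build_graphs(inter, pmap, mrna, mirna, meth)
        delta = transform_matrix(mrna, mirna, meth, graphs, tcfg)
        counts["transform"] = {
            "mirna_edges": graphs.n_mirna_edges,
            "cpg_edges": graphs.n_cpg_edges,
            "mirna_edges_dropped": graphs.n_mirna_edges_dropped,
            "cpg_edges_dropped": graphs.n_cpg_edges_dropped,
        }
        for name, df in delta.to_frames().items():
            _write_frame(df, f"{name}.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("transform", str(exc)) from exc

    try:
        # ---- stage 3: split -----------------------------------------------
        labels = inputs["labels"]
        keep = labels.table["sample_id"].isin(mrna.sample_ids)
        labels_kept = type(labels)(labels.table[keep].reset_index(drop=True))
        split = stratified_split(labels_kept, cfg.test_fraction, seeds["split"])
        counts["split"] = {
            "train": len(split.train_sample_ids),
            "test": len(split.test_sample_ids),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("split", str(exc)) from exc

    try:
        # ---- stage 4: train and evaluate ----------------------------------
        y = labels_kept.labels_for(mrna.sample_ids)
        trans_X = pd.DataFrame(
            delta.transformed.T, index=mrna.sample_ids,
            columns=[f"trans:{g}" for g in delta.gene_ids],
        )
        concat_X = concatenate_features([mrna, mirna, meth])

        spec = ModelSpec(
            cfg.model, _model_hyperparams(cfg, seeds["train"])
        )
        reports = {}
        for name, X in (("transform", trans_X), ("concatenation", concat_X)):
            rep = pooled_cv_report(
                spec, X.to_numpy(), y, cfg.n_folds, seeds["train"], augment=cfg.augment
            )
            reports[name] = rep
            _write_frame(rep.to_frame(), f"eval_{name}.tsv")
            _write_frame(rep.confusion, f"confusion_{name}.tsv")
        counts["train"] = {
            name: {
                "accuracy": rep.accuracy,
                "macro_f1": rep.macro_f1,
                "macro_auroc": rep.auroc_macro,
            }
            for name, rep in reports.items()
        }

        # held-out split evaluation on the transformed features
        tr_ids, te_ids = split.train_sample_ids, split.test_sample_ids
        Xtr = trans_X.loc[tr_ids].to_numpy()
        ytr = labels_kept.labels_for(tr_ids)
        if cfg.augment:
            Xtr, ytr = augment_minority(Xtr, ytr, seed=seeds["train"])
        pred, scores, classes = fit_predict(spec, Xtr, ytr, trans_X.loc[te_ids].to_numpy())
        holdout = evaluate(labels_kept.labels_for(te_ids), pred, scores, classes)
        _write_frame(holdout.to_frame(), "eval_holdout.tsv")
        counts["train"]["holdout"] = {
            "accuracy": holdout.accuracy,
            "macro_f1": holdout.macro_f1,
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("train", str(exc)) from exc

    try:
        # ---- stage 5: explain ---------------------------------------------
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.preprocessing import StandardScaler

        Xtr_raw = trans_X.loc[split.train_sample_ids].to_numpy()
        scaler = StandardScaler().fit(Xtr_raw)
        rf = RandomForestClassifier(n_estimators=50, random_state=seeds["explain"])
        rf.fit(scaler.transform(Xtr_raw), labels_kept.labels_for(split.train_sample_ids))
        ranking = rank_features(
            rf,
            scaler.transform(Xtr_raw),
            labels_kept.labels_for(split.train_sample_ids),
            feature_ids=delta.gene_ids,
            backend=cfg.importance_backend,
            top_k=cfg.top_k,
            seed=seeds["explain"],
        )
        _write_frame(ranking.table, "importance_ranking.tsv", index=False)
        counts["explain"] = {"n_ranked": len(ranking.table)}

        per_class_lists = {}
        k = max(1, cfg.top_k // 4)
        for c in np.unique(y):
            try:
                genes_c = ranking.per_class_top(str(c), k)
            except Exception:
                genes_c = ranking.top(k)
            if inputs["annotations"] is not None:
                genes_c, _ = filter_by_annotation(
                    genes_c,
                    inputs["annotations"],
                    sift_window=cfg.sift_window,
                    polyphen_window=cfg.polyphen_window,
                    logic=cfg.annotation_logic,
                )
            per_class_lists[str(c)] = genes_c
        sets = subtype_unique_sets(per_class_lists)
        rows = [
            {"class": c, "gene": g, "membership": "unique"}
            for c, gs in sets.unique.items()
            for g in sorted(gs)
        ] + [{"class": "ALL", "gene": g, "membership": "shared"} for g in sorted(sets.all_shared)]
        _write_frame(pd.DataFrame(rows, columns=["class", "gene", "membership"]),
                     "subtype_gene_sets.tsv", index=False)
        counts["explain"]["unique_per_class"] = {c: len(g) for c, g in sets.unique.items()}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("explain", str(exc)) from exc

    try:
        # ---- stage 6: survival --------------------------------------------
        if inputs["survival"] is not None:
            surv_frames = []
            trans_expr = _delta_as_matrix(delta)
            for c in np.unique(y):
                ids_c = [s for s, yc in zip(mrna.sample_ids, y) if yc == c]
                genes_c = per_class_lists.get(str(c)) or ranking.top(max(1, cfg.top_k // 4))
                tbl = screen_genes(
                    trans_expr.subset(sample_ids=ids_c),
                    inputs["survival"],
                    genes_c,
                    alpha_level=cfg.alpha_level,
                    quantile=cfg.split_quantile,
                )
                tbl.insert(0, "class", str(c))
                surv_frames.append(tbl)
            surv_all = pd.concat(surv_frames, ignore_index=True)
            _write_frame(surv_all, "survival_screen.tsv", index=False)
            counts["survival"] = {
                "n_tests": int(surv_all["p"].notna().sum()),
                "n_significant": int(surv_all["significant"].sum()),
            }
        else:
            counts["survival"] = {"n_tests": 0, "n_significant": 0}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("survival", str(exc)) from exc

    manifest = RunManifest(
        config=cfg.to_dict(),
        seeds=seeds,
        input_digests=input_digests,
        stage_counts=_jsonable(counts),
        output_paths={k: str(Path(v).name) for k, v in paths.items()},
    )
    manifest.to_file(out / "manifest.json")
    return manifest


def _model_hyperparams(cfg: RunConfig, seed: int) -> dict:
    if cfg.model == "knn":
        return {"knn_neighbors": cfg.knn_neighbors}
    if cfg.model == "feedforward_net":
        return {"hidden_sizes": tuple(cfg.hidden_sizes), "epochs": cfg.net_epochs, "seed": seed}
    if cfg.model == "logistic_ovr":
        return {}
    return {"seed": seed}


def _delta_as_matrix(delta) -> "OmicsMatrix":
    from gainet.io_formats import OmicsMatrix

    return OmicsMatrix(
        delta.gene_ids, delta.sample_ids,
        np.maximum(delta.transformed, 0.0), OmicsKind.MRNA_COUNTS,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 12)
    return obj


def inputs_from_bundle(bundle) -> dict:
    """Adapt a synthetic FixtureBundle to the pipeline's input dict."""
    return {
        "mrna": bundle.mrna,
        "mirna": bundle.mirna,
        "meth": bundle.meth,
        "interactions": bundle.interactions,
        "promoter_map": bundle.promoter_map,
        "labels": bundle.labels,
        "annotations": bundle.annotations,
        "survival": bundle.survival,
    }
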