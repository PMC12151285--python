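"""Self-contained synthetic multi-omics fixtures with planted regulatory signal.

The generator emulates the statistical shape of a TCGA-style cohort: mRNA and
miRNA counts are negative-binomial (overdispersed), CpG methylation values
are Beta-distributed, and a miRNA→gene interaction table plus a promoter
CpG→gene map tie the three matrices together.  Class (subtype) signal is
planted ONLY in the regulators: for a designated subset of "signal" genes,
each class shifts its partner miRNAs on the log2-count scale and its partner
CpGs on the logit-beta scale, and the mRNA counts themselves are drawn around
a baseline multiplied by a suppression factor that decreases with the sampled
partner miRNA levels and promoter methylation.  The class structure therefore
reaches the mRNA matrix only through the regulatory graph — exactly the
situation the modulating-factor transform is designed to exploit.

Every bundle carries its own ground truth (signal genes, regulator sets, the
delta matrices computed by the naive reference evaluator, and the planted
prognostic gene), and generation is bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gainet.graph_transform import (
    RegulatoryGraphs,
    TransformConfig,
    build_graphs,
    normalize_interaction_scores,
)
from gainet.io_formats import (
    AnnotationTable,
    InteractionTable,
    LabelTable,
    OmicsKind,
    OmicsMatrix,
    PromoterMap,
)
from gainet.reference import naive_transform
from gainet.survival import SurvivalRecords


class SyntheticError(ValueError):
    pass


def _default_classes() -> dict[str, int]:
    return {"classA": 45, "classB": 25, "classC": 15, "classD": 15}


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Defaults describe a small imbalanced four-class cohort (100 samples,
    45/25/15/15) with realistic RNA-seq-like counts (NB mean ~200,
    dispersion 0.3) and promoter methylation (Beta, concentration 30).
    A fifth of the genes are "signal" genes, each owning a dedicated
    (disjoint) set of regulator miRNAs and CpGs.  Per class and signal gene
    one coherent regulatory direction is drawn: every partner miRNA of that
    gene shifts by ±1.0 on the log2-count scale and every partner CpG by
    ±1.2 on the logit-beta scale, all in the same direction — emulating a
    subtype-specific miRNA/methylation programme acting on that gene.
    Coherence matters: the modulating factors average over a gene's
    partners, so aligned partner shifts accumulate in delta instead of
    cancelling.  One signal gene is planted as prognostic with hazard
    ratio 3.
    """

    seed: int  # mandatory; every draw flows from it
    n_samples_per_class: dict[str, int] = field(default_factory=_default_classes)
    n_genes: int = 80
    n_mirnas: int = 120
    n_cpgs: int = 150
    mirna_edges_per_gene: tuple[int, int] = (2, 4)
    cpg_edges_per_gene: tuple[int, int] = (2, 4)
    signal_gene_fraction: float = 0.2
    effect_mirna_log2: float = 1.0
    effect_beta_logit: float = 1.2
    baseline_count_mean: float = 200.0
    count_dispersion: float = 0.3
    mirna_count_mean: float = 100.0
    beta_mean: float = 0.5
    beta_concentration: float = 30.0
    suppression_mirna: float = 0.4  # log2-units of mRNA drop per log2-unit of partner miRNA
    suppression_meth: float = 1.0  # log2-units of mRNA drop per unit of mean beta
    noise_sd: float = 0.15  # lognormal noise on the mRNA mean
    survival_baseline_hazard: float = 0.05
    prognostic_hazard_ratio: float = 3.0
    censor_time: float = 30.0
    tss_window_bp: int = 1500

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SyntheticError("seed is mandatory")
        for name in ("n_genes", "n_mirnas", "n_cpgs"):
            if getattr(self, name) < 1:
                raise SyntheticError(f"{name} must be >= 1")
        if any(n < 1 for n in self.n_samples_per_class.values()):
            raise SyntheticError("every class needs at least one sample")
        if self.mirna_edges_per_gene[1] > self.n_mirnas:
            raise SyntheticError("more miRNA edges per gene than miRNAs available")
        if self.cpg_edges_per_gene[1] > self.n_cpgs:
            raise SyntheticError("more CpG edges per gene than CpGs available")
        if not (0 <= self.signal_gene_fraction <= 1):
            raise SyntheticError("signal_gene_fraction must be in [0, 1]")
        n_signal = int(round(self.signal_gene_fraction * self.n_genes))
        if n_signal * self.mirna_edges_per_gene[1] > self.n_mirnas:
            raise SyntheticError(
                "signal genes need disjoint miRNA regulators; "
                "n_signal * max_edges exceeds n_mirnas"
            )
        if n_signal * self.cpg_edges_per_gene[1] > self.n_cpgs:
            raise SyntheticError(
                "signal genes need disjoint CpG regulators; "
                "n_signal * max_edges exceeds n_cpgs"
            )


@dataclass
class FixtureBundle:
    """Everything a pipeline run needs, plus the generator's ground truth."""

    mrna: OmicsMatrix
    mirna: OmicsMatrix
    meth: OmicsMatrix
    interactions: InteractionTable
    promoter_map: PromoterMap
    labels: LabelTable
    annotations: AnnotationTable
    survival: SurvivalRecords
    graphs: RegulatoryGraphs
    true_delta: object  # DeltaResult from the naive reference evaluator
    ground_truth: dict = field(default_factory=dict)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw parameterised by mean and dispersion (var = m + d m^2)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def generate(cfg: SyntheticConfig) -> FixtureBundle:
    """Draw a full cohort bundle under the given study conditions."""
    rng = np.random.default_rng(cfg.seed)

    classes = list(cfg.n_samples_per_class)
    y = np.concatenate(
        [np.full(n, c) for c, n in cfg.n_samples_per_class.items()]
    )
    n_samples = len(y)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    gene_ids = [f"gene{i:03d}" for i in range(cfg.n_genes)]
    mirna_ids = [f"mir{i:03d}" for i in range(cfg.n_mirnas)]
    cpg_ids = [f"cg{i:05d}" for i in range(cfg.n_cpgs)]

    # --- regulatory wiring -------------------------------------------------
    # signal genes own disjoint regulator sets so each subtype programme acts
    # on exactly one gene; background genes wire to the non-regulator pool
    n_signal = int(round(cfg.signal_gene_fraction * cfg.n_genes))
    signal_genes = sorted(rng.choice(cfg.n_genes, size=n_signal, replace=False))
    signal_set = set(signal_genes)

    def _allocate(n_nodes: int, edge_range: tuple[int, int]):
        lo, hi = edge_range
        perm = rng.permutation(n_nodes)
        partners: dict[int, list[int]] = {}
        cursor = 0
        for g in signal_genes:
            k = int(rng.integers(lo, hi + 1))
            partners[g] = sorted(int(v) for v in perm[cursor : cursor + k])
            cursor += k
        background_pool = perm[cursor:]
        for g in range(cfg.n_genes):
            if g in signal_set:
                continue
            k = int(rng.integers(lo, hi + 1))
            k = min(k, len(background_pool))
            idx = rng.choice(len(background_pool), size=k, replace=False)
            partners[g] = sorted(int(background_pool[i]) for i in idx)
        return partners

    mirna_partners = _allocate(cfg.n_mirnas, cfg.mirna_edges_per_gene)
    cpg_partners = _allocate(cfg.n_cpgs, cfg.cpg_edges_per_gene)
    reg_mirnas = sorted({m for g in signal_genes for m in mirna_partners[g]})
    reg_cpgs = sorted({c for g in signal_genes for c in cpg_partners[g]})

    # one coherent regulatory direction per (class, signal gene): all of the
    # gene's partner miRNAs and CpGs shift the same way
    direction = {c: {g: float(rng.choice([-1.0, 1.0])) for g in signal_genes} for c in classes}

    # --- miRNA counts ------------------------------------------------------
    base_mi = cfg.mirna_count_mean * np.exp(rng.normal(0, 0.3, size=cfg.n_mirnas))
    log2_shift = np.zeros((cfg.n_mirnas, n_samples))
    for j, c in enumerate(y):
        for g in signal_genes:
            for mi in mirna_partners[g]:
                log2_shift[mi, j] = cfg.effect_mirna_log2 * direction[c][g]
    mi_mean = base_mi[:, None] * 2.0 ** log2_shift
    mi_mean *= np.exp(rng.normal(0, cfg.noise_sd, size=mi_mean.shape))
    mirna_vals = _nb(rng, mi_mean, cfg.count_dispersion)

    # --- CpG beta values ---------------------------------------------------
    base_logit = _logit(cfg.beta_mean) + rng.normal(0, 0.5, size=cfg.n_cpgs)
    logit_shift = np.zeros((cfg.n_cpgs, n_samples))
    for j, c in enumerate(y):
        for g in signal_genes:
            for cg in cpg_partners[g]:
                logit_shift[cg, j] = cfg.effect_beta_logit * direction[c][g]
    mu = _sigmoid(base_logit[:, None] + logit_shift)
    a = mu * cfg.beta_concentration
    b = (1.0 - mu) * cfg.beta_concentration
    meth_vals = rng.beta(a, b)

    # --- mRNA counts: baseline x suppression by sampled regulators --------
    base_g = cfg.baseline_count_mean * np.exp(rng.normal(0, 0.3, size=cfg.n_genes))
    mrna_mean = np.empty((cfg.n_genes, n_samples))
    for g in range(cfg.n_genes):
        part_mi = mirna_partners[g]
        part_cg = cpg_partners[g]
        m_gs = np.log2(1.0 + mirna_vals[part_mi]).mean(axis=0)
        b_gs = meth_vals[part_cg].mean(axis=0)
        m_ref = np.log2(1.0 + base_mi[part_mi]).mean()
        supp = 2.0 ** (
            -cfg.suppression_mirna * (m_gs - m_ref)
            - cfg.suppression_meth * (b_gs - cfg.beta_mean)
        )
        mrna_mean[g] = base_g[g] * supp
    mrna_mean *= np.exp(rng.normal(0, cfg.noise_sd, size=mrna_mean.shape))
    mrna_vals = _nb(rng, mrna_mean, cfg.count_dispersion)

    mrna = OmicsMatrix(gene_ids, sample_ids, mrna_vals, OmicsKind.MRNA_COUNTS)
    mirna = OmicsMatrix(mirna_ids, sample_ids, mirna_vals, OmicsKind.MIRNA_COUNTS)
    meth = OmicsMatrix(cpg_ids, sample_ids, meth_vals, OmicsKind.METHYLATION_BETA)

    # --- edge tables -------------------------------------------------------
    pairs = [
        {
            "mirna_id": mirna_ids[mi],
            "gene_id": gene_ids[g],
            "raw_score": float(-rng.uniform(0.2, 1.2)),
        }
        for g in range(cfg.n_genes)
        for mi in mirna_partners[g]
    ]
    interactions = normalize_interaction_scores(InteractionTable(pd.DataFrame(pairs)))
    promoter_rows = [
        {
            "cpg_id": cpg_ids[cg],
            "gene_id": gene_ids[g],
            "tss_distance_bp": int(rng.integers(0, cfg.tss_window_bp + 1)),
        }
        for g in range(cfg.n_genes)
        for cg in cpg_partners[g]
    ]
    promoter_map = PromoterMap(pd.DataFrame(promoter_rows))

    labels = LabelTable(pd.DataFrame({"sample_id": sample_ids, "class_label": y}))

    # --- annotations -------------------------------------------------------
    sift = rng.uniform(0, 1, size=cfg.n_genes)
    poly = rng.uniform(0, 1, size=cfg.n_genes)
    hi_score = rng.uniform(0, 1, size=cfg.n_genes)
    miss = rng.random(size=(cfg.n_genes, 3)) < 0.1
    ann = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "sift": np.where(miss[:, 0], np.nan, sift),
            "polyphen": np.where(miss[:, 1], np.nan, poly),
            "haploinsufficiency": np.where(miss[:, 2], np.nan, hi_score),
        }
    )
    annotations = AnnotationTable(ann)

    # --- survival: exponential times, one prognostic gene ------------------
    prognostic_gene = gene_ids[signal_genes[0]] if signal_genes else gene_ids[0]
    g_row = mrna_vals[gene_ids.index(prognostic_gene)]
    high = g_row > np.median(g_row)
    hazard = np.full(n_samples, cfg.survival_baseline_hazard)
    hazard[high] *= cfg.prognostic_hazard_ratio
    t_raw = rng.exponential(1.0 / hazard)
    event = (t_raw <= cfg.censor_time).astype(int)
    time = np.minimum(t_raw, cfg.censor_time)
    survival = SurvivalRecords(
        pd.DataFrame({"sample_id": sample_ids, "time": time, "event": event})
    )

    # --- ground truth ------------------------------------------------------
    graphs = build_graphs(interactions, promoter_map, mrna, mirna, meth)
    meth_clamped = OmicsMatrix(
        cpg_ids, sample_ids, np.clip(meth_vals, 1e-3, 1.0), OmicsKind.METHYLATION_BETA
    )
    true_delta = naive_transform(mrna, mirna, meth_clamped, graphs, TransformConfig())

    return FixtureBundle(
        mrna=mrna,
        mirna=mirna,
        meth=meth,
        interactions=interactions,
        promoter_map=promoter_map,
        labels=labels,
        annotations=annotations,
        survival=survival,
        graphs=graphs,
        true_delta=true_delta,
        ground_truth={
            "signal_genes": [gene_ids[g] for g in signal_genes],
            "regulator_mirnas": [mirna_ids[m] for m in reg_mirnas],
            "regulator_cpgs": [cpg_ids[c] for c in reg_cpgs],
            "prognostic_gene": prognostic_gene,
            "prognostic_hazard_ratio": cfg.prognostic_hazard_ratio,
            "class_sizes": dict(cfg.n_samples_per_class),
        },
    )


def generate_degenerate_cases(seed: int = 0) -> list[FixtureBundle]:
    """Edge-case fixtures with planted, exactly countable violations.

    Bundle 0 (filter fixture), 10 samples x 10 mRNA features:
      * 2 features with 30% zero/missing entries  -> removed by the feature filter
      * 1 feature with exactly 20% zeros          -> kept (strict inequality)
      * 1 sample with 25% zeros (after the feature filter) -> removed
      * a partnerless gene and a constant-expression gene (ground truth tags)
    Bundle 1 (methylation fixture):
      * beta = 0 entries (clamp test) and one all-missing beta feature that
        must trigger the documented imputation error.
    """
    rng = np.random.default_rng(seed)
    n_s, n_f = 10, 10
    sample_ids = [f"S{i:02d}" for i in range(n_s)]
    gene_ids = [f"gene{i:02d}" for i in range(n_f)]
    vals = rng.uniform(50, 150, size=(n_f, n_s)).round()

    # rows 0-1: 3 of 10 entries bad (0.30 > 0.20) -> removed
    vals[0, :2] = 0.0
    vals[0, 2] = np.nan
    vals[1, :3] = 0.0
    # row 2: exactly 2 of 10 zeros (0.20, boundary) -> kept
    vals[2, :2] = 0.0
    # column 9: make 25% of the SURVIVING 8 features zero -> sample removed
    vals[3:5, 9] = 0.0
    # row 5: constant expression (dichotomization error fixture)
    vals[5, :] = 100.0

    mrna = OmicsMatrix(gene_ids, sample_ids, vals, OmicsKind.MRNA_COUNTS)
    mirna = OmicsMatrix(
        ["mir00", "mir01"],
        sample_ids,
        rng.uniform(10, 90, size=(2, n_s)).round(),
        OmicsKind.MIRNA_COUNTS,
    )
    meth_ids = ["cg00000", "cg00001", "cg00002"]
    meth_vals = rng.beta(5, 5, size=(3, n_s))
    meth = OmicsMatrix(meth_ids, sample_ids, meth_vals, OmicsKind.METHYLATION_BETA)

    # every gene except gene06 (partnerless) gets one partner of each kind
    partnered = [g for g in gene_ids if g != "gene06"]
    interactions = normalize_interaction_scores(
        InteractionTable(
            pd.DataFrame(
                {
                    "mirna_id": ["mir00" if i % 2 else "mir01" for i in range(len(partnered))],
                    "gene_id": partnered,
                    "raw_score": -rng.uniform(0.2, 1.2, size=len(partnered)),
                }
            )
        )
    )
    promoter_map = PromoterMap(
        pd.DataFrame(
            {
                "cpg_id": [meth_ids[i % 3] for i in range(len(partnered))],
                "gene_id": partnered,
                "tss_distance_bp": [1500 if i == 0 else 200 * (i % 7) for i in range(len(partnered))],
            }
        )
    )
    labels = LabelTable(
        pd.DataFrame(
            {"sample_id": sample_ids, "class_label": ["g1"] * 5 + ["g2"] * 5}
        )
    )
    annotations = AnnotationTable(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "sift": rng.uniform(0, 1, n_f),
                "polyphen": rng.uniform(0, 1, n_f),
                "haploinsufficiency": rng.uniform(0, 1, n_f),
            }
        )
    )
    survival = SurvivalRecords(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "time": rng.exponential(20, n_s),
                "event": rng.integers(0, 2, n_s),
            }
        )
    )
    graphs = build_graphs(interactions, promoter_map, mrna, mirna, meth)
    filter_bundle = FixtureBundle(
        mrna=mrna,
        mirna=mirna,
        meth=meth,
        interactions=interactions,
        promoter_map=promoter_map,
        labels=labels,
        annotations=annotations,
        survival=survival,
        graphs=graphs,
        true_delta=None,
        ground_truth={
            "case": "filters",
            "planted_removed_features": ["gene00", "gene01"],
            "planted_boundary_feature": "gene02",
            "planted_removed_samples": ["S09"],
            "partnerless_gene": "gene06",
            "constant_gene": "gene05",
        },
    )

    # --- methylation edge cases -------------------------------------------
    meth2_ids = ["cg10000", "cg10001", "cg10002"]
    meth2 = np.vstack(
        [
            np.array([0.0, 0.2, 0.4, 0.6, 0.8]),  # contains beta = 0 -> clamp
            np.full(5, np.nan),  # all missing -> documented error
            np.array([0.5, np.nan, 0.5, 0.5, 0.5]),  # single missing -> imputed
        ]
    )
    s5 = [f"T{i}" for i in range(5)]
    meth_bundle = FixtureBundle(
        mrna=OmicsMatrix(
            ["geneX"], s5, rng.uniform(50, 150, size=(1, 5)).round(), OmicsKind.MRNA_COUNTS
        ),
        mirna=OmicsMatrix(
            ["mirX"], s5, rng.uniform(10, 90, size=(1, 5)).round(), OmicsKind.MIRNA_COUNTS
        ),
        meth=OmicsMatrix(meth2_ids, s5, meth2, OmicsKind.METHYLATION_BETA),
        interactions=None,
        promoter_map=None,
        labels=None,
        annotations=None,
        survival=None,
        graphs=None,
        true_delta=None,
        ground_truth={
            "case": "methylation",
            "beta_zero_feature": "cg10000",
            "all_missing_feature": "cg10001",
            "single_missing_feature": "cg10002",
        },
    )
    return [filter_bundle, meth_bundle]


def write_bundle(bundle: FixtureBundle, out_dir) -> dict[str, str]:
    """Write a bundle's tables as TSV files; returns name -> path."""
    from pathlib import Path

    from gainet.io_formats import write_omics_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for name, m in (("mrna", bundle.mrna), ("mirna", bundle.mirna), ("meth", bundle.meth)):
        p = out / f"{name}.tsv"
        write_omics_matrix(m, p)
        paths[name] = str(p)
    tables = {
        "interactions": bundle.interactions.table if bundle.interactions else None,
        "promoter_map": bundle.promoter_map.table if bundle.promoter_map else None,
        "labels": bundle.labels.table if bundle.labels else None,
        "annotations": bundle.annotations.table if bundle.annotations else None,
        "survival": bundle.survival.table if bundle.survival else None,
    }
    for name, t in tables.items():
        if t is None:
            continue
        p = out / f"{name}.tsv"
        t.to_csv(p, sep="\t", index=False, na_rep="NA")
        paths[name] = str(p)
    return paths
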