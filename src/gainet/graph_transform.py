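"""Weighted bipartite regulatory graphs and the modulating-factor transform.

This is the package core.  For every gene g and sample s two multiplicative
modulating factors are computed from the gene's regulatory partners:

* ``delta1[g, s]`` — repression pressure from the miRNAs targeting g,

      delta1 = (1/n) * sum_i 1 / (IS_i * exp(alpha * log2(expr_i + pc)))

  where IS_i in (0, 1] is the normalised interaction score of partner miRNA i
  (stronger interaction = larger IS = stronger downweighting), expr_i its
  expression in sample s, alpha > 0 the decay sharpness, and pc a pseudocount
  that keeps log2 finite at zero counts;

* ``delta2[g, s]`` — pressure from promoter CpG methylation,

      delta2 = (1/n) * sum_i 1 / exp(beta_exp * log2(beta_i))

  over the beta values (clamped into (0, 1]) of the CpGs mapped to g's
  promoter.

The combined factor is the weighted mean ``delta = (w1*d1 + w2*d2)/(w1+w2)``
(default weights 1:1) and the transformed expression is
``trans = delta * expr(mRNA)``.  Low regulator activity (expression 0,
IS = 1, beta = 1) gives delta = 1, i.e. the transform is the identity in the
absence of regulatory pressure; higher miRNA expression or methylation pulls
delta below/above accordingly, embedding the regulatory context into the
mRNA feature itself.

Terms are evaluated in log space (log-sum-exp) so large normalised counts
cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from gainet.io_formats import InteractionTable, OmicsMatrix, PromoterMap


class TransformError(ValueError):
    pass


@dataclass
class TransformConfig:
    """All free parameters of the modulating-factor transform.

    alpha and beta_exp control how sharply miRNA expression and CpG
    methylation modulate the factors (both default 1.5, a deliberately mild
    decay); w1:w2 weights the two factors in the combination (1:1 default,
    the best-performing ratio of the equal-weight experiments); is_floor
    bounds 1/IS; expr_pseudocount keeps log2 of a zero count finite.
    """

    alpha: float = 1.5
    beta_exp: float = 1.5
    w1: float = 1.0
    w2: float = 1.0
    expr_pseudocount: float = 1.0
    is_floor: float = 0.01
    missing_partner_policy: str = "fallback"  # or "neutral_one"
    log2_expression: bool = False  # optionally log2(x+1)-transform mRNA before Eq. 7

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and np.isfinite(self.alpha)):
            raise ValueError("alpha must be finite and > 0")
        if not (self.beta_exp > 0 and np.isfinite(self.beta_exp)):
            raise ValueError("beta_exp must be finite and > 0")
        if self.w1 < 0 or self.w2 < 0 or self.w1 + self.w2 <= 0:
            raise ValueError("weights must be nonnegative with w1 + w2 > 0")
        if not (0 < self.is_floor < 1):
            raise ValueError("is_floor must lie in (0, 1)")
        if self.expr_pseudocount <= 0:
            raise ValueError("expr_pseudocount must be > 0")
        if self.missing_partner_policy not in ("fallback", "neutral_one"):
            raise ValueError("missing_partner_policy must be 'fallback' or 'neutral_one'")


@dataclass
class RegulatoryGraphs:
    """The two aligned bipartite edge sets, keyed by gene id.

    ``mirna_edges[gene] = [(mirna_id, IS), ...]`` and
    ``cpg_edges[gene] = [cpg_id, ...]``; every partner id exists in the
    corresponding matrix, edge lists are deduplicated, and genes lacking
    partners in a graph simply have no entry there.
    """

    mirna_edges: dict[str, list[tuple[str, float]]]
    cpg_edges: dict[str, list[str]]
    n_mirna_edges_dropped: int = 0
    n_cpg_edges_dropped: int = 0

    @property
    def n_mirna_edges(self) -> int:
        return sum(len(v) for v in self.mirna_edges.values())

    @property
    def n_cpg_edges(self) -> int:
        return sum(len(v) for v in self.cpg_edges.values())


@dataclass
class DeltaResult:
    """Per-(gene, sample) modulating factors and the transformed matrix.

    ``delta1``/``delta2`` are NaN where the gene has no partners in that
    graph; ``delta`` is always defined (the missing-partner policy fills the
    gaps) and ``transformed = delta * expr`` elementwise.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    delta1: np.ndarray
    delta2: np.ndarray
    delta: np.ndarray
    transformed: np.ndarray
    config: TransformConfig = field(default_factory=TransformConfig)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            name: pd.DataFrame(getattr(self, name), index=self.gene_ids, columns=self.sample_ids)
            for name in ("delta1", "delta2", "delta", "transformed")
        }


def normalize_interaction_scores(
    t: InteractionTable, is_floor: float = 0.01
) -> InteractionTable:
    """Min–max rescale |raw_score| onto [is_floor, 1] as the IS column.

    Raw TargetScan-style context scores are <= 0 with more negative meaning
    stronger repression; taking the absolute value preserves that ordering
    ("stronger interaction = larger IS") and the floor bounds the 1/IS term.
    If all raw scores coincide the table is degenerate and every IS is 1.
    """
    if len(t) == 0:
        raise TransformError("cannot normalise an empty interaction table")
    strength = np.abs(t.table["raw_score"].to_numpy(dtype=float))
    lo, hi = strength.min(), strength.max()
    if hi == lo:
        is_score = np.ones_like(strength)
    else:
        is_score = is_floor + (1.0 - is_floor) * (strength - lo) / (hi - lo)
    out = t.table.copy()
    out["is_score"] = is_score
    return InteractionTable(out)


def build_graphs(
    t: InteractionTable,
    p: PromoterMap,
    mrna: OmicsMatrix,
    mirna: OmicsMatrix,
    meth: OmicsMatrix,
) -> RegulatoryGraphs:
    """Restrict both edge sets to features present in the aligned matrices.

    Edges naming an absent gene/miRNA/CpG are dropped and counted; duplicate
    promoter rows collapse to one edge.  Raises if neither graph retains a
    single usable edge.
    """
    if "is_score" not in t.table.columns:
        raise TransformError("interaction table has no is_score; normalise it first")
    genes = set(mrna.feature_ids)
    mirnas = set(mirna.feature_ids)
    cpgs = set(meth.feature_ids)

    mirna_edges: dict[str, list[tuple[str, float]]] = {}
    seen_pairs: set[tuple[str, str]] = set()
    dropped_mi = 0
    for row in t.table.itertuples(index=False):
        g, mi = str(row.gene_id), str(row.mirna_id)
        if g not in genes or mi not in mirnas:
            dropped_mi += 1
            continue
        if (g, mi) in seen_pairs:
            continue
        seen_pairs.add((g, mi))
        mirna_edges.setdefault(g, []).append((mi, float(row.is_score)))

    cpg_edges: dict[str, list[str]] = {}
    seen_cpg: set[tuple[str, str]] = set()
    dropped_cpg = 0
    for row in p.table.itertuples(index=False):
        g, c = str(row.gene_id), str(row.cpg_id)
        if g not in genes or c not in cpgs:
            dropped_cpg += 1
            continue
        if (g, c) in seen_cpg:
            continue
        seen_cpg.add((g, c))
        cpg_edges.setdefault(g, []).append(c)

    graphs = RegulatoryGraphs(mirna_edges, cpg_edges, dropped_mi, dropped_cpg)
    if graphs.n_mirna_edges == 0 and graphs.n_cpg_edges == 0:
        raise TransformError("no usable edges in either regulatory graph")
    return graphs


def delta1_gene_sample(
    exprs: Sequence[float],
    iss: Sequence[float],
    alpha: float = 1.5,
    pseudocount: float = 1.0,
) -> float:
    """miRNA modulating factor for one gene in one sample.

    Averages 1/(IS_i * exp(alpha*log2(expr_i + pc))) over the gene's partner
    miRNAs; evaluated via log-sum-exp.  Returns NaN for an empty partner
    list (the "no partners" signal handled by the combination policy).
    """
    e = np.asarray(exprs, dtype=float)
    s = np.asarray(iss, dtype=float)
    if e.size == 0:
        return float("nan")
    if e.shape != s.shape:
        raise ValueError("exprs and iss must have equal length")
    # log term (natural log): -ln IS_i - alpha * log2(e_i + pc)
    log_terms = -np.log(s) - alpha * np.log2(e + pseudocount)
    return float(np.exp(logsumexp(log_terms) - np.log(e.size)))


def delta2_gene_sample(betas: Sequence[float], beta_exp: float = 1.5) -> float:
    """Methylation modulating factor: mean of 1/exp(beta_exp*log2(beta_i)).

    Betas must lie in (0, 1] (clamp upstream); returns NaN for an empty list.
    """
    b = np.asarray(betas, dtype=float)
    if b.size == 0:
        return float("nan")
    if np.any(b <= 0) or np.any(b > 1):
        raise ValueError("beta values must lie in (0, 1]")
    log_terms = -beta_exp * np.log2(b)
    return float(np.exp(logsumexp(log_terms) - np.log(b.size)))


def combine_delta(
    d1: float,
    d2: float,
    w1: float = 1.0,
    w2: float = 1.0,
    policy: str = "fallback",
) -> float:
    """Weighted mean of the two factors with a policy for absent partners.

    NaN marks an absent factor.  Both present: (w1*d1 + w2*d2)/(w1+w2).
    Exactly one present: "fallback" returns it unchanged, "neutral_one"
    returns 1.  Both absent: 1 (the transform is the identity for that gene).
    """
    have1 = not np.isnan(d1)
    have2 = not np.isnan(d2)
    if have1 and have2:
        return (w1 * d1 + w2 * d2) / (w1 + w2)
    if not have1 and not have2:
        return 1.0
    if policy == "neutral_one":
        return 1.0
    if policy == "fallback":
        return d1 if have1 else d2
    raise ValueError(f"unknown missing-partner policy {policy!r}")


def _check_aligned(*ms: OmicsMatrix) -> None:
    ref = ms[0].sample_ids
    for m in ms[1:]:
        if m.sample_ids != ref:
            raise TransformError(
                "matrices are not sample-aligned; intersect and order them first"
            )


def transform_matrix(
    mrna: OmicsMatrix,
    mirna: OmicsMatrix,
    meth: OmicsMatrix,
    graphs: RegulatoryGraphs,
    cfg: TransformConfig | None = None,
) -> DeltaResult:
    """Compute delta1, delta2, delta and the transformed mRNA matrix.

    All three matrices must share an identically ordered sample list.  The
    computation is vectorised per gene across samples and is deterministic:
    identical inputs give bit-identical outputs.
    """
    cfg = cfg or TransformConfig()
    _check_aligned(mrna, mirna, meth)

    n_genes, n_samples = mrna.values.shape
    mirna_row = {f: i for i, f in enumerate(mirna.feature_ids)}
    cpg_row = {f: i for i, f in enumerate(meth.feature_ids)}

    delta1 = np.full((n_genes, n_samples), np.nan)
    delta2 = np.full((n_genes, n_samples), np.nan)

    for gi, gene in enumerate(mrna.feature_ids):
        edges = graphs.mirna_edges.get(gene)
        if edges:
            rows = [mirna_row[mi] for mi, _ in edges]
            iss = np.array([s for _, s in edges])  # (k,)
            expr = mirna.values[rows]  # (k, n_samples)
            log_terms = -np.log(iss)[:, None] - cfg.alpha * np.log2(
                expr + cfg.expr_pseudocount
            )
            delta1[gi] = np.exp(logsumexp(log_terms, axis=0) - np.log(len(edges)))
        cpgs = graphs.cpg_edges.get(gene)
        if cpgs:
            rows = [cpg_row[c] for c in cpgs]
            betas = meth.values[rows]  # (k, n_samples)
            if np.any(betas <= 0) or np.any(betas > 1):
                raise TransformError(
                    f"beta values for gene {gene!r} outside (0, 1]; clamp them first"
                )
            log_terms = -cfg.beta_exp * np.log2(betas)
            delta2[gi] = np.exp(logsumexp(log_terms, axis=0) - np.log(len(cpgs)))

    have1 = ~np.isnan(delta1)
    have2 = ~np.isnan(delta2)
    wsum = cfg.w1 + cfg.w2
    delta = np.ones((n_genes, n_samples))
    both = have1 & have2
    delta[both] = (cfg.w1 * delta1[both] + cfg.w2 * delta2[both]) / wsum
    if cfg.missing_partner_policy == "fallback":
        only1 = have1 & ~have2
        only2 = have2 & ~have1
        delta[only1] = delta1[only1]
        delta[only2] = delta2[only2]
    # "neutral_one": singletons stay at the initialised 1

    expr = mrna.values
    if cfg.log2_expression:
        expr = np.log2(expr + 1.0)
    transformed = delta * expr
    return DeltaResult(
        list(mrna.feature_ids), list(mrna.sample_ids), delta1, delta2, delta, transformed, cfg
    )
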