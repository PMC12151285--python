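"""Naive edge-loop reference evaluator for the modulating-factor transform.

Deliberately written as plain per-entry Python loops with none of the
vectorisation or log-space tricks of :mod:`gainet.graph_transform`, so it can
serve as an independent cross-check: the fast implementation must agree with
this one to numerical precision on any instance.  It is also what stamps the
ground-truth delta matrices into synthetic fixture bundles.
"""

from __future__ import annotations

import math

import numpy as np

from gainet.graph_transform import DeltaResult, RegulatoryGraphs, TransformConfig
from gainet.io_formats import OmicsMatrix


def naive_transform(
    mrna: OmicsMatrix,
    mirna: OmicsMatrix,
    meth: OmicsMatrix,
    graphs: RegulatoryGraphs,
    cfg: TransformConfig | None = None,
) -> DeltaResult:
    """Per-entry loop evaluation of delta1, delta2, delta and the transform."""
    cfg = cfg or TransformConfig()
    mirna_row = {f: i for i, f in enumerate(mirna.feature_ids)}
    cpg_row = {f: i for i, f in enumerate(meth.feature_ids)}
    n_genes, n_samples = mrna.values.shape
    delta1 = np.full((n_genes, n_samples), np.nan)
    delta2 = np.full((n_genes, n_samples), np.nan)
    delta = np.ones((n_genes, n_samples))

    for gi, gene in enumerate(mrna.feature_ids):
        mi_edges = graphs.mirna_edges.get(gene, [])
        cpgs = graphs.cpg_edges.get(gene, [])
        for sj in range(n_samples):
            d1 = math.nan
            if mi_edges:
                total = 0.0
                for mi_id, is_score in mi_edges:
                    e = mirna.values[mirna_row[mi_id], sj]
                    total += 1.0 / (
                        is_score * math.exp(cfg.alpha * math.log2(e + cfg.expr_pseudocount))
                    )
                d1 = total / len(mi_edges)
                delta1[gi, sj] = d1
            d2 = math.nan
            if cpgs:
                total = 0.0
                for cpg_id in cpgs:
                    b = meth.values[cpg_row[cpg_id], sj]
                    total += 1.0 / math.exp(cfg.beta_exp * math.log2(b))
                d2 = total / len(cpgs)
                delta2[gi, sj] = d2
            have1, have2 = not math.isnan(d1), not math.isnan(d2)
            if have1 and have2:
                delta[gi, sj] = (cfg.w1 * d1 + cfg.w2 * d2) / (cfg.w1 + cfg.w2)
            elif have1 or have2:
                if cfg.missing_partner_policy == "fallback":
                    delta[gi, sj] = d1 if have1 else d2
                else:
                    delta[gi, sj] = 1.0
            else:
                delta[gi, sj] = 1.0

    expr = np.log2(mrna.values + 1.0) if cfg.log2_expression else mrna.values
    transformed = delta * expr
    return DeltaResult(
        list(mrna.feature_ids), list(mrna.sample_ids), delta1, delta2, delta, transformed, cfg
    )
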