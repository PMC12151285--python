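"""Random small transform instances for the acceptance script's oracle check."""

import numpy as np
import pandas as pd

from gainet.graph_transform import build_graphs, normalize_interaction_scores
from gainet.io_formats import InteractionTable, OmicsKind, OmicsMatrix, PromoterMap


def random_instance(rng, max_genes=10, max_samples=5):
    n_g = rng.integers(1, max_genes + 1)
    n_s = rng.integers(1, max_samples + 1)
    n_mi = rng.integers(1, 6)
    n_cg = rng.integers(1, 6)
    genes = [f"g{i}" for i in range(n_g)]
    samples = [f"s{i}" for i in range(n_s)]
    mirnas = [f"m{i}" for i in range(n_mi)]
    cpgs = [f"c{i}" for i in range(n_cg)]

    mrna = OmicsMatrix(genes, samples, rng.uniform(0, 500, size=(n_g, n_s)), OmicsKind.MRNA_COUNTS)
    mirna = OmicsMatrix(
        mirnas, samples, rng.uniform(0, 300, size=(n_mi, n_s)), OmicsKind.MIRNA_COUNTS
    )
    meth = OmicsMatrix(
        cpgs, samples, rng.uniform(0.01, 1.0, size=(n_cg, n_s)), OmicsKind.METHYLATION_BETA
    )

    pairs = []
    for g in genes:
        for m in mirnas:
            if rng.random() < 0.5:
                pairs.append({"mirna_id": m, "gene_id": g, "raw_score": -rng.uniform(0.1, 1.0)})
    if not pairs:
        pairs.append({"mirna_id": mirnas[0], "gene_id": genes[0], "raw_score": -0.5})
    inter = normalize_interaction_scores(InteractionTable(pd.DataFrame(pairs)))

    prom = []
    for g in genes:
        for c in cpgs:
            if rng.random() < 0.5:
                prom.append(
                    {"cpg_id": c, "gene_id": g, "tss_distance_bp": int(rng.integers(0, 1500))}
                )
    if not prom:
        prom.append({"cpg_id": cpgs[0], "gene_id": genes[0], "tss_distance_bp": 100})
    pmap = PromoterMap(pd.DataFrame(prom))

    graphs = build_graphs(inter, pmap, mrna, mirna, meth)
    return mrna, mirna, meth, graphs
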