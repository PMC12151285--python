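# gainet

Graph-based integration of mRNA expression, miRNA expression and promoter
CpG methylation for cancer-subtype classification, with downstream feature
explanation and survival screening.

## The problem

Bulk multi-omics cohorts (e.g. breast-cancer subtyping studies) measure three
tightly coupled regulatory layers per patient: mRNA counts, miRNA counts and
CpG methylation β values. The common "early integration" baseline simply
concatenates the three feature blocks, discarding the biology that links
them: miRNAs bind target mRNAs and lower their expression, and promoter
methylation represses transcription. `gainet` instead encodes those links as
two weighted bipartite graphs — miRNA→gene edges carrying a normalised
interaction score IS ∈ (0, 1], and CpG→gene edges restricted to CpGs within
0–1500 bp upstream of the transcription start site — and folds the
regulators' per-sample state into the mRNA features themselves.

## The model

For each gene *g* and sample *s*, two multiplicative modulating factors are
computed from *g*'s regulatory partners:

```
δ1(g,s) = (1/n) Σ_i  1 / ( IS_i · exp(α · log2(e_i + 1)) )      (miRNA pressure)
δ2(g,s) = (1/n) Σ_i  1 / exp(β · log2(β_i))                     (methylation pressure)
δ(g,s)  = (w1·δ1 + w2·δ2) / (w1 + w2)                           (default w1:w2 = 1:1)
trans(g,s) = δ(g,s) · expr(g,s)
```

where `e_i` is partner miRNA expression, `β_i` a partner CpG's methylation
fraction, and α = β = 1.5 control the decay sharpness. Neutral regulators
(expression 0 with IS = 1, or β = 1) give δ = 1, so unregulated genes pass
through unchanged; active repressors push δ away from 1, making the
transformed feature carry both the gene's expression and its regulatory
context. The transformed matrix then feeds a standard pipeline: stratified
splitting, optional ADASYN-style minority oversampling, four classifier
families (one-vs-rest logistic regression, kNN with k = 4, random forest,
and a 3-hidden-layer ReLU/softmax feed-forward net), exact tree-Shapley
feature ranking, a SIFT/PolyPhen/haploinsufficiency annotation filter, and
median-split Kaplan–Meier log-rank screening of subtype-specific genes.

## Worked example

Everything runs on a self-contained synthetic cohort (no downloads). The
generator plants class signal *only* in the regulators of a fifth of the
genes, so the mRNA matrix carries subtype information only through the
regulatory graph — the situation the transform is designed to exploit:

```python
from gainet.synthetic import SyntheticConfig, generate
from gainet.preprocess import preprocess_all
from gainet.graph_transform import TransformConfig, build_graphs, transform_matrix
from gainet.classify import ModelSpec, concatenate_features
from gainet.pipeline import pooled_cv_report

bundle = generate(SyntheticConfig(seed=7))
mrna, mirna, meth, pmap, report = preprocess_all(
    bundle.mrna, bundle.mirna, bundle.meth, bundle.promoter_map
)
graphs = build_graphs(bundle.interactions, pmap, mrna, mirna, meth)
result = transform_matrix(mrna, mirna, meth, graphs, TransformConfig())
print(f"retained {len(report.samples_retained)} samples;",
      f"{graphs.n_mirna_edges} miRNA edges, {graphs.n_cpg_edges} CpG edges")

y = bundle.labels.labels_for(mrna.sample_ids)
spec = ModelSpec("random_forest", {"seed": 7})
rep_t = pooled_cv_report(spec, result.transformed.T, y, 5, seed=7)
rep_c = pooled_cv_report(spec, concatenate_features([mrna, mirna, meth]).to_numpy(), y, 5, seed=7)
print(rep_t.summary())
print(f"concatenation baseline macro F1  {rep_c.macro_f1:.4f}")
```

prints

```
retained 100 samples; 244 miRNA edges, 247 CpG edges
        precision  recall   f1  auroc
class
classA        1.0     1.0  1.0    1.0
classB        1.0     1.0  1.0    1.0
classC        1.0     1.0  1.0    1.0
classD        1.0     1.0  1.0    1.0
accuracy     1.0000
macro F1     1.0000
macro AUROC  1.0000
concatenation baseline macro F1  1.0000
```

The per-class rows are precision/recall/F1 and one-vs-rest AUROC from
five-fold cross-validated predictions pooled over all 100 samples; at the
generator's default effect sizes both integration routes separate the four
subtypes perfectly, and the transform does so from the 80 mRNA features
alone while the baseline needs all 350 raw features.

The same flow is available from the shell:

```bash
gainet simulate --seed 7 --out data/
gainet run --config run.cfg --input-dir data/ --out run_out/
```

`run_out/` then holds the filtered matrices, the δ1/δ2/δ/transformed TSVs,
evaluation and confusion tables, the importance ranking, the survival screen
and a `manifest.json` whose digest is reproducible bit-for-bit under a fixed
config and seed.

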