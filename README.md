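# precursorpred

Predict which primary-metabolism precursors a plant specialized metabolite
is biosynthesized from — given only its structure — and explain every
prediction by mapping model coefficients back to molecular substructures.

Plant natural products (alkaloids, terpenoids, phenylpropanoids,
glucosinolates, benzoxazinoids) are assembled from a small vocabulary of
building blocks: amino acids such as tryptophan, prenyl diphosphates such as
GPP/FPP/GGPP, flavonoid intermediates, and others. Knowing a compound's
precursors is the first step of any retrobiosynthesis or pathway-discovery
effort. `precursorpred` frames this as multi-label classification: for a
molecule with fingerprint x ∈ {0,1}^d and precursor label ℓ,

    score_ℓ(x) = x_kept · w_ℓ + b_ℓ,        predict ℓ  ⇔  score_ℓ(x) > 0,

where x_kept keeps the fingerprint bits with variance > τ (default
τ = 0.0628) and (w_ℓ, b_ℓ) minimize the ridge objective
‖Xw + b·1 − y‖² + α‖w‖² on ±1 targets. Evaluation uses macro metrics
(mPrecision, mRecall, mF1 — unweighted means of the per-label values, the
right choice for strongly imbalanced label sets), and model comparisons use
label-wise Wilcoxon signed-rank tests with W = min(W⁺, W⁻) and exact
small-sample p-values. Because the model is linear over traceable circular
fingerprint bits, each prediction decomposes exactly into per-substructure
contributions.

The package also contains: pathway-graph tooling that assigns precursor
labels by reverse depth-first search with a nearest-precursor stopping rule;
three split regimes (multi-label stratified 70/20/10, distant-similarity-
cluster, and cross-class-overlap adversarial splits); and a seeded synthetic
generator that plants marker substructures (indole, quinoline, catechol,
prenyl, furan) on neutral scaffolds so the whole pipeline is testable
without any database download.

## Worked example

```python
from precursorpred import (
    evaluate, fit_pipeline, generate_dataset, stratified_split,
    MoleculeRecord, attribution_report,
)

ds = generate_dataset(300, seed=42)              # planted-substructure data
split = stratified_split(ds, seed=42)
train = ds.subset(split.train_idx + split.valid_idx)
test = ds.subset(split.test_idx)

model = fit_pipeline(train.records, train.labels, ds.vocab)   # tau=0.0628, alpha=1
report = evaluate(test.labels, model.predict_labels(test.records), list(ds.vocab))
print(report["macro"])
# {'m_precision': 1.0, 'm_recall': 1.0, 'm_f1': 1.0, 'n_labels': 5}

probe = MoleculeRecord.from_smiles("probe", "C1CCCCC1c1ccc2[nH]ccc2c1")
for att in attribution_report(model, probe, "tryptophan_like", top_k=3):
    print(att.bit, round(att.coefficient, 4), att.status, sorted(att.atoms))
# 711 0.2279 active_positive [0, 1, 2, 13, 14]
# 26  0.2279 active_positive [0, 1, 2, 3, 4, 12, 13, 14]
# 119 0.2279 active_positive [2, 12, 13, 14]
```

The macro block says every one of the five synthetic precursor labels is
recovered perfectly on held-out molecules at zero label noise. The
attribution lines say the three strongest positively-weighted bits that are
*on* in the probe all trace to atoms of its indole ring — the model predicts
a tryptophan-like origin because of the indole, not because of the
scaffold. More narrative walk-throughs live in `examples/`.

A command-line interface mirrors the library
(`precursorpred train/predict/explain/compare/split/labels/generate`), e.g.:

```bash
precursorpred generate -n 200 --seed 1 -o data.csv
precursorpred train run.yaml          # writes model.json, metrics.json, search_log.csv
precursorpred predict out/model.json mols.smi -o predictions.csv
```

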