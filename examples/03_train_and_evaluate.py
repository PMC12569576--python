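"""Train the full pipeline on a synthetic planted-substructure dataset.

Fingerprint -> variance filter (tau = 0.0628) -> one-vs-rest ridge, selected
on validation macro-F1 and evaluated on a held-out test set.
"""

from precursorpred import (
    evaluate, fit_pipeline, generate_dataset, select_model, stratified_split,
)

ds = generate_dataset(300, seed=42)
split = stratified_split(ds, fractions=(0.7, 0.2, 0.1), seed=42)
train, valid, test = (ds.subset(i) for i in (split.train_idx, split.valid_idx, split.test_idx))

model, log = select_model(
    train.records, train.labels, valid.records, valid.labels, ds.vocab,
    alpha_grid=[0.1, 1.0, 10.0], tau_grid=[0.0628],
)
print(log.to_string(index=False))

report = evaluate(test.labels, model.predict_labels(test.records), list(ds.vocab))
print(f"\ntest mF1 = {report['macro']['m_f1']:.3f}, "
      f"mPrecision = {report['macro']['m_precision']:.3f}, "
      f"mRecall = {report['macro']['m_recall']:.3f}")
# Near-perfect macro metrics: at zero label noise the planted markers are
# fully recoverable from the fingerprint bits.
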