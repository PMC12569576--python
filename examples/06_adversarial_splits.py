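"""The three split regimes, including the two adversarial ones.

Distant-cluster splitting tests extrapolation to unseen chemotypes;
class-overlap splitting tests whether near-identical structures from
different biosynthetic classes can still be told apart.
"""

from precursorpred import (
    class_overlap_split, distant_cluster_split, generate_dataset, stratified_split,
)

ds = generate_dataset(150, seed=3)

for name, split in [
    ("stratified", stratified_split(ds, seed=0)),
    ("distant_cluster", distant_cluster_split(ds, seed=0)),
    ("class_overlap", class_overlap_split(ds, seed=0)),
]:
    print(f"{name:16s} train={len(split.train_idx):3d} valid={len(split.valid_idx):3d} "
          f"test={len(split.test_idx):3d}  notes={split.notes}")
# The distant-cluster test set comes from whole similarity clusters far from
# the rest; the class-overlap test set collects cross-class near-duplicates.
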