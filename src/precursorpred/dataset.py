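"""Labeled multi-label datasets and the three train/validation/test split regimes.

A labeled dataset pairs molecule records with an n×L binary label matrix over
a fixed precursor vocabulary; one compound may carry several positive labels.
Three split regimes are provided:

* ``stratified`` — multi-label iterative stratification at 70/20/10 so each
  label's positive rate is approximately preserved in every subset;
* ``distant_cluster`` — Butina sphere-exclusion clustering on Tanimoto
  distance; the clusters most dissimilar to the rest of the data form the
  test pool, with a minimum number of positives per label moved back to
  train so every precursor stays learnable;
* ``class_overlap`` — the adversarial regime: every compound involved in a
  highly similar cross-class pair is forced into the test set, so the model
  must separate near-identical structures from different biosynthetic
  origins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit.ML.Cluster import Butina

from .errors import ConfigError, DataError, SmilesParseError
from .featurize import (
    FingerprintConfig,
    MoleculeRecord,
    fingerprint,
    similarity_matrix,
)
from .pathway import PrecursorVocabulary

logger = logging.getLogger(__name__)

RESERVED_COLUMNS = ("id", "smiles", "np_class")


@dataclass
class LabeledDataset:
    """Molecule records aligned with an n×L binary label matrix."""

    records: list[MoleculeRecord]
    labels: np.ndarray
    vocab: PrecursorVocabulary
    n_dropped: int = 0  # rows discarded at read time for unparsable SMILES

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2:
            raise DataError("labels must be a 2-D matrix")
        n, L = self.labels.shape
        if n != len(self.records):
            raise DataError(f"{len(self.records)} records but {n} label rows")
        if L != len(self.vocab):
            raise DataError(f"{len(self.vocab)} vocabulary entries but {L} label columns")
        bad = ~np.isin(self.labels, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"label value {self.labels[i, j]} at row {i}, column {self.vocab.names[j]!r} "
                "is outside {0, 1}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = list(idx)
        return LabeledDataset(
            records=[self.records[i] for i in idx],
            labels=self.labels[idx],
            vocab=self.vocab,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "np_class": [r.np_class for r in self.records],
            }
        )
        for j, name in enumerate(self.vocab):
            df[name] = self.labels[:, j]
        return df


def read_dataset(path) -> LabeledDataset:
    """Read a dataset CSV: columns ``id`` (optional), ``smiles``, ``np_class``
    (optional), then one 0/1 column per precursor label.

    Rows whose SMILES does not parse are dropped with a logged count; a label
    value outside {0, 1} is a schema error naming the row and column.
    """
    df = pd.read_csv(path)
    if "smiles" not in df.columns:
        raise DataError(f"dataset {path} has no 'smiles' column (columns: {list(df.columns)})")
    label_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if not label_cols:
        raise DataError(f"dataset {path} has no label columns")
    for col in label_cols:
        vals = df[col]
        bad = ~vals.isin([0, 1, "0", "1"])
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise DataError(
                f"label value {vals.iloc[row]!r} at row {row}, column {col!r} is outside {{0, 1}}"
            )
    records: list[MoleculeRecord] = []
    rows: list[int] = []
    dropped = 0
    for i, row in df.iterrows():
        rid = str(row["id"]) if "id" in df.columns else f"mol{i:05d}"
        np_class = row.get("np_class")
        if pd.isna(np_class):
            np_class = None
        try:
            rec = MoleculeRecord.from_smiles(rid, str(row["smiles"]), np_class)
        except SmilesParseError:
            dropped += 1
            continue
        records.append(rec)
        rows.append(i)
    if dropped:
        logger.warning("dropped %d rows with unparsable SMILES while reading %s", dropped, path)
    labels = df.loc[rows, label_cols].to_numpy(dtype=np.int8)
    ds = LabeledDataset(
        records=records,
        labels=labels,
        vocab=PrecursorVocabulary(tuple(label_cols)),
        n_dropped=dropped,
    )
    return ds


def write_dataset(dataset: LabeledDataset, path) -> None:
    """Write the CSV dialect read by :func:`read_dataset` (round-trip stable)."""
    dataset.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# Splits
# --------------------------------------------------------------------------

SPLIT_REGIMES = ("stratified", "distant_cluster", "class_overlap")


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive train/valid/test index lists plus provenance."""

    train_idx: list[int]
    valid_idx: list[int]
    test_idx: list[int]
    regime: str
    seed: int
    config: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        parts = [self.train_idx, self.valid_idx, self.test_idx]
        allidx = sorted(i for p in parts for i in p)
        if len(set(allidx)) != len(allidx):
            raise DataError("split subsets overlap")
        if self.regime not in SPLIT_REGIMES:
            raise ConfigError(f"unknown split regime {self.regime!r}")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "regime": self.regime,
                    "seed": self.seed,
                    "train_idx": list(map(int, self.train_idx)),
                    "valid_idx": list(map(int, self.valid_idx)),
                    "test_idx": list(map(int, self.test_idx)),
                    "config": self.config,
                    "notes": self.notes,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "DatasetSplit":
        d = json.loads(Path(path).read_text())
        return cls(
            train_idx=d["train_idx"], valid_idx=d["valid_idx"], test_idx=d["test_idx"],
            regime=d["regime"], seed=d["seed"], config=d.get("config", {}),
            notes=d.get("notes", {}),
        )


def _target_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment so subset sizes sum exactly to n."""
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    short = n - sum(sizes)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for k in range(short):
        sizes[order[k]] += 1
    return sizes


def stratified_split(
    dataset: LabeledDataset,
    fractions: Sequence[float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Multi-label iterative stratification into train/valid/test.

    Greedy rarest-label-first assignment: repeatedly take the label with the
    fewest unassigned positives and place its examples into the subset whose
    per-label quota for that label is least satisfied, under hard per-subset
    size caps so the 70/20/10 proportions are met within ±1.  Deterministic
    given the seed (ties broken by the seeded RNG).
    """
    if len(fractions) != 3:
        raise ConfigError("fractions must have exactly three entries (train, valid, test)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(dataset)
    if n < 10:
        raise DataError(f"need at least 10 compounds to split, got {n}")
    rng = np.random.default_rng(seed)
    Y = dataset.labels.astype(int)
    L = Y.shape[1]
    caps = _target_sizes(n, fractions)
    # desired positives per subset for every label
    desired = np.array([[Y[:, j].sum() * f for f in fractions] for j in range(L)])
    assigned = np.full(n, -1, dtype=int)
    remaining_caps = np.array(caps, dtype=float)

    def place(i: int, prefer: np.ndarray) -> None:
        # prefer: per-subset priority score (higher = better); caps are hard
        order = np.lexsort((rng.random(3), -remaining_caps, -prefer))
        for s in order:
            if remaining_caps[s] >= 1:
                assigned[i] = s
                remaining_caps[s] -= 1
                desired[Y[i] == 1, s] -= 1
                return
        raise DataError("no subset capacity left")  # unreachable: caps sum to n

    while True:
        unassigned = assigned == -1
        if not unassigned.any():
            break
        pos_left = (Y[unassigned] == 1).sum(axis=0)
        active = np.where(pos_left > 0)[0]
        if active.size == 0:
            # label-free leftovers: fill by remaining capacity
            for i in np.where(unassigned)[0]:
                place(i, np.zeros(3))
            break
        j = active[np.argmin(pos_left[active])]  # rarest label first
        for i in np.where(unassigned & (Y[:, j] == 1))[0]:
            place(i, desired[j])

    split = DatasetSplit(
        train_idx=sorted(np.where(assigned == 0)[0].tolist()),
        valid_idx=sorted(np.where(assigned == 1)[0].tolist()),
        test_idx=sorted(np.where(assigned == 2)[0].tolist()),
        regime="stratified",
        seed=seed,
        config={"fractions": list(fractions)},
    )
    return split


def _butina_clusters(S: np.ndarray, cutoff: float) -> list[tuple[int, ...]]:
    """Butina sphere-exclusion clustering on 1 − Tanimoto distance."""
    n = S.shape[0]
    dists = []
    for i in range(1, n):
        for j in range(i):
            dists.append(1.0 - S[i, j])
    return list(Butina.ClusterData(dists, n, cutoff, isDistData=True))


def distant_cluster_split(
    dataset: LabeledDataset,
    cluster_distance_cutoff: float = 0.6,
    test_fraction: float = 0.1,
    min_train_positives: int = 2,
    seed: int = 0,
    fp_config: FingerprintConfig = FingerprintConfig(),
) -> DatasetSplit:
    """Adversarial split from chemically distant similarity clusters.

    Compounds are clustered with Butina sphere exclusion on 1 − Tanimoto;
    clusters least similar (by mean inter-cluster Tanimoto) to the remaining
    data are moved whole into the test pool until it reaches
    ``test_fraction``.  To keep every precursor learnable, for each label at
    least ``min_train_positives`` positive compounds are pulled back from the
    test pool into training.  The remainder is split into train/valid by
    stratification at a 7:2 ratio.
    """
    n = len(dataset)
    if n < 20:
        raise DataError(f"need at least 20 compounds for a distant-cluster split, got {n}")
    S = similarity_matrix(dataset.records, fp_config)
    clusters = _butina_clusters(S, cluster_distance_cutoff)
    if len(clusters) < 2:
        raise DataError(
            "all compounds fall in a single similarity cluster; "
            "no distant cluster can be formed (try a smaller cutoff)"
        )
    # distance of each cluster to the rest of the dataset
    scores = []
    for c in clusters:
        members = np.array(c)
        outside = np.setdiff1d(np.arange(n), members)
        scores.append(float(S[np.ix_(members, outside)].mean()))
    order = np.argsort(scores, kind="stable")  # most distant first
    target = int(round(test_fraction * n))
    test: list[int] = []
    for k in order:
        if len(test) >= target:
            break
        test.extend(clusters[k])
    test_set = set(test)
    # pin per-label minimum representation directly to train
    Y = dataset.labels
    pinned: set[int] = set()
    moved_back: list[int] = []
    for j in range(Y.shape[1]):
        pos = np.where(Y[:, j] == 1)[0]
        if pos.size == 0:
            continue
        outside = sorted(int(i) for i in pos if i not in test_set)
        take = outside[:min_train_positives]
        need = min_train_positives - len(take)
        if need > 0:
            from_test = sorted(int(i) for i in pos if i in test_set)[:need]
            for i in from_test:
                test_set.discard(i)
                moved_back.append(i)
            take += from_test
        pinned.update(take)
    remainder = sorted(set(range(n)) - test_set - pinned)
    if len(remainder) >= 10:
        rest = dataset.subset(remainder)
        sub = stratified_split(rest, fractions=(7 / 9, 2 / 9, 0.0), seed=seed)
        train_rest = [remainder[i] for i in sub.train_idx]
        valid_idx = sorted(remainder[i] for i in sub.valid_idx)
    else:  # too few unpinned compounds to stratify a validation set
        train_rest = remainder
        valid_idx = []
    return DatasetSplit(
        train_idx=sorted(set(train_rest) | pinned),
        valid_idx=valid_idx,
        test_idx=sorted(test_set),
        regime="distant_cluster",
        seed=seed,
        config={
            "cluster_distance_cutoff": cluster_distance_cutoff,
            "test_fraction": test_fraction,
            "min_train_positives": min_train_positives,
        },
        notes={
            "n_clusters": len(clusters),
            "moved_back_to_train": sorted(map(int, moved_back)),
        },
    )


def class_overlap_split(
    dataset: LabeledDataset,
    similarity_threshold: float = 0.7,
    seed: int = 0,
    fp_config: FingerprintConfig = FingerprintConfig(),
) -> DatasetSplit:
    """Adversarial split on cross-class structural overlap.

    Every compound participating in a pair with Tanimoto ≥ threshold whose
    members carry *different* natural-product class tags goes to the test
    set; the rest is stratified into train/valid.  If no such pair exists the
    operation reports an empty adversarial core and falls back to a plain
    stratified split.
    """
    if any(r.np_class is None for r in dataset.records):
        raise ConfigError("class_overlap_split requires an np_class tag on every record")
    n = len(dataset)
    S = similarity_matrix(dataset.records, fp_config)
    classes = np.array([r.np_class for r in dataset.records])
    test_set: set[int] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if classes[i] != classes[j] and S[i, j] >= similarity_threshold:
                test_set.update((i, j))
    if not test_set:
        logger.warning(
            "no cross-class pair reaches Tanimoto %.2f; adversarial test core is empty, "
            "falling back to a stratified split", similarity_threshold,
        )
        base = stratified_split(dataset, seed=seed)
        return DatasetSplit(
            train_idx=base.train_idx, valid_idx=base.valid_idx, test_idx=base.test_idx,
            regime="class_overlap", seed=seed,
            config={"similarity_threshold": similarity_threshold},
            notes={"adversarial_core_empty": True},
        )
    remainder = sorted(set(range(n)) - test_set)
    if len(remainder) >= 10:
        rest = dataset.subset(remainder)
        sub = stratified_split(rest, fractions=(7 / 9, 2 / 9, 0.0), seed=seed)
        train_idx = sorted(remainder[i] for i in sub.train_idx)
        valid_idx = sorted(remainder[i] for i in sub.valid_idx)
    else:
        train_idx, valid_idx = remainder, []
    return DatasetSplit(
        train_idx=train_idx,
        valid_idx=valid_idx,
        test_idx=sorted(test_set),
        regime="class_overlap",
        seed=seed,
        config={"similarity_threshold": similarity_threshold},
        notes={"adversarial_core_empty": False, "n_adversarial": len(test_set)},
    )
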