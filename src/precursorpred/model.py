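"""Variance-threshold feature selection, one-vs-rest ridge classification, and
validation-driven model selection.

The classifier is the standard "ridge classifier": per label, regularized
least squares on ±1 targets,

    minimize ||X w + b·1 − y||²  +  alpha ||w||²      (intercept unpenalized)

solved in closed form via the centered normal equations, with sign
thresholding at 0 for prediction.  Before fitting, near-constant fingerprint
bits are removed by a variance threshold: a binary column with positive rate
p has population variance p(1−p), and columns with variance ≤ τ are dropped.
The default τ = 0.0628 removes bits present in fewer than ~6.7 % (or more
than ~93.3 %) of training molecules.

Model selection is an exhaustive seeded search over (alpha, τ, radius) grids
maximizing macro-F1 on the validation set; ties go to the smaller alpha,
then the smaller τ, then the smaller radius.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ConfigError, DataError
from .featurize import FingerprintConfig, MoleculeRecord, feature_matrix
from .metrics import evaluate
from .pathway import PrecursorVocabulary

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: Variance threshold selected by the validation search in the original study.
DEFAULT_VARIANCE_THRESHOLD = 0.0628
DEFAULT_ALPHA = 1.0


@dataclass(frozen=True)
class VarianceFilter:
    """Keeps exactly the columns whose population variance exceeds ``threshold``."""

    threshold: float
    kept_indices: tuple[int, ...]
    n_features_in: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in:
            raise ConfigError(
                f"filter was fit on {self.n_features_in} columns, got {X.shape[1]}"
            )
        return X[:, list(self.kept_indices)]


def fit_variance_filter(X: np.ndarray, threshold: float = DEFAULT_VARIANCE_THRESHOLD) -> VarianceFilter:
    """Fit the variance filter: column j is kept iff Var(X_j) > threshold.

    Population (ddof=0) variance, so for a binary column with mean p the
    criterion is p(1−p) > τ.  The comparison is strict: constant columns
    (variance 0) are removed even at τ = 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("variance filter needs a 2-D matrix with at least 2 rows")
    if threshold < 0:
        raise ConfigError(f"variance threshold must be >= 0, got {threshold}")
    var = X.var(axis=0)  # ddof=0
    kept = tuple(int(j) for j in np.where(var > threshold)[0])
    return VarianceFilter(threshold=threshold, kept_indices=kept, n_features_in=X.shape[1])


def fit_ridge_ovr(
    X_kept: np.ndarray,
    Y: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    fit_intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Closed-form one-vs-rest ridge fit on ±1 targets.

    Per label ℓ the target vector is y = 2·Y_ℓ − 1 and (w_ℓ, b_ℓ) minimize
    ‖X w + b·1 − y‖² + alpha‖w‖² with the intercept left unpenalized
    (solved by centering X and y).  Returns (W of shape d×L, b of shape L,
    degenerate label indices).  A label column with no positives or no
    negatives gets a constant predictor: w = 0, b = ±1.
    """
    X = np.asarray(X_kept, dtype=float)
    Y = np.asarray(Y)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, d = X.shape
    if n < 2:
        raise DataError("ridge fit needs at least 2 samples")
    if Y.shape[0] != n:
        raise DataError(f"X has {n} rows but Y has {Y.shape[0]}")
    if alpha < 0:
        raise ConfigError(f"alpha must be >= 0, got {alpha}")
    L = Y.shape[1]
    T = 2.0 * Y.astype(float) - 1.0  # ±1 targets

    degenerate = [j for j in range(L) if len(np.unique(Y[:, j])) < 2]
    if degenerate:
        logger.warning(
            "labels %s have a single class in training; using constant predictors",
            degenerate,
        )

    if fit_intercept:
        x_mean = X.mean(axis=0)
        t_mean = T.mean(axis=0)
        Xc = X - x_mean
        Tc = T - t_mean
    else:
        x_mean = np.zeros(d)
        t_mean = np.zeros(L)
        Xc, Tc = X, T

    G = Xc.T @ Xc + alpha * np.eye(d)
    if alpha == 0:
        # unregularized: the normal equations are singular iff Xc is rank-deficient
        if np.linalg.matrix_rank(Xc) < d:
            raise DataError(
                "alpha = 0 with rank-deficient features: the least-squares solution "
                "is not unique; use alpha > 0"
            )
        W = scipy.linalg.solve(G, Xc.T @ Tc, assume_a="sym")
    else:
        W = scipy.linalg.solve(G, Xc.T @ Tc, assume_a="pos")
    b = t_mean - x_mean @ W if fit_intercept else np.zeros(L)

    for j in degenerate:
        W[:, j] = 0.0
        b[j] = 1.0 if Y[0, j] == 1 else -1.0
    return W, np.asarray(b, dtype=float), degenerate


@dataclass
class RidgeOvRModel:
    """Fitted pipeline: fingerprint → variance filter → affine per-label scores.

    ``score(x) = x_kept · W + b``; label ℓ is predicted active iff its score
    is strictly positive (a score of exactly 0 is inactive).
    """

    W: np.ndarray  # d_kept × L
    b: np.ndarray  # L
    alpha: float
    filter: VarianceFilter
    fp_config: FingerprintConfig
    vocab: PrecursorVocabulary
    degenerate_labels: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.shape != (len(self.filter.kept_indices), len(self.vocab)):
            raise ConfigError(
                f"weight matrix shape {self.W.shape} inconsistent with "
                f"{len(self.filter.kept_indices)} kept features × {len(self.vocab)} labels"
            )

    def decision_scores(
        self, records: Sequence[MoleculeRecord], X: np.ndarray | None = None
    ) -> np.ndarray:
        """n×L real score matrix.  ``X`` may supply a precomputed raw feature
        matrix (must match the model's fingerprint width)."""
        if X is None:
            X = feature_matrix(records, self.fp_config)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.fp_config.n_bits:
            raise ConfigError(
                f"feature width {X.shape[1]} does not match model fingerprint "
                f"width {self.fp_config.n_bits}"
            )
        return self.filter.transform(X) @ self.W + self.b

    def predict_labels(
        self, records: Sequence[MoleculeRecord], X: np.ndarray | None = None
    ) -> np.ndarray:
        """n×L binary predictions: active iff score > 0."""
        return (self.decision_scores(records, X) > 0).astype(np.int8)

    # -- serialization: versioned, human-diffable JSON (no pickles) --------

    def to_json(self, path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "vocab": list(self.vocab.names),
            "fp_config": {
                "kind": self.fp_config.kind,
                "radius": self.fp_config.radius,
                "n_bits": self.fp_config.n_bits,
            },
            "variance_threshold": self.filter.threshold,
            "kept_indices": list(self.filter.kept_indices),
            "n_features_in": self.filter.n_features_in,
            "alpha": self.alpha,
            "W": self.W.tolist(),
            "b": self.b.tolist(),
            "degenerate_labels": list(map(int, self.degenerate_labels)),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "RidgeOvRModel":
        d = json.loads(Path(path).read_text())
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ConfigError(f"unsupported model format version {d.get('format_version')}")
        return cls(
            W=np.array(d["W"], dtype=float),
            b=np.array(d["b"], dtype=float),
            alpha=d["alpha"],
            filter=VarianceFilter(
                threshold=d["variance_threshold"],
                kept_indices=tuple(d["kept_indices"]),
                n_features_in=d["n_features_in"],
            ),
            fp_config=FingerprintConfig(**d["fp_config"]),
            vocab=PrecursorVocabulary(tuple(d["vocab"])),
            degenerate_labels=d.get("degenerate_labels", []),
        )


def fit_pipeline(
    records: Sequence[MoleculeRecord],
    Y: np.ndarray,
    vocab: PrecursorVocabulary,
    fp_config: FingerprintConfig = FingerprintConfig(),
    tau: float = DEFAULT_VARIANCE_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> RidgeOvRModel:
    """Fit the full pipeline on training records: featurize, filter, ridge."""
    X = feature_matrix(records, fp_config)
    filt = fit_variance_filter(X, tau)
    W, b, degenerate = fit_ridge_ovr(filt.transform(X).astype(float), Y, alpha)
    return RidgeOvRModel(
        W=W, b=b, alpha=alpha, filter=filt, fp_config=fp_config, vocab=vocab,
        degenerate_labels=degenerate,
    )


def select_model(
    train_records: Sequence[MoleculeRecord],
    Y_train: np.ndarray,
    valid_records: Sequence[MoleculeRecord],
    Y_valid: np.ndarray,
    vocab: PrecursorVocabulary,
    alpha_grid: Sequence[float] = (0.1, 1.0, 10.0),
    tau_grid: Sequence[float] = (DEFAULT_VARIANCE_THRESHOLD,),
    radius_grid: Sequence[int] = (2,),
    n_bits: int = 2048,
    fp_kind: str = "circular",
    seed: int = 0,
    max_trials: int | None = None,
) -> tuple[RidgeOvRModel, pd.DataFrame]:
    """Grid search maximizing validation macro-F1.

    Every (radius, τ, alpha) candidate is fit on train and scored on valid;
    if ``max_trials`` is given, a seeded random subsample of the grid is
    evaluated instead of the full grid.  Returns the winning refit model and
    the full per-trial log.  Exact-tie rule: smaller alpha, then smaller τ,
    then smaller radius.
    """
    if not alpha_grid or not tau_grid or not radius_grid:
        raise ConfigError("search grids must be non-empty")
    combos = [
        (r, t, a)
        for r in sorted(radius_grid)
        for t in sorted(tau_grid)
        for a in sorted(alpha_grid)
    ]
    if max_trials is not None and max_trials < len(combos):
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(len(combos), size=max_trials, replace=False))
        combos = [combos[i] for i in keep]

    rows = []
    best = None  # (mf1, -alpha, -tau, -radius) maximized lexicographically
    best_model = None
    for trial, (radius, tau, alpha) in enumerate(combos):
        fp_config = FingerprintConfig(kind=fp_kind, radius=radius, n_bits=n_bits)
        model = fit_pipeline(train_records, Y_train, vocab, fp_config, tau, alpha)
        rep = evaluate(Y_valid, model.predict_labels(valid_records), list(vocab))
        mf1 = rep["macro"]["m_f1"]
        rows.append(
            {"trial": trial, "alpha": alpha, "tau": tau, "radius": radius, "valid_mF1": mf1}
        )
        key = (mf1, -alpha, -tau, -radius)
        if best is None or key > best:
            best = key
            best_model = model
    log = pd.DataFrame(rows)
    return best_model, log
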