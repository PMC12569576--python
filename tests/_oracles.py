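"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle re-derives an expected value by a method unrelated to the
implementation it checks: exhaustive path enumeration for pathway labeling,
a generic numerical optimizer for the ridge closed form, full sign-flip
enumeration for the Wilcoxon signed-rank null, and raw-count arithmetic for
the macro metrics.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata


def nearest_precursor_bruteforce(g: nx.DiGraph, target: str, vocab: set[str]) -> set[str]:
    """Enumerate every simple directed path into ``target``; per path take the
    vocabulary node nearest the target (no vocab node between it and target)."""
    found = set()
    for source in g.nodes:
        if source == target or source not in vocab:
            continue
        for path in nx.all_simple_paths(g, source, target):
            interior = path[1:-1]
            if not any(node in vocab for node in interior):
                found.add(source)
                break
    return found


def ridge_objective_minimizer(
    X: np.ndarray, y: np.ndarray, alpha: float, fit_intercept: bool = True
) -> tuple[np.ndarray, float]:
    """Minimize ||Xw + b − y||² + alpha||w||² with a generic quasi-Newton
    optimizer (intercept unpenalized)."""
    n, d = X.shape

    def obj(theta):
        w = theta[:d]
        b = theta[d] if fit_intercept else 0.0
        r = X @ w + b - y
        return r @ r + alpha * (w @ w)

    def grad(theta):
        w = theta[:d]
        b = theta[d] if fit_intercept else 0.0
        r = X @ w + b - y
        g = np.empty(d + (1 if fit_intercept else 0))
        g[:d] = 2 * X.T @ r + 2 * alpha * w
        if fit_intercept:
            g[d] = 2 * r.sum()
        return g

    x0 = np.zeros(d + (1 if fit_intercept else 0))
    res = minimize(obj, x0, jac=grad, method="L-BFGS-B",
                   options={"maxiter": 10000, "ftol": 1e-15, "gtol": 1e-12})
    w = res.x[:d]
    b = res.x[d] if fit_intercept else 0.0
    return w, b


def wsr_enumeration(d: np.ndarray) -> tuple[float, float, float, float]:
    """Exact Wilcoxon signed-rank by full enumeration of all 2^n sign
    assignments.  Returns (W+, W−, W, two-sided p)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 0.0, 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product((False, True), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if wp <= w + 1e-12:
            count += 1
    p = min(1.0, 2.0 * count / 2**n)
    return float(w_plus), float(w_minus), float(w), p


def macro_bruteforce(Y_true: np.ndarray, Y_pred: np.ndarray) -> dict:
    """Re-derive per-label and macro metrics directly from raw counts."""
    precs, recs, f1s = [], [], []
    for j in range(Y_true.shape[1]):
        t, p = Y_true[:, j], Y_pred[:, j]
        tp = sum(1 for a, b in zip(t, p) if a == 1 and b == 1)
        fp = sum(1 for a, b in zip(t, p) if a == 0 and b == 1)
        fn = sum(1 for a, b in zip(t, p) if a == 1 and b == 0)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    return {
        "precision": precs,
        "recall": recs,
        "f1": f1s,
        "m_precision": sum(precs) / len(precs),
        "m_recall": sum(recs) / len(recs),
        "m_f1": sum(f1s) / len(f1s),
    }


def random_dag(rng: np.random.Generator, max_nodes: int = 8) -> nx.DiGraph:
    """Random DAG on 3..max_nodes nodes via a random topological order."""
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    order = rng.permutation(n)
    g = nx.DiGraph()
    g.add_nodes_from(names)
    p = float(rng.uniform(0.2, 0.6))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[order[i]], names[order[j]])
    return g
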