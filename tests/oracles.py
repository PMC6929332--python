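"""Independent brute-force reference implementations used by the tests.

These are deliberately written as explicit loops over sets and scalars so
they share no code path with the vectorized package implementations they
check.
"""

from __future__ import annotations

import numpy as np


def jaccard_by_sets(w: np.ndarray) -> np.ndarray:
    """Bipartite Jaccard via explicit set enumeration."""
    n_r, n_d = w.shape
    drug_sets = [set(np.nonzero(w[i])[0].tolist()) for i in range(n_r)]
    disease_sets = [set(np.nonzero(w[:, j])[0].tolist()) for j in range(n_d)]
    out = np.zeros((n_r, n_d))
    for i in range(n_r):
        for j in range(n_d):
            two_hop: set[int] = set()
            for drug in disease_sets[j]:
                two_hop |= drug_sets[drug]
            union = drug_sets[i] | two_hop
            if union:
                out[i, j] = len(drug_sets[i] & two_hop) / len(union)
    return out


def sharing_weights_by_loops(w: np.ndarray, axis: int) -> dict[tuple[int, int], int]:
    """Shared-counterpart edge weights via a double loop; axis 0 = drugs."""
    m = w if axis == 0 else w.T
    n = m.shape[0]
    weights: dict[tuple[int, int], int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            count = sum(
                1 for k in range(m.shape[1]) if m[i, k] == 1 and m[j, k] == 1
            )
            if count > 0:
                weights[(i, j)] = count
    return weights


def gip_by_loops(profiles: np.ndarray, gamma_tilde: float) -> np.ndarray:
    """Gaussian profile kernel via scalar loops."""
    n = profiles.shape[0]
    mean_sq = sum(float(profiles[i] @ profiles[i]) for i in range(n)) / n
    gamma = gamma_tilde / mean_sq
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            diff = profiles[i] - profiles[j]
            out[i, j] = np.exp(-gamma * float(diff @ diff))
    return out


def drug_walk_by_scalars(
    s_d: np.ndarray, w: np.ndarray, floors: np.ndarray, alpha: float
) -> np.ndarray:
    """Per-element scalar recursion of the drug-side walk."""
    n_r, n_d = w.shape
    f = w.astype(float).copy()
    t_max = int(max(floors)) if len(floors) else 0
    for t in range(1, t_max + 1):
        nxt = f.copy()
        for i in range(n_r):
            if t <= floors[i]:
                for j in range(n_d):
                    acc = 0.0
                    for k in range(n_d):
                        acc += s_d[k, j] * f[i, k]
                    nxt[i, j] = alpha * acc + (1 - alpha) * w[i, j]
        f = nxt
    return f


def disease_walk_by_scalars(
    s_r: np.ndarray, w: np.ndarray, floors: np.ndarray, alpha: float
) -> np.ndarray:
    """Per-element scalar recursion of the disease-side walk."""
    n_r, n_d = w.shape
    f = w.astype(float).copy()
    t_max = int(max(floors)) if len(floors) else 0
    for t in range(1, t_max + 1):
        nxt = f.copy()
        for j in range(n_d):
            if t <= floors[j]:
                for i in range(n_r):
                    acc = 0.0
                    for k in range(n_r):
                        acc += s_r[i, k] * f[k, j]
                    nxt[i, j] = alpha * acc + (1 - alpha) * w[i, j]
        f = nxt
    return f


def auroc_trapezoid(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC integral by the trapezoidal rule over distinct thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    tpr = [0.0]
    fpr = [0.0]
    for thr in thresholds:
        predicted = scores >= thr
        tpr.append(float((predicted & (labels == 1)).sum()) / n_pos)
        fpr.append(float((predicted & (labels == 0)).sum()) / n_neg)
    return float(np.trapezoid(tpr, fpr))


def random_bipartite(rng: np.random.Generator, n_r: int, n_d: int, p: float = 0.3):
    """Random binary association matrix, re-drawn until it has a positive entry."""
    while True:
        w = (rng.random((n_r, n_d)) < p).astype(np.int8)
        if w.sum() > 0:
            return w
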