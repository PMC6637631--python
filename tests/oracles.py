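"""Independent brute-force oracles used to cross-check the implementation.

Every function here recomputes a quantity by direct enumeration or by literal
composition of the underlying probability definitions, deliberately avoiding
the package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np


def set_similarity(R0: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity by explicit neighbor-set enumeration."""
    nm = R0.shape[0]
    sets = [set(np.flatnonzero(R0[m]).tolist()) for m in range(nm)]
    S = np.zeros((nm, nm))
    for k in range(nm):
        for r in range(nm):
            if k == r or not sets[k] or not sets[r]:
                continue
            S[k, r] = len(sets[k] & sets[r]) / np.sqrt(len(sets[k]) * len(sets[r]))
    return S


def set_cooccurrence(R0: np.ndarray) -> np.ndarray:
    nm = R0.shape[0]
    sets = [set(np.flatnonzero(R0[m]).tolist()) for m in range(nm)]
    C = np.zeros((nm, nm), dtype=int)
    for k in range(nm):
        for r in range(nm):
            if k != r and sets[k] & sets[r]:
                C[k, r] = 1
    return C


def topk_recommender(Rp: np.ndarray, R0: np.ndarray, k: int) -> np.ndarray:
    """Literal double-loop evaluation of the top-k neighborhood summation:
    score(t, u) = sum of Rp[t, m] over m in N(u) ∩ topk(t)."""
    nm, nu = R0.shape
    out = np.zeros((nm, nu))
    for t in range(nm):
        order = sorted(range(nm), key=lambda m: (-Rp[t, m], m))
        top = set(order[: min(k, nm)])
        for u in range(nu):
            known = set(np.flatnonzero(R0[:, u]).tolist())
            out[t, u] = sum(Rp[t, m] for m in known & top)
    return out


def bayes_score_oracle(cn1, cn2, evidence, priors, alpha: float) -> float:
    """Posterior-odds score assembled from the per-neighbor conditional
    probabilities themselves (Laplace-smoothed), not from count ratios."""
    p1 = priors.p1
    p0 = priors.p0
    s = p1 / p0
    for m in cn1:
        e = evidence[m]
        p_e1_m = (e.n_plus + 1) / (e.n_plus + e.n_minus + 2)  # smoothed conditional
        p_e0_m = 1.0 - p_e1_m
        # Bayes-inverted likelihood ratio: p(m|e=1)/p(m|e=0)
        s *= (p_e1_m / p1) / (p_e0_m / p0)
    for m in cn2:
        e = evidence[m]
        p_e1_m = (e.n_plus + 1) / (e.n_plus + e.n_minus + 2)
        p_e0_m = 1.0 - p_e1_m
        s *= (p_e1_m / p_e0_m) ** alpha * (p0 / p1)
    return s


def concordance_auc(scores, labels) -> float:
    """Mann-Whitney AUC by O(n^2) pair counting, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_network(rng, nm=8, nl=5, nd=4, density=0.3):
    """Random original/full adjacency blocks plus a known-association matrix;
    the full blocks add a few recommended edges on top of the original ones."""
    O_l = (rng.random((nm, nl)) < density).astype(np.int8)
    O_d = (rng.random((nm, nd)) < density).astype(np.int8)
    extra_l = (rng.random((nm, nl)) < density / 2).astype(np.int8)
    extra_d = (rng.random((nm, nd)) < density / 2).astype(np.int8)
    A_l = np.maximum(O_l, extra_l)
    A_d = np.maximum(O_d, extra_d)
    Y = (rng.random((nl, nd)) < density).astype(np.int8)
    return O_l, O_d, A_l, A_d, Y
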