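"""Naive-Bayes common-neighbor scoring of lncRNA-disease pairs.

Each candidate pair (l, d) is scored by the posterior odds that an edge exists,
under conditional independence of its common-neighbor miRNAs on the densified
network. A common neighbor m contributes the Laplace-smoothed evidence ratio
(N+ + 1)/(N- + 1), where N+ counts known lncRNA-disease associations bridged by
m and N- = N_l * N_d - N+ the unbridged pairs; neighbors reached through a
recommended edge (CN2) have their ratio damped by an exponent alpha in (0, 1],
reflecting the lower credibility of recommended links. Each neighbor of either
kind also carries the constant factor 1/phi (inverse prior odds) arising from
Bayes inversion of the per-neighbor conditionals, so

    S(l, d) = phi * prod_{m in CN1} [ r_m / phi ] * prod_{m in CN2} [ r_m^alpha / phi ]

with r_m the smoothed evidence ratio and phi the global prior odds. The raw
odds are then normalized resource-allocation style:

    S'(l, d) = log S(l, d) / prod_{m in CN1 ∪ CN2} k_m

with k_m the degree of m on the densified network, and an empty-neighborhood
denominator of 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PriorOdds:
    """Global prior on a lncRNA-disease edge: p1 = |known| / (nl * nd)."""

    known_count: int
    total_pairs: int

    def __post_init__(self) -> None:
        if not 0 < self.known_count < self.total_pairs:
            raise ValueError(
                f"degenerate prior: {self.known_count} known of {self.total_pairs} pairs"
            )

    @property
    def p1(self) -> float:
        return self.known_count / self.total_pairs

    @property
    def p0(self) -> float:
        return 1.0 - self.p1

    @property
    def odds(self) -> float:
        return self.p1 / self.p0


def compute_priors(n_known: int, n_lnc: int, n_dis: int) -> PriorOdds:
    if n_lnc < 1 or n_dis < 1:
        raise ValueError("need at least one lncRNA and one disease")
    return PriorOdds(known_count=n_known, total_pairs=n_lnc * n_dis)


@dataclass(frozen=True)
class NeighborPartition:
    """Common-neighbor miRNAs of one pair, split by edge provenance.

    CN1: both incident edges original; CN2: at least one recommended.
    """

    lnc: int
    dis: int
    cn1: tuple[int, ...]
    cn2: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.cn1) & set(self.cn2):
            raise ValueError("CN1 and CN2 must be disjoint")


def neighbor_partition(
    O_l: np.ndarray, O_d: np.ndarray, A_l: np.ndarray, A_d: np.ndarray, l: int, d: int
) -> NeighborPartition:
    """Partition the common neighbors of (l, d) given original (O_*) and full
    (A_*, including recommended edges) adjacency blocks."""
    common = (A_l[:, l] > 0) & (A_d[:, d] > 0)
    both_orig = (O_l[:, l] > 0) & (O_d[:, d] > 0)
    cn1 = np.flatnonzero(common & both_orig)
    cn2 = np.flatnonzero(common & ~both_orig)
    return NeighborPartition(
        lnc=l, dis=d, cn1=tuple(int(i) for i in cn1), cn2=tuple(int(i) for i in cn2)
    )


@dataclass(frozen=True)
class MiRNAEvidence:
    """Per-miRNA bridge counts on the densified network.

    ``n_plus`` known lncRNA-disease edges whose endpoints are both adjacent to
    the miRNA; ``n_minus = n_lnc * n_dis - n_plus``; ``degree = n_lnc + n_dis``.
    """

    n_lnc: int
    n_dis: int
    n_plus: int

    @property
    def n_minus(self) -> int:
        return self.n_lnc * self.n_dis - self.n_plus

    @property
    def degree(self) -> int:
        return self.n_lnc + self.n_dis

    @property
    def ratio(self) -> float:
        """Laplace-smoothed evidence ratio (N+ + 1)/(N- + 1)."""
        return (self.n_plus + 1) / (self.n_minus + 1)


def evidence_counts(
    A_l: np.ndarray, A_d: np.ndarray, Y: np.ndarray
) -> list[MiRNAEvidence]:
    """Evidence for every miRNA. ``Y`` is the binary lncRNA x disease matrix of
    known associations in the training data."""
    A_l = np.asarray(A_l, dtype=float)
    A_d = np.asarray(A_d, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n_l = A_l.sum(axis=1).astype(int)
    n_d = A_d.sum(axis=1).astype(int)
    n_plus = np.einsum("ml,ld,md->m", A_l, Y, A_d).round().astype(int)
    return [
        MiRNAEvidence(n_lnc=int(a), n_dis=int(b), n_plus=int(c))
        for a, b, c in zip(n_l, n_d, n_plus)
    ]


def pair_score(
    partition: NeighborPartition,
    evidence: list[MiRNAEvidence],
    priors: PriorOdds,
    alpha: float,
) -> float:
    """Raw posterior-odds score S of one pair (always > 0)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    phi = priors.odds
    s = phi
    for m in partition.cn1:
        s *= evidence[m].ratio / phi
    for m in partition.cn2:
        s *= evidence[m].ratio ** alpha / phi
    return s


def normalize_score(
    score: float,
    partition: NeighborPartition,
    evidence: list[MiRNAEvidence],
    log_base: float | None = None,
) -> float:
    """Degree-normalized log score S' = log S / prod of neighbor degrees."""
    if score <= 0:
        raise ValueError("raw score must be positive")
    denom = 1.0
    for m in partition.cn1 + partition.cn2:
        k = evidence[m].degree
        if k == 0:
            raise ValueError("common neighbor with zero degree")
        denom *= k
    num = math.log(score) if log_base is None else math.log(score, log_base)
    return num / denom


def score_all_pairs(
    O_l: np.ndarray,
    O_d: np.ndarray,
    A_l: np.ndarray,
    A_d: np.ndarray,
    Y: np.ndarray,
    priors: PriorOdds,
    alpha: float,
    log_base: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (raw S, normalized S') matrices over all lncRNA x disease pairs.

    Equivalent to looping ``pair_score`` / ``normalize_score`` over every pair;
    pairs with no common neighbor score S = phi, S' = log(phi).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    O_l = np.asarray(O_l, dtype=float)
    O_d = np.asarray(O_d, dtype=float)
    A_l = np.asarray(A_l, dtype=float)
    A_d = np.asarray(A_d, dtype=float)

    ev = evidence_counts(A_l, A_d, Y)
    log_ratio = np.array([math.log(e.ratio) for e in ev])
    degree = np.array([e.degree for e in ev], dtype=float)
    log_phi = math.log(priors.odds)

    # per-neighbor log contributions: CN1 -> log r - log phi; CN2 -> a*log r - log phi
    c1 = log_ratio - log_phi
    c2 = alpha * log_ratio - log_phi
    cn1_sum = O_l.T @ (c1[:, None] * O_d)
    full_sum = A_l.T @ (c2[:, None] * A_d)
    orig_sum = O_l.T @ (c2[:, None] * O_d)
    log_S = log_phi + cn1_sum + (full_sum - orig_sum)

    log_deg = np.where(degree > 0, np.log(np.maximum(degree, 1.0)), 0.0)
    deg_prod = np.exp(A_l.T @ (log_deg[:, None] * A_d))
    num = log_S if log_base is None else log_S / math.log(log_base)
    return np.exp(log_S), num / deg_prod
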