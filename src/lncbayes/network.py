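"""Tripartite network construction and item-based collaborative filtering.

The miRNA layer plays the role of "items" and the lncRNA and disease layers
jointly play the role of "users". The spliced binary adjacency ``R0`` has one
row per miRNA and one column per user (all lncRNAs first, then all diseases).
Cosine similarity between miRNA rows yields a similarity matrix ``R'``; the
product ``R1 = R' @ R0`` scores every (miRNA, user) pair; miRNAs scoring above
the mean score of a user's known miRNAs are recommended as new edges, giving
the densified network on which the Bayes scorer operates.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import AssociationTable, EntityIndex

ORIGINAL = "original"
RECOMMENDED = "recommended"


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary miRNA x (lncRNA || disease) adjacency with its label indices."""

    values: np.ndarray
    mirnas: EntityIndex
    lncrnas: EntityIndex
    diseases: EntityIndex

    def __post_init__(self) -> None:
        nm, nu = self.values.shape
        if nm != len(self.mirnas) or nu != len(self.lncrnas) + len(self.diseases):
            raise ValueError("adjacency shape does not match the indices")
        vals = np.unique(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")

    @property
    def n_lnc(self) -> int:
        return len(self.lncrnas)

    @property
    def lnc_block(self) -> np.ndarray:
        return self.values[:, : self.n_lnc]

    @property
    def dis_block(self) -> np.ndarray:
        return self.values[:, self.n_lnc:]


def build_mld_matrix(
    ml: AssociationTable,
    md: AssociationTable,
    mirnas: EntityIndex,
    lncrnas: EntityIndex,
    diseases: EntityIndex,
) -> AdjacencyMatrix:
    """Splice the miRNA-lncRNA and miRNA-disease layers into one binary matrix."""
    nm, nl, nd = len(mirnas), len(lncrnas), len(diseases)
    R0 = np.zeros((nm, nl + nd), dtype=np.int8)
    for m, l in ml.records:
        R0[mirnas.position(m), lncrnas.position(l)] = 1
    for m, d in md.records:
        R0[mirnas.position(m), nl + diseases.position(d)] = 1
    return AdjacencyMatrix(values=R0, mirnas=mirnas, lncrnas=lncrnas, diseases=diseases)


def cooccurrence(R0: np.ndarray) -> np.ndarray:
    """Binary miRNA co-occurrence: 1 iff two miRNAs share >=1 user; zero diagonal."""
    R0 = np.asarray(R0)
    if R0.size == 0:
        raise ValueError("empty adjacency")
    C = (R0 @ R0.T > 0).astype(np.int8)
    np.fill_diagonal(C, 0)
    return C


def similarity(R0: np.ndarray) -> np.ndarray:
    """Cosine similarity between binary miRNA rows.

    ``R'(k, r) = |N(k) ∩ N(r)| / sqrt(|N(k)| |N(r)|)`` with a zero diagonal;
    rows with zero degree get similarity 0 everywhere (0/0 convention).
    """
    R0 = np.asarray(R0, dtype=float)
    if R0.size == 0:
        raise ValueError("empty adjacency")
    inter = R0 @ R0.T
    deg = R0.sum(axis=1)
    denom = np.sqrt(np.outer(deg, deg))
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(denom > 0, inter / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(S, 0.0)
    return S


def recommender_scores(
    Rp: np.ndarray, R0: np.ndarray, k: int | str = "all"
) -> np.ndarray:
    """Relevance score of every (miRNA, user) pair.

    With ``k="all"`` this is the plain product ``R' @ R0`` (the zero diagonal of
    ``R'`` already excludes self-similarity). With a finite ``k`` the score of
    (m_t, user) sums similarity only over the user's known miRNAs that are also
    among the top-k miRNAs most similar to m_t (ties broken by row position).
    """
    Rp = np.asarray(Rp, dtype=float)
    R0 = np.asarray(R0, dtype=float)
    if k == "all" or k is None:
        return Rp @ R0
    k = int(k)
    if k <= 0:
        raise ValueError("k must be a positive integer or 'all'")
    nm = Rp.shape[0]
    mask = np.zeros_like(Rp)
    for t in range(nm):
        order = np.lexsort((np.arange(nm), -Rp[t]))
        top = order[: min(k, nm)]
        mask[t, top] = 1.0
    return (Rp * mask) @ R0


def recommendation_thresholds(R1: np.ndarray, R0: np.ndarray) -> np.ndarray:
    """Per-user mean recommender score over that user's known miRNAs (NaN if none)."""
    R0 = np.asarray(R0)
    known = R0 > 0
    counts = known.sum(axis=0)
    sums = np.where(known, R1, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def recommend_edges(R1: np.ndarray, R0: np.ndarray) -> list[tuple[int, int]]:
    """New (miRNA row, user column) pairs whose score strictly exceeds the
    user's threshold; users with no known miRNA are skipped."""
    R1 = np.asarray(R1, dtype=float)
    R0 = np.asarray(R0)
    pbar = recommendation_thresholds(R1, R0)
    additions: list[tuple[int, int]] = []
    for u in range(R0.shape[1]):
        if not np.isfinite(pbar[u]):
            continue
        for m in range(R0.shape[0]):
            if R0[m, u] == 0 and R1[m, u] > pbar[u]:
                additions.append((m, u))
    return additions


def build_network(
    R0: AdjacencyMatrix, ld: AssociationTable | None = None
) -> nx.Graph:
    """Tripartite graph with role node attributes and edge provenance flags."""
    G = nx.Graph()
    for lab in R0.mirnas.labels:
        G.add_node(("m", R0.mirnas.position(lab)), role="miRNA", label=lab)
    for lab in R0.lncrnas.labels:
        G.add_node(("l", R0.lncrnas.position(lab)), role="lncRNA", label=lab)
    for lab in R0.diseases.labels:
        G.add_node(("d", R0.diseases.position(lab)), role="disease", label=lab)
    nm, _ = R0.values.shape
    nl = R0.n_lnc
    for m in range(nm):
        for u in np.flatnonzero(R0.values[m]):
            tgt = ("l", int(u)) if u < nl else ("d", int(u - nl))
            G.add_edge(("m", m), tgt, provenance=ORIGINAL)
    if ld is not None:
        for l, d in ld.records:
            G.add_edge(
                ("l", R0.lncrnas.position(l)),
                ("d", R0.diseases.position(d)),
                provenance=ORIGINAL,
            )
    return G


def update_network(
    G: nx.Graph, additions: list[tuple[int, int]], n_lnc: int
) -> nx.Graph:
    """Add recommended (miRNA, user) edges; refuses to duplicate any edge."""
    H = G.copy()
    for m, u in additions:
        tgt = ("l", u) if u < n_lnc else ("d", u - n_lnc)
        if H.has_edge(("m", m), tgt):
            raise ValueError(f"edge ({('m', m)}, {tgt}) already present")
        H.add_edge(("m", m), tgt, provenance=RECOMMENDED)
    return H


def network_adjacency(
    G: nx.Graph, nm: int, nl: int, nd: int, include_recommended: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """miRNA x lncRNA and miRNA x disease adjacency blocks of the graph."""
    A_l = np.zeros((nm, nl), dtype=np.int8)
    A_d = np.zeros((nm, nd), dtype=np.int8)
    for (kind_a, i), (kind_b, j), data in G.edges(data=True):
        if not include_recommended and data.get("provenance") == RECOMMENDED:
            continue
        if kind_a != "m":
            (kind_a, i), (kind_b, j) = (kind_b, j), (kind_a, i)
        if kind_a != "m":
            continue
        if kind_b == "l":
            A_l[i, j] = 1
        elif kind_b == "d":
            A_d[i, j] = 1
    return A_l, A_d


def network_edge_list(R0: AdjacencyMatrix, G: nx.Graph) -> list[tuple[str, str, str]]:
    """(node1, node2, provenance) rows with original labels, for TSV export."""
    rows = []
    for a, b, data in G.edges(data=True):
        la = G.nodes[a]["label"]
        lb = G.nodes[b]["label"]
        rows.append((la, lb, data.get("provenance", ORIGINAL)))
    return sorted(rows)
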