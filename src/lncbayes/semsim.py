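"""DAG-based disease semantic similarity (Wang-style measure).

A disease is described by the sub-DAG of its ontology ancestors (e.g. MeSH
descriptors). The disease itself contributes 1; every ancestor t contributes
``D(t) = max(delta * D(ct))`` over its children ct inside the sub-DAG, with
semantic contribution factor delta (default 0.5). The semantic value DV is the
sum of contributions, and the similarity of two diseases is the contribution
mass they share relative to their total:

    SD(i, j) = sum_{t in T_i ∩ T_j} (D_i(t) + D_j(t)) / (DV_i + DV_j)

which is symmetric, 1 on the diagonal and bounded in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io import EntityIndex, _key


@dataclass(frozen=True)
class DiseaseDAG:
    """Ontology parent links as a validated acyclic child -> parent digraph."""

    graph: nx.DiGraph  # edge (child, parent)

    def __contains__(self, label: str) -> bool:
        return _key(label) in self.graph

    def ancestors_closure(self, label: str) -> set[str]:
        """The disease itself plus all ancestors (casefolded keys)."""
        k = _key(label)
        if k not in self.graph:
            raise KeyError(f"disease {label!r} not in the DAG")
        return {k} | nx.descendants(self.graph, k)  # parents lie downstream


def parse_dag(edges: Iterable[Sequence[str]]) -> DiseaseDAG:
    """Build a DiseaseDAG from (child, parent) records; rejects cycles."""
    G = nx.DiGraph()
    for rec in edges:
        child, parent = _key(str(rec[0])), _key(str(rec[1]))
        if not child or not parent:
            raise ValueError(f"empty label in DAG edge {tuple(rec)!r}")
        if child == parent:
            raise ValueError(f"self-parenting node {rec[0]!r}")
        G.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(G):
        cycle = nx.find_cycle(G)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    return DiseaseDAG(graph=G)


def read_dag(path: str | Path) -> DiseaseDAG:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = [p.strip() for p in line.replace(",", "\t").split("\t")]
        if len(parts) < 2:
            raise ValueError(f"DAG line needs 2 columns: {line!r}")
        rows.append(parts[:2])
    return parse_dag(rows)


@dataclass(frozen=True)
class SemanticProfile:
    """Ancestor contribution map and semantic value of one disease."""

    disease: str
    contributions: dict[str, float]
    delta: float

    @property
    def dv(self) -> float:
        return sum(self.contributions.values())


def semantic_contribution(
    dag: DiseaseDAG, disease: str, delta: float = 0.5
) -> SemanticProfile:
    """Contribution of every ancestor of ``disease``; the disease itself gets 1."""
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    root = _key(disease)
    closure = dag.ancestors_closure(disease)
    contrib: dict[str, float] = {root: 1.0}
    # process ancestors in topological order away from the disease
    sub = dag.graph.subgraph(closure)
    for node in nx.topological_sort(sub):
        if node == root:
            continue
        children = [c for c in sub.predecessors(node)]
        contrib[node] = max(delta * contrib[c] for c in children)
    return SemanticProfile(disease=disease, contributions=contrib, delta=delta)


def semantic_similarity(a: SemanticProfile, b: SemanticProfile) -> float:
    """Shared-contribution similarity of two profiles from the same DAG/delta."""
    if a.delta != b.delta:
        raise ValueError("profiles computed with different delta")
    shared = set(a.contributions) & set(b.contributions)
    num = sum(a.contributions[t] + b.contributions[t] for t in shared)
    return num / (a.dv + b.dv)


def similarity_matrix(
    dag: DiseaseDAG | None, diseases: EntityIndex, delta: float = 0.5
) -> np.ndarray:
    """Pairwise disease similarity; diseases absent from the DAG (or with no
    DAG at all) fall back to an identity row/column so the semantic stage
    degrades to a no-op for them."""
    nd = len(diseases)
    SD = np.eye(nd)
    if dag is None:
        return SD
    profiles: dict[int, SemanticProfile] = {}
    for i, lab in enumerate(diseases.labels):
        if lab in dag:
            profiles[i] = semantic_contribution(dag, lab, delta)
    for i, pi in profiles.items():
        for j, pj in profiles.items():
            if j > i:
                SD[i, j] = SD[j, i] = semantic_similarity(pi, pj)
    return SD


def combine_scores(Sprime: np.ndarray, SD: np.ndarray) -> np.ndarray:
    """Mix normalized Bayes scores across semantically similar diseases:
    matrix product over the shared disease dimension."""
    Sprime = np.asarray(Sprime, dtype=float)
    SD = np.asarray(SD, dtype=float)
    if Sprime.shape[1] != SD.shape[0] or SD.shape[0] != SD.shape[1]:
        raise ValueError(
            f"disease dimensions do not match: {Sprime.shape} vs {SD.shape}"
        )
    return Sprime @ SD
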