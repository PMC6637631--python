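"""Synthetic inputs: the worked-example toy network, random tripartite networks
with a planted miRNA-mediated association signal, and random disease ontologies.

The generator emulates the modular organisation of curated ncRNA association
data: miRNAs, lncRNAs and diseases each belong to one of a few latent
functional groups, and a miRNA is far more likely to be associated with
lncRNAs/diseases of its own group. lncRNA-disease associations are then
planted preferentially on pairs bridged by at least ``min_shared`` miRNA
mediators — the mechanism the scorer is built to detect, and the reason
item-based collaborative filtering has structure to learn: miRNA co-occurrence
reflects group membership, so recommended edges mostly stay within a group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .io import AssociationTable, _key
from .semsim import DiseaseDAG

#: miRNA-lncRNA edges of the 5-miRNA / 2-lncRNA / 2-disease worked example.
TOY_ML_EDGES = (("m1", "l1"), ("m1", "l2"), ("m2", "l1"), ("m3", "l2"))
#: miRNA-disease edges of the worked example.
TOY_MD_EDGES = (
    ("m1", "d1"), ("m2", "d1"), ("m3", "d2"),
    ("m4", "d2"), ("m5", "d1"), ("m5", "d2"),
)


def toy_tables() -> tuple[AssociationTable, AssociationTable]:
    """The small worked-example network (ml, md) used throughout the docs/tests."""
    ml = AssociationTable.from_records("miRNA-lncRNA", TOY_ML_EDGES)
    md = AssociationTable.from_records("miRNA-disease", TOY_MD_EDGES)
    return ml, md


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings for the planted-signal tripartite network.

    ``ml_density``/``md_density`` are the *mean* edge probabilities of each
    layer; ``concentration`` is the within-group/between-group odds of an edge
    (1 = unstructured). A lncRNA-disease pair sharing at least ``min_shared``
    miRNA neighbors is a true association with probability ``boosted_rate``,
    otherwise ``base_rate``. Defaults give a sparse, strongly modular network
    of a few dozen entities per layer in which roughly half the associations
    are mediator-driven.
    """

    n_lncrna: int = 30
    n_mirna: int = 40
    n_disease: int = 25
    ml_density: float = 0.10
    md_density: float = 0.10
    n_groups: int = 5
    concentration: float = 30.0
    base_rate: float = 0.02
    boosted_rate: float = 0.5
    min_shared: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_lncrna, self.n_mirna, self.n_disease):
            if n < 1:
                raise ValueError("entity counts must be >= 1")
        for p in (self.ml_density, self.md_density, self.base_rate, self.boosted_rate):
            if not 0 < p < 1:
                raise ValueError("densities and rates must lie in (0, 1)")
        if self.n_groups < 1 or self.concentration < 1:
            raise ValueError("need n_groups >= 1 and concentration >= 1")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


def _labels(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _block_probabilities(
    density: float, n_groups: int, concentration: float
) -> tuple[float, float]:
    """Within/between-group edge probabilities with the stated mean density.

    The within-group probability is capped at 0.9; the between-group
    probability is then raised so the mean density is preserved exactly.
    """
    w = 1.0 / n_groups
    p_out = density / (w * concentration + (1 - w))
    p_in = concentration * p_out
    if p_in > 0.9:
        p_in = 0.9
        p_out = max((density - w * p_in) / (1 - w), 0.0)
    return p_in, p_out


def generate_tripartite(
    config: SynthConfig = SynthConfig(),
) -> tuple[AssociationTable, AssociationTable, AssociationTable]:
    """Sample (ml, md, ld) tables; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    lncs = _labels("L", config.n_lncrna)
    mirs = _labels("M", config.n_mirna)
    diss = _labels("D", config.n_disease)

    g_l = rng.integers(0, config.n_groups, config.n_lncrna)
    g_m = rng.integers(0, config.n_groups, config.n_mirna)
    g_d = rng.integers(0, config.n_groups, config.n_disease)

    p_in_ml, p_out_ml = _block_probabilities(
        config.ml_density, config.n_groups, config.concentration
    )
    p_in_md, p_out_md = _block_probabilities(
        config.md_density, config.n_groups, config.concentration
    )
    P_ml = np.where(g_m[:, None] == g_l[None, :], p_in_ml, p_out_ml)
    P_md = np.where(g_m[:, None] == g_d[None, :], p_in_md, p_out_md)
    ml_adj = rng.random(P_ml.shape) < P_ml
    md_adj = rng.random(P_md.shape) < P_md
    if not ml_adj.any() or not md_adj.any():
        raise ValueError("configuration produced an empty association layer")

    shared = ml_adj.astype(int).T @ md_adj.astype(int)  # lncRNA x disease
    p = np.where(shared >= config.min_shared, config.boosted_rate, config.base_rate)
    ld_adj = rng.random(p.shape) < p
    if not ld_adj.any():
        raise ValueError("configuration produced no lncRNA-disease associations")

    ml = AssociationTable.from_records(
        "miRNA-lncRNA",
        [(mirs[m], lncs[l]) for m, l in zip(*np.nonzero(ml_adj))],
    )
    md = AssociationTable.from_records(
        "miRNA-disease",
        [(mirs[m], diss[d]) for m, d in zip(*np.nonzero(md_adj))],
    )
    ld = AssociationTable.from_records(
        "lncRNA-disease",
        [(lncs[l], diss[d]) for l, d in zip(*np.nonzero(ld_adj))],
    )
    return ml, md, ld


def generate_dag(
    labels: list[str] | int,
    branching: float = 0.2,
    seed: int = 0,
) -> DiseaseDAG:
    """Random rooted ontology over ``labels`` (or ``n`` auto-named nodes).

    Node i > 0 gets one parent drawn uniformly from earlier nodes, plus a second
    distinct parent with probability ``branching``; acyclic by construction.
    """
    if isinstance(labels, int):
        labels = _labels("D", labels)
    rng = np.random.default_rng(seed)
    G = nx.DiGraph()
    G.add_nodes_from(_key(lab) for lab in labels)
    for i in range(1, len(labels)):
        parent = int(rng.integers(0, i))
        G.add_edge(_key(labels[i]), _key(labels[parent]))
        if i > 1 and rng.random() < branching:
            second = int(rng.integers(0, i))
            if second != parent:
                G.add_edge(_key(labels[i]), _key(labels[second]))
    assert nx.is_directed_acyclic_graph(G)
    return DiseaseDAG(graph=G)
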