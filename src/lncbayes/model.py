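"""The end-to-end estimator: collaborative filtering + naive Bayes + semantics.

``CollaborativeNaiveBayes`` follows scikit-learn conventions: hyperparameters in
``__init__``, data in ``fit``, fitted state in trailing-underscore attributes,
``get_params``/``set_params``/``clone`` compatibility. ``fit`` consumes the
known lncRNA-disease associations (the supervision) plus the miRNA-lncRNA and
miRNA-disease side networks, and materialises the full scoring pipeline:

1. harmonize the three tables to a consistent entity universe;
2. splice the binary adjacency, compute miRNA cosine similarity and the
   recommender matrix, add mean-threshold recommended edges (densified network);
3. score every lncRNA-disease pair with the common-neighbor naive Bayes odds,
   normalize by log/degree product;
4. optionally mix scores across semantically similar diseases via an ontology.

``decision_function`` then returns scores for arbitrary labeled pairs and
``rank_diseases``/``rank_lncrnas`` produce per-entity candidate rankings.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import bayes, network, semsim
from .io import AssociationTable, build_indices, harmonize
from .semsim import DiseaseDAG


class CollaborativeNaiveBayes(BaseEstimator):
    """Rank lncRNA-disease pairs on a collaboratively densified tripartite network.

    Parameters
    ----------
    alpha : float in (0, 1]
        Decay exponent damping evidence from recommended (CN2) common
        neighbors; smaller values trust recommended links less. Default 0.05.
    top_k : int or "all"
        Neighborhood size of the item-based recommender; "all" uses the plain
        similarity product.
    delta : float in (0, 1)
        Semantic contribution factor of the ontology similarity stage.
    log_base : float or None
        Base of the logarithm in the degree normalization (None = natural).
    use_semantic : bool
        Whether to mix scores across similar diseases when a DAG is supplied.
    harmonize : bool
        Whether to restrict the input tables to a mutually consistent entity
        universe before building the network (the curated-database protocol).
        Disable for inputs that are already a single coherent network, e.g.
        the packaged toy example whose m4/m5 have no lncRNA edges.

    Attributes (after ``fit``)
    --------------------------
    mirnas_, lncrnas_, diseases_ : EntityIndex
    r0_ : AdjacencyMatrix          spliced binary miRNA x (lncRNA || disease)
    similarity_ : ndarray          miRNA x miRNA cosine similarity (zero diag)
    recommender_ : ndarray         miRNA x user relevance scores
    recommendations_ : list        added (miRNA row, user column) edges
    network_ : nx.Graph            densified tripartite network
    priors_ : PriorOdds or None
    evidence_ : list[MiRNAEvidence] or None
    score_raw_, score_norm_, score_ : ndarray (lncRNA x disease) or None
    """

    def __init__(
        self,
        alpha: float = 0.05,
        top_k: int | str = "all",
        delta: float = 0.5,
        log_base: float | None = None,
        use_semantic: bool = True,
        harmonize: bool = True,
    ) -> None:
        self.alpha = alpha
        self.top_k = top_k
        self.delta = delta
        self.log_base = log_base
        self.use_semantic = use_semantic
        self.harmonize = harmonize

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        X: AssociationTable | Iterable[Sequence[str]] | None,
        y: None = None,
        *,
        ml: AssociationTable,
        md: AssociationTable,
        dag: DiseaseDAG | None = None,
        aliases: Mapping[str, str] | None = None,
    ) -> "CollaborativeNaiveBayes":
        """Fit on known lncRNA-disease associations ``X`` with side networks.

        ``X`` may be None or empty, in which case only the collaborative
        filtering stages run (no Bayes scores are available).
        """
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        ld = _as_ld_table(X)
        if self.harmonize:
            md_h, ml_h, ld_h = harmonize(md, ml, ld, aliases=aliases)
        else:
            from .io import apply_aliases

            md_h, ml_h, ld_h = md, ml, ld
            if aliases:
                md_h = apply_aliases(md, aliases)
                ml_h = apply_aliases(ml, aliases)
                ld_h = apply_aliases(ld, aliases) if ld is not None else None
        self.ld_ = ld_h
        self.mirnas_, self.lncrnas_, self.diseases_ = build_indices(md_h, ml_h)

        self.r0_ = network.build_mld_matrix(
            ml_h, md_h, self.mirnas_, self.lncrnas_, self.diseases_
        )
        R0 = self.r0_.values
        self.cooccurrence_ = network.cooccurrence(R0)
        self.similarity_ = network.similarity(R0)
        self.recommender_ = network.recommender_scores(self.similarity_, R0, self.top_k)
        self.recommendations_ = network.recommend_edges(self.recommender_, R0)
        base_net = network.build_network(self.r0_, ld_h)
        self.network_ = network.update_network(
            base_net, self.recommendations_, self.r0_.n_lnc
        )

        nm, nl, nd = len(self.mirnas_), len(self.lncrnas_), len(self.diseases_)
        self.O_l_, self.O_d_ = network.network_adjacency(
            self.network_, nm, nl, nd, include_recommended=False
        )
        self.A_l_, self.A_d_ = network.network_adjacency(
            self.network_, nm, nl, nd, include_recommended=True
        )

        self.priors_ = None
        self.evidence_ = None
        self.score_raw_ = self.score_norm_ = self.score_ = None
        if ld_h is not None and len(ld_h) > 0:
            self._fit_scores(ld_h, dag)
        return self

    def _fit_scores(self, ld: AssociationTable, dag: DiseaseDAG | None) -> None:
        nl_ld = len(ld.sources)
        nd_ld = len(ld.targets)
        self.priors_ = bayes.compute_priors(len(ld), nl_ld, nd_ld)
        Y = self.known_matrix_ = self._ld_matrix(ld)
        self.evidence_ = bayes.evidence_counts(self.A_l_, self.A_d_, Y)
        self.score_raw_, self.score_norm_ = bayes.score_all_pairs(
            self.O_l_, self.O_d_, self.A_l_, self.A_d_, Y,
            self.priors_, self.alpha, self.log_base,
        )
        if self.use_semantic and dag is not None:
            self.disease_similarity_ = semsim.similarity_matrix(
                dag, self.diseases_, self.delta
            )
            self.score_ = semsim.combine_scores(self.score_norm_, self.disease_similarity_)
        else:
            self.disease_similarity_ = np.eye(len(self.diseases_))
            self.score_ = self.score_norm_.copy()

    def _ld_matrix(self, ld: AssociationTable) -> np.ndarray:
        Y = np.zeros((len(self.lncrnas_), len(self.diseases_)), dtype=np.int8)
        for l, d in ld.records:
            Y[self.lncrnas_.position(l), self.diseases_.position(d)] = 1
        return Y

    # -------------------------------------------------------------- predict
    def _check_scored(self) -> None:
        if getattr(self, "score_", None) is None:
            raise RuntimeError(
                "model has no scores: fit with a non-empty lncRNA-disease table"
            )

    def decision_function(self, pairs: Iterable[Sequence[str]]) -> np.ndarray:
        """Scores for (lncRNA label, disease label) pairs."""
        self._check_scored()
        out = [
            self.score_[self.lncrnas_.position(l), self.diseases_.position(d)]
            for l, d in pairs
        ]
        return np.asarray(out, dtype=float)

    def rank_lncrnas(self, disease: str, exclude_known: bool = True) -> list[tuple[str, float]]:
        """Candidate lncRNAs for one disease, best first; deterministic ties."""
        self._check_scored()
        d = self.diseases_.position(disease)
        known = {l for l, dd in self.ld_.records if self.diseases_.position(dd) == d} \
            if (exclude_known and self.ld_ is not None) else set()
        known_keys = {k.strip().casefold() for k in known}
        out = [
            (lab, float(self.score_[i, d]))
            for i, lab in enumerate(self.lncrnas_.labels)
            if lab.strip().casefold() not in known_keys
        ]
        return sorted(out, key=lambda t: (-t[1], t[0]))

    def ranked_pairs(self, exclude_known: bool = True) -> list[tuple[str, str, float]]:
        """All (lncRNA, disease, score) triples, best first."""
        self._check_scored()
        known = set()
        if exclude_known and self.ld_ is not None:
            known = {
                (self.lncrnas_.position(l), self.diseases_.position(d))
                for l, d in self.ld_.records
            }
        out = [
            (ll, dl, float(self.score_[i, j]))
            for i, ll in enumerate(self.lncrnas_.labels)
            for j, dl in enumerate(self.diseases_.labels)
            if (i, j) not in known
        ]
        return sorted(out, key=lambda t: (-t[2], t[0], t[1]))


def _as_ld_table(X) -> AssociationTable | None:
    if X is None:
        return None
    if isinstance(X, AssociationTable):
        if X.kind != "lncRNA-disease":
            raise ValueError("X must be a lncRNA-disease table")
        return X
    records = list(X)
    if not records:
        return None
    return AssociationTable.from_records("lncRNA-disease", records)
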