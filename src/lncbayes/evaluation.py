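"""Leave-one-out cross-validation, ROC/AUC, top-k F1 and paired comparisons.

LOOCV holds out each known lncRNA-disease association in turn, retrains the
entire pipeline on the remaining associations (the collaborative filtering
stage never sees the association table, so no stage ever observes the held-out
edge), ranks the held-out lncRNA among the candidates for its disease, and
pools candidate scores across folds into a single ROC with held-out pairs as
positives and never-known pairs as negatives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_curve

from .io import AssociationTable, _key
from .model import CollaborativeNaiveBayes
from .semsim import DiseaseDAG

logger = logging.getLogger(__name__)

#: scorer(lncRNA label, disease label) -> float, built per training fold
ScorerFactory = Callable[[AssociationTable], Callable[[str, str], float]]


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC by threshold sweep and AUC by trapezoidal integration.

    With the sweep over unique scores, the trapezoid under the curve equals the
    rank-statistic (Mann-Whitney concordance) AUC, ties contributing 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to build a ROC")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


@dataclass(frozen=True)
class FoldRecord:
    lncrna: str
    disease: str
    rank: int
    n_candidates: int
    scores: dict[str, float] = field(repr=False)


@dataclass(frozen=True)
class LoocvResult:
    folds: list[FoldRecord]
    roc: ROCResult
    per_disease_auc: dict[str, float] | None = None


def _default_scorer_factory(
    ml: AssociationTable,
    md: AssociationTable,
    dag: DiseaseDAG | None,
    estimator: CollaborativeNaiveBayes,
) -> ScorerFactory:
    def factory(ld_train: AssociationTable):
        model = clone(estimator)
        model.fit(ld_train, ml=ml, md=md, dag=dag)
        return lambda l, d: float(
            model.score_[model.lncrnas_.position(l), model.diseases_.position(d)]
        )

    return factory


def degree_baseline_factory(
    ml: AssociationTable, md: AssociationTable
) -> ScorerFactory:
    """Baseline ranking pairs by miRNA-degree product only — no common-neighbor
    information; used as the floor the pipeline must beat."""
    deg_l: dict[str, int] = {}
    for _, l in ml.records:
        deg_l[_key(l)] = deg_l.get(_key(l), 0) + 1
    deg_d: dict[str, int] = {}
    for _, d in md.records:
        deg_d[_key(d)] = deg_d.get(_key(d), 0) + 1

    def factory(ld_train: AssociationTable):
        return lambda l, d: float(deg_l.get(_key(l), 0) * deg_d.get(_key(d), 0))

    return factory


def loocv(
    ml: AssociationTable,
    md: AssociationTable,
    ld: AssociationTable,
    *,
    estimator: CollaborativeNaiveBayes | None = None,
    dag: DiseaseDAG | None = None,
    scorer_factory: ScorerFactory | None = None,
    per_disease: bool = False,
) -> LoocvResult:
    """Leave-one-out over known associations with full per-fold retraining."""
    from .io import harmonize

    md, ml, ld = harmonize(md, ml, ld)
    if ld is None or len(ld) < 2:
        raise ValueError("need at least two known associations for LOOCV")
    if scorer_factory is None:
        scorer_factory = _default_scorer_factory(
            ml, md, dag, estimator or CollaborativeNaiveBayes()
        )
    known = {( _key(l), _key(d)) for l, d in ld.records}
    all_lncs = list(ml.targets)

    pooled_scores: list[float] = []
    pooled_labels: list[int] = []
    by_disease: dict[str, tuple[list[float], list[int]]] = {}
    folds: list[FoldRecord] = []
    for heldout in ld.records:
        l_star, d_star = heldout
        train = AssociationTable(
            kind="lncRNA-disease",
            records=tuple(r for r in ld.records if r != heldout),
        )
        try:
            score = scorer_factory(train)
        except ValueError as exc:
            warnings.warn(f"skipping fold {heldout}: {exc}")
            continue
        trained_for_d = {
            _key(l) for l, d in train.records if _key(d) == _key(d_star)
        }
        candidates = [l for l in all_lncs if _key(l) not in trained_for_d]
        cand_scores = {l: score(l, d_star) for l in candidates}
        s_star = cand_scores[_compat_label(cand_scores, l_star)]
        rank = 1 + sum(1 for v in cand_scores.values() if v > s_star)
        folds.append(
            FoldRecord(
                lncrna=l_star,
                disease=d_star,
                rank=rank,
                n_candidates=len(candidates),
                scores=cand_scores,
            )
        )
        for l, v in cand_scores.items():
            if _key(l) == _key(l_star):
                lab = 1
            elif (_key(l), _key(d_star)) in known:
                continue  # positive in another fold; excluded from negatives
            else:
                lab = 0
            pooled_scores.append(v)
            pooled_labels.append(lab)
            by_disease.setdefault(d_star, ([], []))[0].append(v)
            by_disease[d_star][1].append(lab)

    roc = roc_auc(pooled_scores, pooled_labels)
    per_d = None
    if per_disease:
        per_d = {}
        for d, (s, y) in by_disease.items():
            if len(set(y)) == 2:
                per_d[d] = roc_auc(s, y).auc
    logger.info("LOOCV: %d folds, pooled AUC %.4f", len(folds), roc.auc)
    return LoocvResult(folds=folds, roc=roc, per_disease_auc=per_d)


def _compat_label(scores: dict[str, float], label: str) -> str:
    for k in scores:
        if _key(k) == _key(label):
            return k
    raise KeyError(label)


@dataclass(frozen=True)
class F1Result:
    k: int
    precision: float
    recall: float
    f1: float


def f1_at_k(
    ranked: Sequence[tuple[str, str]],
    positives: Sequence[tuple[str, str]],
    k: int,
) -> F1Result:
    """Precision/recall/F1 of the top-k ranked pairs against held-out positives."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pos = {(_key(l), _key(d)) for l, d in positives}
    if not pos:
        raise ValueError("no positives in the test split")
    hits = sum(1 for l, d in ranked[:k] if (_key(l), _key(d)) in pos)
    precision = hits / k
    recall = hits / len(pos)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return F1Result(k=k, precision=precision, recall=recall, f1=f1)


def split_evaluation(
    ml: AssociationTable,
    md: AssociationTable,
    ld: AssociationTable,
    *,
    k_values: Sequence[int] = (5, 10, 15, 20),
    train_fraction: float = 0.8,
    seed: int = 0,
    estimator: CollaborativeNaiveBayes | None = None,
    dag: DiseaseDAG | None = None,
) -> list[F1Result]:
    """Seeded 80/20 split of known associations; F1@k on the pooled ranking of
    all non-training pairs."""
    rng = np.random.default_rng(seed)
    records = list(ld.records)
    n_train = max(1, int(round(train_fraction * len(records))))
    if n_train >= len(records):
        n_train = len(records) - 1
    order = rng.permutation(len(records))
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]

    model = clone(estimator) if estimator is not None else CollaborativeNaiveBayes()
    model.fit(
        AssociationTable.from_records("lncRNA-disease", train),
        ml=ml, md=md, dag=dag,
    )
    ranked = [(l, d) for l, d, _ in model.ranked_pairs(exclude_known=True)]
    # keep only test positives that are inside the scored universe
    universe_l = {_key(l) for l in model.lncrnas_.labels}
    universe_d = {_key(d) for d in model.diseases_.labels}
    test_in = [
        (l, d) for l, d in test if _key(l) in universe_l and _key(d) in universe_d
    ]
    return [f1_at_k(ranked, test_in, k) for k in k_values]


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Classical two-sided paired t-test on matched score series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length series of length >= 2")
    d = x - y
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError("zero variance of differences")
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)
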