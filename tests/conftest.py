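"""Shared fixtures: the worked-example toy network and its printed matrices."""

import numpy as np
import pytest

from lncbayes import CollaborativeNaiveBayes, toy_tables

# The toy network's published intermediate matrices (rounded as printed).
TOY_COOCCURRENCE = np.array(
    [
        [0, 1, 1, 0, 1],
        [1, 0, 0, 0, 1],
        [1, 0, 0, 1, 1],
        [0, 0, 1, 0, 1],
        [1, 1, 1, 1, 0],
    ]
)

TOY_SIMILARITY_PRINTED = np.array(
    [
        [0, 0.81, 0.405, 0, 0.405],
        [0.81, 0, 0, 0, 0.5],
        [0.405, 0, 0, 0.7, 0.5],
        [0, 0, 0.7, 0, 0.7],
        [0.405, 0.5, 0.5, 0.7, 0],
    ]
)

TOY_RECOMMENDER_PRINTED = np.array(
    [
        [0.81, 0.405, 1.215, 0.81],
        [0.81, 0.81, 1.31, 0.5],
        [0.405, 0.405, 0.905, 1.2],
        [0, 0.7, 0.7, 1.4],
        [0.905, 0.905, 0.905, 1.2],
    ]
)

# (miRNA, user) edges the mean-threshold rule must add to the toy network
TOY_RECOMMENDED_EDGES = {("m5", "l1"), ("m2", "l2"), ("m4", "l2"), ("m5", "l2")}


@pytest.fixture(scope="session")
def toy():
    """(ml, md) tables of the 5-miRNA worked example."""
    return toy_tables()


@pytest.fixture(scope="session")
def toy_model(toy):
    """Collaborative-filtering stages fitted on the toy network (no ld)."""
    ml, md = toy
    model = CollaborativeNaiveBayes(harmonize=False)
    model.fit(None, ml=ml, md=md)
    return model


@pytest.fixture(scope="session")
def toy_scored(toy):
    """Full pipeline on the toy network with two known ld associations."""
    ml, md = toy
    model = CollaborativeNaiveBayes(harmonize=False, alpha=0.5)
    model.fit([("l1", "d1"), ("l2", "d2")], ml=ml, md=md)
    return model
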