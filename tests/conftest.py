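import numpy as np
import pandas as pd
import pytest

import therascore as ts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expr():
    """4 cells × 5 genes with hand-checkable values (g2 is zero in cellB)."""
    values = np.array(
        [
            [2.0, 0.0, 4.0, 1.0, 0.5],
            [1.0, 0.0, 0.0, 2.0, 1.5],
            [3.0, 2.0, 1.0, 0.0, 0.2],
            [0.5, 1.0, 2.0, 3.0, 0.8],
        ]
    )
    return ts.ExpressionMatrix(
        values, ["cellA", "cellB", "cellC", "cellD"], ["g1", "g2", "g3", "g4", "g5"]
    )


@pytest.fixture
def random_expr(rng):
    """200 cells × 60 genes of log-normal-ish values with some exact zeros."""
    vals = np.exp(rng.normal(0.3, 0.8, size=(200, 60)))
    vals[rng.random(size=vals.shape) < 0.2] = 0.0
    return ts.ExpressionMatrix(
        vals,
        [f"c{i}" for i in range(200)],
        [f"g{j}" for j in range(60)],
    )


@pytest.fixture
def random_collection(rng):
    """3 signatures over the random_expr gene space (one unidirectional)."""
    genes = [f"g{j}" for j in range(60)]
    return ts.SignatureCollection(
        [
            ts.GeneSignature("sigA", frozenset(genes[0:8]), frozenset(genes[8:16])),
            ts.GeneSignature("sigB", frozenset(genes[20:30]), frozenset(genes[30:38])),
            ts.GeneSignature("sigC", frozenset(genes[40:50]), frozenset()),
        ],
        name="random3",
    )


@pytest.fixture(scope="session")
def sim_default():
    """The default planted study condition (500 cells, 6-drug panel)."""
    return ts.simulate(ts.SimConfig(seed=7))


@pytest.fixture(scope="session")
def scored_default(sim_default):
    """bc_score + nUMI regression of the default simulation."""
    expr, collection, truth, covars = sim_default
    scores = ts.bc_score(expr, collection)
    return ts.regress_out(scores, covars, ["nUMI"]), truth, covars
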