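"""Shared fixtures: visual systems, small worked trees, random catch factories."""

import numpy as np
import pandas as pd
import pytest

from aposignal.phylo import read_newick
from aposignal.vision import ConeCatch, VisualSystem


@pytest.fixture(scope="session")
def symmetric_vs():
    """Equal cone abundances, ω = 0.05: every noise channel identical."""
    return VisualSystem(abundance=(1, 1, 1, 1), weber=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def random_catch(rng):
    """Factory for random strictly-positive cone catches (log-uniform spread)."""

    def make(n=1):
        out = [
            ConeCatch(*np.exp(rng.uniform(np.log(0.02), np.log(2.0), size=5)))
            for _ in range(n)
        ]
        return out[0] if n == 1 else out

    return make


@pytest.fixture(scope="session")
def balanced4_tree():
    """Balanced 4-tip tree with unit internal and terminal branches."""
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def worked_gls_fixture():
    """4-tip tree with response/predictor vectors for the explicit GLS oracle."""
    tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    y = pd.Series([1.0, 2.0, 4.0, 5.0], index=list("ABCD"))
    x = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("ABCD"), name="x")
    return tree, y, x
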