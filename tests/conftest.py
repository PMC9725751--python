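import numpy as np
import pytest

from lineagestat import LineageEnsemble, LineageRecord
from lineagestat.fixtures import (
    build_skewed_regrowth,
    build_t1,
    build_two_root,
    build_uniform,
    random_tree_ensemble,
)


@pytest.fixture
def t1():
    """The 3-lineage worked micro-tree: D = (1, 2, 2), N0 = 1."""
    return build_t1()[0]


@pytest.fixture
def t1_manifest():
    return build_t1()[1]


@pytest.fixture
def uniform_tree():
    """No heterogeneity: 2 founders, every lineage divides 3 times."""
    return build_uniform(d=3, n0=2)[0]


@pytest.fixture
def two_root():
    return build_two_root()[0]


@pytest.fixture
def chrono_pair_01():
    """Two isolated lineages with D = 0 and 1 (chronological statistics)."""
    recs = [LineageRecord("m0", 0), LineageRecord("m1", 1)]
    return LineageEnsemble("chronological", recs, 2.0, 0.0, 1.0)


@pytest.fixture
def skewed():
    """Right-skewed chronological division counts (regrowth-like)."""
    return build_skewed_regrowth(p0=0.9, dmax=6, n=200)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def random_ensembles(rng):
    """A batch of fuzzed complete-tree ensembles for property checks."""
    return [random_tree_ensemble(rng, max_lineages=80) for _ in range(25)]
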