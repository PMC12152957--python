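"""Shared fixtures: the enumerated scaffold space is expensive enough to
build once per session and reuse across modules."""

import pytest

from bnpah.features import feature_table
from bnpah.molgraph import automorphism_group, build_molecular_graph
from bnpah.scaffolds import DualistTree, enumerate_scaffolds


@pytest.fixture(scope="session")
def scaffolds6():
    """All cata-condensed scaffolds with 2..6 rings."""
    return enumerate_scaffolds(6)


@pytest.fixture(scope="session")
def graphs6(scaffolds6):
    """(tree, graph, automorphism group) triples for the full space."""
    out = []
    for tree in scaffolds6:
        g = build_molecular_graph(tree)
        out.append((tree, g, automorphism_group(g)))
    return out


@pytest.fixture(scope="session")
def features6():
    """Feature table over all 23,894 isomers."""
    return feature_table(6)


@pytest.fixture(scope="session")
def naphthalene():
    tree = enumerate_scaffolds(2)[0]
    return tree, build_molecular_graph(tree)


@pytest.fixture(scope="session")
def benzene_graph():
    """Single-ring test input; outside the enumerated space."""
    tree = DualistTree(cells=((0, 0),), edges=())
    return build_molecular_graph(tree)
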