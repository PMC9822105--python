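import numpy as np
import pytest

from gotriplet import (
    AnnotationSet,
    GoTerm,
    OntologyDAG,
    SyntheticConfig,
    generate_dataset,
)


def make_dag(edges: dict[str, set[str]], aspect: str = "BP", root: str = "GO:0008150"):
    """Build an OntologyDAG from a child -> parents mapping."""
    terms = {
        acc: GoTerm(id=acc, namespace=aspect, parents=frozenset(parents))
        for acc, parents in edges.items()
    }
    return OntologyDAG(terms=terms, roots={aspect: root})


@pytest.fixture
def chain_dag():
    """root <- p <- q linear chain."""
    return make_dag(
        {
            "GO:0008150": set(),
            "GO:9000001": {"GO:0008150"},  # p
            "GO:9000002": {"GO:9000001"},  # q
        }
    )


@pytest.fixture
def diamond_dag():
    """root <- a, b; a,b <- c (diamond) plus a spur d under a."""
    return make_dag(
        {
            "GO:0008150": set(),
            "GO:9000001": {"GO:0008150"},
            "GO:9000002": {"GO:0008150"},
            "GO:9000003": {"GO:9000001", "GO:9000002"},
            "GO:9000004": {"GO:9000001"},
        }
    )


def annotation_set(mapping, aspect="BP", propagated=True):
    return AnnotationSet(
        annotations={p: frozenset(t) for p, t in mapping.items()},
        aspect=aspect,
        propagated=propagated,
    )


@pytest.fixture(scope="session")
def high_signal_dataset():
    """Well-separated clusters: the geometry encodes function cleanly."""
    cfg = SyntheticConfig(
        n_terms=40, n_proteins=80, n_clusters=4, dim=16, signal=6.0, seed=7
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
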