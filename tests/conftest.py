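"""Shared fixtures: small hand-built ontologies and a cached default run."""

from __future__ import annotations

import io

import numpy as np
import pytest

from termscape import ontology, pipeline, synthetic

CHAIN_OBO = """format-version: 1.2
ontology: test

[Term]
id: GO:0000001
name: root
namespace: cellular_component

[Term]
id: GO:0000002
name: a
namespace: cellular_component
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: b
namespace: cellular_component
is_a: GO:0000002 ! a

[Term]
id: GO:0000004
name: c
namespace: cellular_component
is_a: GO:0000003 ! b

[Term]
id: GO:0000005
name: d
namespace: cellular_component
is_a: GO:0000004 ! c
"""

DIAMOND_OBO = """format-version: 1.2
ontology: test

[Term]
id: GO:0000001
name: root
namespace: cellular_component

[Term]
id: GO:0000002
name: a
namespace: cellular_component
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: b
namespace: cellular_component
is_a: GO:0000002 ! a

[Term]
id: GO:0000004
name: c
namespace: cellular_component
is_a: GO:0000002 ! a

[Term]
id: GO:0000005
name: d
namespace: cellular_component
is_a: GO:0000003 ! b
is_a: GO:0000004 ! c
"""


@pytest.fixture
def chain_graph():
    """root <- a <- b <- c <- d via is_a."""
    return ontology.parse_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture
def diamond_graph():
    """d is_a b, d is_a c, b is_a a, c is_a a, a is_a root."""
    return ontology.parse_obo(io.StringIO(DIAMOND_OBO))


def random_dag(seed: int, n_terms: int = 50, depth: int = 4) -> ontology.OntologyGraph:
    """Small random ontology for oracle comparisons."""
    config = synthetic.SyntheticConfig(seed=seed, n_terms=n_terms, depth=depth)
    return synthetic.generate_dag(config)


def random_corpus(seed: int, graph, n_proteins: int = 30):
    """Random direct annotations over a graph (independent of the generator)."""
    rng = np.random.default_rng(seed)
    root = next(iter(graph.roots.values()))
    terms = sorted(t for t in graph.terms if t != root)
    direct = {}
    for i in range(n_proteins):
        k = int(rng.integers(1, 4))
        direct[f"P{i:03d}"] = set(rng.choice(terms, size=min(k, len(terms)), replace=False))
    from termscape.annotation import AnnotationCorpus

    return AnnotationCorpus(direct=direct, namespace="cellular_component")


def brute_force_counts(graph, corpus, proteins=None):
    """Oracle: per-protein union of ancestor closures, then membership counts."""
    chosen = corpus.proteins if proteins is None else (proteins & corpus.proteins)
    counts: dict[str, int] = {}
    total = 0
    for protein in chosen:
        annots = corpus.direct[protein]
        if not annots:
            continue
        total += 1
        reached = set()
        for term in annots:
            reached.add(term)
            reached |= graph.ancestors(term)
        for term in reached:
            counts[term] = counts.get(term, 0) + 1
    return counts, total


ACCEPTANCE_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def default_runs():
    """The five fixed-seed end-to-end analyses of the default synthetic config."""
    runs = {}
    for seed in ACCEPTANCE_SEEDS:
        config = synthetic.SyntheticConfig(seed=seed)
        graph, background, abundance, truth = synthetic.simulate(config)
        result = pipeline.analyze(graph, background, abundance)
        runs[seed] = (graph, background, abundance, truth, result)
    return runs


@pytest.fixture(scope="session")
def default_run(default_runs):
    """The seed-0 run, for tests that need just one realization."""
    return default_runs[ACCEPTANCE_SEEDS[0]]
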