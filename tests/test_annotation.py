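"""GAF parsing, true-path counting, and fraction assignment."""

import io
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from termscape import annotation
from termscape.annotation import (
    assign_fractions,
    dataset_counts,
    parse_gaf,
    propagate_counts,
)

from conftest import brute_force_counts, random_corpus, random_dag


def gaf_row(protein, term, aspect="C", qualifier="located_in"):
    cols = [""] * 17
    cols[0], cols[1], cols[2] = "DB", protein, protein
    cols[3], cols[4], cols[5] = qualifier, term, "REF:1"
    cols[6], cols[8] = "IEA", aspect
    cols[11], cols[12], cols[13], cols[14] = "protein", "taxon:1", "20200101", "DB"
    return "\t".join(cols)


def make_gaf(rows):
    return io.StringIO("!gaf-version: 2.2\n" + "\n".join(rows) + "\n")


def test_not_qualifier_rows_are_dropped():
    corpus = parse_gaf(
        make_gaf(
            [
                gaf_row("P1", "GO:1"),
                gaf_row("P1", "GO:2", qualifier="NOT|located_in"),
                gaf_row("P2", "GO:1"),
            ]
        ),
        "cellular_component",
    )
    assert sum(len(v) for v in corpus.direct.values()) == 2


def test_duplicate_annotations_collapse():
    corpus = parse_gaf(
        make_gaf([gaf_row("P1", "GO:1"), gaf_row("P1", "GO:1")]), "cellular_component"
    )
    assert corpus.direct == {"P1": {"GO:1"}}


def test_aspect_filter_keeps_requested_namespace_only():
    rows = (
        [gaf_row(f"P{i}", f"GO:{i}", aspect="C") for i in range(4)]
        + [gaf_row(f"Q{i}", f"GO:{i}", aspect="P") for i in range(3)]
        + [gaf_row(f"R{i}", f"GO:{i}", aspect="F") for i in range(3)]
    )
    corpus = parse_gaf(make_gaf(rows), "cellular_component")
    assert set(corpus.direct) == {"P0", "P1", "P2", "P3"}


def test_malformed_rows_skipped_with_warning(caplog):
    rows = [gaf_row("P1", "GO:1"), "short\trow"]
    with caplog.at_level(logging.WARNING):
        corpus = parse_gaf(make_gaf(rows), "cellular_component")
    assert len(corpus) == 1
    assert "malformed" in caplog.text


def test_no_usable_rows_is_an_error():
    with pytest.raises(ValueError):
        parse_gaf(make_gaf([gaf_row("P1", "GO:1", aspect="P")]), "cellular_component")


def test_chain_propagation_reaches_root(chain_graph):
    corpus = annotation.AnnotationCorpus(
        direct={"P1": {"GO:0000005"}}, namespace="cellular_component"
    )
    index = propagate_counts(chain_graph, corpus)
    assert index.total == 1
    assert all(index[t] == 1 for t in chain_graph.terms)


def test_protein_with_two_children_counted_once(diamond_graph):
    corpus = annotation.AnnotationCorpus(
        direct={"P1": {"GO:0000003", "GO:0000004"}}, namespace="cellular_component"
    )
    index = propagate_counts(diamond_graph, corpus)
    assert index["GO:0000002"] == 1  # shared parent: one protein, one count
    assert index["GO:0000001"] == 1


@pytest.mark.parametrize("seed", range(3))
def test_propagation_matches_ancestor_union_oracle(seed):
    graph = random_dag(seed)
    corpus = random_corpus(seed, graph)
    index = propagate_counts(graph, corpus)
    counts, total = brute_force_counts(graph, corpus)
    assert index.counts == counts
    assert index.total == total


@pytest.mark.parametrize("seed", range(3))
def test_count_monotonicity_child_le_parent(seed):
    graph = random_dag(seed)
    index = propagate_counts(graph, random_corpus(seed, graph))
    for child, parent, _ in graph.edges():
        assert index[child] <= index[parent]


def test_disjoint_subset_warns_and_returns_zero(chain_graph, caplog):
    corpus = annotation.AnnotationCorpus(
        direct={"P1": {"GO:0000005"}}, namespace="cellular_component"
    )
    with caplog.at_level(logging.WARNING):
        index = propagate_counts(chain_graph, corpus, protein_subset={"ZZZ"})
    assert index.total == 0 and index.counts == {}


def abundance(rows):
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["cytosolic", "membrane", "nucleus"]
    )


def test_nucleus_enriched_protein_assigned_to_nucleus():
    # nucleus/cytosolic = 1.4 (>= 1.3) and nucleus/membrane = 1.4 (>= 1.3)
    table = abundance({"P1": [1.0, 1.0, 1.4]})
    assert assign_fractions(table).labels == {"P1": "nucleus"}


def test_flat_profile_is_non_specific():
    table = abundance({"P1": [1.0, 1.0, 1.0]})
    assert assign_fractions(table).labels == {"P1": "non-specific"}


def test_membrane_needs_fifty_percent_over_cytosolic():
    # membrane/cytosolic = 1.45 < 1.5 -> fails the 50% margin
    table = abundance({"P1": [1.0, 1.45, 1.0]})
    assert assign_fractions(table).labels == {"P1": "non-specific"}
    # 1.55 clears both the 50% (cytosolic) and 30% (nucleus) margins
    table = abundance({"P2": [1.0, 1.55, 1.0]})
    assert assign_fractions(table).labels == {"P2": "membrane"}


def test_zero_denominator_counts_as_infinite_enrichment():
    table = abundance({"P1": [0.0, 2.0, 0.0]})
    assert assign_fractions(table).labels == {"P1": "membrane"}


@settings(max_examples=30, deadline=None)
@given(
    intensities=st.lists(
        st.floats(min_value=0.01, max_value=1e3), min_size=3, max_size=3
    ),
    scale=st.floats(min_value=1e-3, max_value=1e3),
)
def test_assignment_invariant_under_row_rescaling(intensities, scale):
    t1 = abundance({"P1": intensities})
    t2 = abundance({"P1": [v * scale for v in intensities]})
    assert assign_fractions(t1).labels == assign_fractions(t2).labels


def test_negative_intensity_is_an_error():
    with pytest.raises(ValueError):
        assign_fractions(abundance({"P1": [1.0, -0.1, 1.0]}))


def test_unknown_fraction_in_margins_is_an_error():
    with pytest.raises(ValueError, match="unknown fraction"):
        assign_fractions(
            abundance({"P1": [1, 1, 1]}), margins={("golgi", "cytosolic"): 0.3}
        )


def test_dataset_totals_partition_annotated_proteins(chain_graph):
    corpus = annotation.AnnotationCorpus(
        direct={p: {"GO:0000003"} for p in ["P1", "P2", "P3", "P4"]},
        namespace="cellular_component",
    )
    table = abundance(
        {"P1": [2.0, 1.0, 1.0], "P2": [2.0, 1.0, 1.0], "P3": [1.0, 1.0, 1.0], "P4": [1, 1, 1]}
    )
    assignment = assign_fractions(table)
    per = dataset_counts(chain_graph, corpus, assignment)
    assert sum(index.total for index in per.values()) == 4
    assert per["cytosolic"].total == 2
    assert per["non-specific"].total == 2


@pytest.mark.parametrize("seed", range(2))
def test_dataset_counts_match_per_label_oracle(seed):
    graph = random_dag(seed)
    corpus = random_corpus(seed, graph, n_proteins=6)
    proteins = sorted(corpus.direct)
    rng = np.random.default_rng(seed)
    rows = {}
    for p in proteins:
        profile = [1.0, 1.0, 1.0]
        if rng.random() < 0.6:
            profile[int(rng.integers(3))] = 2.0
        rows[p] = profile
    assignment = assign_fractions(abundance(rows))
    per = dataset_counts(graph, corpus, assignment)
    for label in assignment.dataset_names:
        counts, total = brute_force_counts(graph, corpus, assignment.proteins_of(label))
        assert per[label].counts == counts
        assert per[label].total == total


def test_empty_label_yields_zero_total(chain_graph, caplog):
    corpus = annotation.AnnotationCorpus(
        direct={"P1": {"GO:0000002"}}, namespace="cellular_component"
    )
    assignment = assign_fractions(abundance({"P1": [2.0, 1.0, 1.0]}))
    with caplog.at_level(logging.WARNING):
        per = dataset_counts(chain_graph, corpus, assignment)
    assert per["nucleus"].total == 0


def test_unannotated_proteins_excluded_from_totals_by_default(chain_graph):
    corpus = annotation.AnnotationCorpus(
        direct={"P1": {"GO:0000002"}}, namespace="cellular_component"
    )
    assignment = assign_fractions(abundance({"P1": [2.0, 1, 1], "P2": [2.0, 1, 1]}))
    per = dataset_counts(chain_graph, corpus, assignment)
    assert per["cytosolic"].total == 1
    per_all = dataset_counts(chain_graph, corpus, assignment, count_unannotated=True)
    assert per_all["cytosolic"].total == 2
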