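"""Writers for analysis outputs: TSV tables, DOT subgraphs, SVG bi-plots.

All outputs are plain text with period decimal separators.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

from .multivariate import PCAModel, biplot_data
from .ontology import OntologyGraph
from .pipeline import AnalysisResult, EnrichmentReport

GROUPED_COLOR = "#4b7bd4"  # blue: terms picked up by PCA group extraction
ENRICHED_COLOR = "#e69138"  # orange: terms significant by hypergeometric test
BOTH_COLOR = "#cc0000"  # red: found by both routes
CONNECTOR_COLOR = "#bbbbbb"


def write_contribution(table: pd.DataFrame, path: str) -> None:
    table.round(2).to_csv(path, sep="\t", float_format="%.2f")


def write_groups(result: AnalysisResult, path: str) -> None:
    result.groups_frame().to_csv(path, sep="\t", index=False)


def write_biplot_tsv(model: PCAModel, path: str, i: int = 1, j: int = 2) -> None:
    biplot_data(model, i, j).to_csv(path, sep="\t", index=False)


def write_enrichment(report: EnrichmentReport, graph: OntologyGraph, outdir: str) -> None:
    for fraction, results in report.results.items():
        rows = [
            (
                r.term,
                graph.name_of(r.term) if r.term in graph else "",
                r.k,
                r.n,
                r.K,
                r.M,
                r.p_raw,
                r.p_adj,
                int(r.significant),
            )
            for r in results
        ]
        frame = pd.DataFrame(
            rows,
            columns=["term", "name", "k", "n", "K", "M", "p_raw", "p_adj", "significant"],
        )
        frame.to_csv(os.path.join(outdir, f"enrichment_{fraction}.tsv"), sep="\t", index=False)
    corr = pd.DataFrame(
        sorted(report.correlations.items()), columns=["fraction", "pearson_r"]
    )
    corr.to_csv(os.path.join(outdir, "enrichment_correlations.tsv"), sep="\t", index=False)


def write_dot(
    graph: OntologyGraph,
    grouped_terms: Iterable[str],
    enriched_terms: Iterable[str],
    path: str,
    include_ancestors: bool = True,
) -> None:
    """DOT export of the subgraph spanned by grouped and enriched terms.

    Grouped terms are colored blue, enriched terms orange, terms found
    by both routes red; ancestors added for connectivity stay grey.
    """
    grouped = {t for t in grouped_terms if t in graph}
    enriched = {t for t in enriched_terms if t in graph}
    keep = grouped | enriched
    if include_ancestors:
        extra: set[str] = set()
        for term in keep:
            extra |= graph.ancestors(term)
        keep = keep | extra

    def color(term: str) -> str:
        if term in grouped and term in enriched:
            return BOTH_COLOR
        if term in grouped:
            return GROUPED_COLOR
        if term in enriched:
            return ENRICHED_COLOR
        return CONNECTOR_COLOR

    lines = ["digraph ontology {", '  rankdir="BT";', '  node [style="filled", shape="box"];']
    for term in sorted(keep):
        name = graph.name_of(term).replace('"', "'")
        lines.append(f'  "{term}" [label="{term}\\n{name}", fillcolor="{color(term)}"];')
    for child, parent, rel in sorted(graph.edges()):
        if child in keep and parent in keep:
            style = "solid" if rel == "is_a" else "dashed"
            lines.append(f'  "{child}" -> "{parent}" [style="{style}", label="{rel}"];')
    lines.append("}")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def write_biplot_svg(
    model: PCAModel,
    labels: Mapping[str, object],
    path: str,
    i: int = 2,
    j: int = 3,
) -> None:
    """Bi-plot drawing (term scores colored by group, loading arrows)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = biplot_data(model, i, j)
    scores = data[data["kind"] == "score"]
    loadings = data[data["kind"] == "loading"]
    ci, cj = data.columns[2], data.columns[3]

    unique = sorted({str(labels.get(t, "unassigned")) for t in scores["point"]})
    cmap = plt.get_cmap("tab10")
    colors = {lab: cmap(n % 10) for n, lab in enumerate(unique)}

    fig, ax = plt.subplots(figsize=(7, 6))
    for lab in unique:
        pts = scores[[str(labels.get(t, "unassigned")) == lab for t in scores["point"]]]
        ax.scatter(pts[ci], pts[cj], s=12, alpha=0.7, label=lab, color=colors[lab])
    for _, row in loadings.iterrows():
        ax.annotate(
            "",
            xy=(row[ci], row[cj]),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="red"),
        )
        ax.text(row[ci], row[cj], str(row["point"]), color="red", fontsize=9)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"PC{i}")
    ax.set_ylabel(f"PC{j}")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
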