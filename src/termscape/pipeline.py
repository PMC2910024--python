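"""End-to-end orchestration: annotations -> scores -> PCA -> groups -> enrichment.

This is the programmatic surface the command line wraps: given an
ontology, an annotation corpus and a protein x fraction abundance
table, run fraction assignment, true-path counting, representation
scoring, PCA and group extraction, and optionally the hypergeometric
comparison per clean fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import annotation, enrichment, multivariate, scoring
from .annotation import AnnotationCorpus, FractionAssignment, TermCountIndex
from .multivariate import PCAModel, TermGroup
from .ontology import OntologyGraph
from .scoring import ScoreMatrix, TermScore

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    assignment: FractionAssignment
    background_counts: TermCountIndex
    dataset_counts: dict[str, TermCountIndex]
    scores: dict[str, list[TermScore]]
    matrix: ScoreMatrix
    model: PCAModel
    contribution: pd.DataFrame
    groups: list[TermGroup]
    group_counts: pd.DataFrame
    placeholder: float

    def groups_frame(self) -> pd.DataFrame:
        """Long-format groups table: label, term, score, rank."""
        rows = []
        for group in self.groups:
            first = group.label[0] if isinstance(group.label, tuple) else None
            for rank, term in enumerate(group.members, start=1):
                r = None
                if first is not None:
                    for s in self.scores.get(first, []):
                        if s.term == term:
                            r = s.r
                            break
                rows.append((group.label_text, term, r, rank))
        return pd.DataFrame(rows, columns=["label", "term", "r", "rank"])


@dataclass
class EnrichmentReport:
    results: dict[str, list[enrichment.EnrichmentResult]]
    correlations: dict[str, float | None] = field(default_factory=dict)


#: Default absence sentinel for the analysis entry point.  The classical
#: starting value -10 sits inside the bulk of finite log2 scores at
#: realistic corpus sizes, while a value at the finite minimum lets
#: absence dominate the variance; -16 sits between bulk and floor on
#: corpora of the scale this package targets.
DEFAULT_ANALYSIS_PLACEHOLDER = -16.0


def analyze(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    abundance: pd.DataFrame,
    variant: str = "bounded",
    placeholder: float | str = DEFAULT_ANALYSIS_PLACEHOLDER,
    margins: Mapping[frozenset[str], float] | None = None,
    cosine_threshold: float = 0.8,
    magnitude_quantile: float = 0.5,
    components: Sequence[int] | None = None,
    assignment_mode: str = "ratio",
    count_unannotated: bool = False,
) -> AnalysisResult:
    """Run the full analysis on one namespace.

    ``placeholder`` is either a fixed value, ``"auto"`` (one below the
    floor of the smallest finite log2 score, never above -10), or
    ``"grid"`` (auto start, then a descending grid searched for the
    best group separation).
    """
    assignment = annotation.assign_fractions(
        abundance, margins=margins, mode=assignment_mode
    )
    counts = annotation.dataset_counts(
        graph, corpus, assignment, count_unannotated=count_unannotated
    )
    background = annotation.propagate_counts(graph, corpus)

    scores: dict[str, list[TermScore]] = {}
    for name, index in counts.items():
        if index.total == 0:
            logger.warning("dataset %r is empty; excluded from the score matrix", name)
            continue
        scores[name] = scoring.score_dataset(graph, background, index, variant=variant)

    if len(scores) < 2:
        raise ValueError("need at least 2 non-empty datasets for PCA")

    if placeholder == "auto":
        chosen = scoring.placeholder_floor(scores)
    elif placeholder == "grid":
        chosen = scoring.select_placeholder(
            lambda c: scoring.build_matrix(scores, placeholder=c),
            scoring.DEFAULT_PLACEHOLDER_GRID,
        )
    else:
        chosen = float(placeholder)

    matrix = scoring.build_matrix(scores, placeholder=chosen)
    model = multivariate.pca(matrix)
    contribution = multivariate.contribution_table(model)
    groups = multivariate.extract_groups(
        model,
        matrix,
        cosine_threshold=cosine_threshold,
        magnitude_quantile=magnitude_quantile,
        components=components,
    )
    return AnalysisResult(
        assignment=assignment,
        background_counts=background,
        dataset_counts=counts,
        scores=scores,
        matrix=matrix,
        model=model,
        contribution=contribution,
        groups=groups,
        group_counts=multivariate.count_groups(groups),
        placeholder=chosen,
    )


def enrich_fractions(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    result: AnalysisResult,
    alpha: float = 0.05,
    scale: float = 100.0,
) -> EnrichmentReport:
    """Hypergeometric testing of each fraction's protein list.

    The target is a fraction's assigned-and-annotated proteins, the
    background the whole corpus.  Per fraction the report carries the
    Pearson correlation between the scaled representation score and
    -log10 p over terms present in that dataset (None when degenerate).
    """
    background_proteins = corpus.proteins
    report = EnrichmentReport(results={})
    for fraction in result.assignment.fractions:
        target = result.assignment.proteins_of(fraction) & background_proteins
        if not target:
            logger.warning("fraction %r has no annotated proteins; skipped", fraction)
            continue
        results = enrichment.enrich(
            graph, corpus, target=target, background=background_proteins, alpha=alpha
        )
        report.results[fraction] = results
        present = [s for s in result.scores.get(fraction, []) if s.x > 0]
        try:
            report.correlations[fraction] = enrichment.score_pvalue_correlation(
                present, results, scale=scale
            )
        except ValueError as exc:
            logger.warning("correlation undefined for %r: %s", fraction, exc)
            report.correlations[fraction] = None
    return report
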