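"""Hypergeometric over-representation testing and the R-vs-p comparison.

Classic term enrichment: for a term with K annotated proteins in a
background of M, the probability of seeing at least k annotated
proteins in a target list of size n by chance is the upper tail of a
hypergeometric distribution.  Counts are distinct-protein counts after
true-path propagation, mirroring the scoring side, so the two rankings
are directly comparable: the representation score R (scaled by 100) is
correlated against -log10 of the raw p-value over shared terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationCorpus, propagate_counts
from .ontology import DEFAULT_RELATIONS, OntologyGraph
from .scoring import TermScore


@dataclass
class EnrichmentResult:
    term: str
    k: int  # target proteins reaching the term
    n: int  # target size
    K: int  # background proteins reaching the term
    M: int  # background size
    p_raw: float
    p_adj: float = 1.0
    significant: bool = False


def hypergeom_pvalue(k: int, n: int, K: int, M: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(M, K, n).

    Evaluated through the survival function of
    :class:`scipy.stats.hypergeom`, which works in log space internally;
    the k = 0 tail is exactly 1.
    """
    if not (0 <= k <= n <= M):
        raise ValueError(f"require 0 <= k <= n <= M, got k={k}, n={n}, M={M}")
    if not (k <= K <= M):
        raise ValueError(f"require k <= K <= M, got k={k}, K={K}, M={M}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def bh_adjust(p_values: Sequence[float], method: str = "fdr_bh") -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept.

    ``method="bonferroni"`` is available as the conservative alternative.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method=method)
    return [float(v) for v in adjusted]


def enrich(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    target: set[str],
    background: set[str],
    alpha: float = 0.05,
    relations: frozenset[str] = DEFAULT_RELATIONS,
    method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Over-representation of every term with background support.

    ``target`` must be a subset of ``background``; counts come from
    true-path propagation restricted to each set.  Results are sorted by
    adjusted p-value, then term id, and flagged at level ``alpha``.
    """
    if not target:
        raise ValueError("empty target set")
    if not target <= background:
        raise ValueError("target is not a subset of the background")
    bg_index = propagate_counts(graph, corpus, protein_subset=background, relations=relations)
    tg_index = propagate_counts(graph, corpus, protein_subset=target, relations=relations)
    n, M = tg_index.total, bg_index.total
    if M == 0:
        raise ValueError("background has no annotated proteins")

    results = []
    for term in sorted(bg_index.counts):
        K = bg_index.counts[term]
        k = tg_index[term]
        results.append(
            EnrichmentResult(
                term=term, k=k, n=n, K=K, M=M, p_raw=hypergeom_pvalue(k, n, K, M)
            )
        )
    adjusted = bh_adjust([r.p_raw for r in results], method=method)
    for r, p_adj in zip(results, adjusted):
        r.p_adj = p_adj
        r.significant = p_adj <= alpha
    results.sort(key=lambda r: (r.p_adj, r.term))
    return results


def score_pvalue_correlation(
    scores: Iterable[TermScore],
    results: Iterable[EnrichmentResult],
    scale: float = 100.0,
    use_adjusted: bool = False,
) -> float:
    """Pearson correlation between scale*R and -log10(p) over shared terms.

    Raises ``ValueError`` with fewer than 3 shared terms or when either
    side is constant (the correlation is undefined, not zero).
    """
    r_by_term = {s.term: s.r for s in scores}
    pairs = []
    for res in results:
        if res.term in r_by_term:
            p = res.p_adj if use_adjusted else res.p_raw
            pairs.append((scale * r_by_term[res.term], -np.log10(p)))
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} shared terms; need at least 3")
    xs = np.array([a for a, _ in pairs])
    ys = np.array([b for _, b in pairs])
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("degenerate (constant) input; correlation undefined")
    return float(stats.pearsonr(xs, ys).statistic)
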