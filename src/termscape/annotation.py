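"""Protein annotations: GAF parsing, true-path counting, fraction assignment.

Two counting quantities drive the representation score: the number of
distinct background proteins reaching a term under the true-path rule
(``y_i`` out of ``M_GOA``) and the same count restricted to the proteins
of one experimental dataset (``x_i`` out of ``N_exp``).  A protein
annotated to several descendants of a term is counted once.

Proteins from a fractionation experiment are assigned to the fraction in
which they are sufficiently enriched over every other fraction; proteins
without a clear winner are pooled into the "non-specific" dataset, which
acts as an internal standard in the downstream analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .ontology import DEFAULT_RELATIONS, OntologyGraph

logger = logging.getLogger(__name__)

NON_SPECIFIC = "non-specific"

ASPECT_TO_NAMESPACE = {
    "C": "cellular_component",
    "P": "biological_process",
    "F": "molecular_function",
}

#: Pairwise enrichment margins of the subcellular fractionation protocol:
#: 30% for nucleus/cytosolic and membrane/nucleus, 50% for membrane/cytosolic.
DEFAULT_FRACTION_MARGINS: dict[frozenset[str], float] = {
    frozenset({"nucleus", "cytosolic"}): 0.30,
    frozenset({"membrane", "nucleus"}): 0.30,
    frozenset({"membrane", "cytosolic"}): 0.50,
}


@dataclass
class AnnotationCorpus:
    """Direct protein -> term annotations within one namespace."""

    direct: dict[str, set[str]]
    namespace: str

    @property
    def proteins(self) -> set[str]:
        return set(self.direct)

    def __len__(self) -> int:
        return len(self.direct)


@dataclass
class TermCountIndex:
    """Distinct-protein counts per term after true-path propagation.

    ``counts[t]`` is the number of distinct proteins annotated to ``t``
    or to any term below it; ``total`` is the number of distinct
    annotated proteins considered.
    """

    counts: dict[str, int]
    total: int

    def __getitem__(self, term: str) -> int:
        return self.counts.get(term, 0)


@dataclass
class FractionAssignment:
    """protein -> fraction label (or "non-specific")."""

    labels: dict[str, str]
    fractions: tuple[str, ...]

    def proteins_of(self, label: str) -> set[str]:
        return {p for p, lab in self.labels.items() if lab == label}

    @property
    def dataset_names(self) -> tuple[str, ...]:
        return self.fractions + (NON_SPECIFIC,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["protein", "fraction"]
        )


def parse_gaf(source: str | IO[str], namespace: str) -> AnnotationCorpus:
    """Parse a GAF 2.x association file, keeping one namespace (aspect).

    Rows whose qualifier contains ``NOT`` are dropped, duplicate
    (protein, term) pairs collapse to a single annotation, and malformed
    rows are skipped with a warning.  Raises ``ValueError`` if no usable
    row remains.
    """
    aspect = {v: k for k, v in ASPECT_TO_NAMESPACE.items()}.get(namespace)
    if aspect is None:
        raise ValueError(f"unknown namespace {namespace!r}")

    handle: IO[str]
    close = False
    if isinstance(source, str):
        handle = open(source)
        close = True
    else:
        handle = source

    direct: dict[str, set[str]] = {}
    malformed = 0
    try:
        for line in handle:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                malformed += 1
                continue
            protein, qualifier, term, row_aspect = cols[1], cols[3], cols[4], cols[8]
            if row_aspect != aspect:
                continue
            if "NOT" in qualifier.split("|"):
                continue
            if not protein or not term:
                malformed += 1
                continue
            direct.setdefault(protein, set()).add(term)
    finally:
        if close:
            handle.close()

    if malformed:
        logger.warning("skipped %d malformed GAF rows", malformed)
    if not direct:
        raise ValueError("no usable annotation rows in GAF input")
    return AnnotationCorpus(direct=direct, namespace=namespace)


def propagate_counts(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    protein_subset: set[str] | None = None,
    relations: frozenset[str] = DEFAULT_RELATIONS,
) -> TermCountIndex:
    """Distinct-protein counts per term under the true-path rule.

    Each protein contributes once to every directly annotated term and
    to all ancestors of those terms.  ``total`` counts the distinct
    proteins (optionally restricted to ``protein_subset``) carrying at
    least one annotation in the namespace.
    """
    if protein_subset is not None:
        proteins = protein_subset & corpus.proteins
        if not proteins and protein_subset:
            logger.warning("protein subset is disjoint from the annotation corpus")
    else:
        proteins = corpus.proteins

    # memoized per-term closure: ancestors(t) | {t}
    closure: dict[str, frozenset[str]] = {}

    def term_closure(term: str) -> frozenset[str]:
        got = closure.get(term)
        if got is None:
            got = frozenset(graph.ancestors(term, relations)) | {term}
            closure[term] = got
        return got

    counts: dict[str, int] = {}
    total = 0
    for protein in proteins:
        annotated = corpus.direct[protein]
        if not annotated:
            continue
        total += 1
        reached: set[str] = set()
        for term in annotated:
            reached |= term_closure(graph._check_term(term))
        for term in reached:
            counts[term] = counts.get(term, 0) + 1
    return TermCountIndex(counts=counts, total=total)


def _normalize_margins(
    fractions: Iterable[str],
    margins: Mapping[tuple[str, str] | frozenset[str], float] | None,
) -> dict[frozenset[str], float]:
    fractions = list(fractions)
    table: dict[frozenset[str], float] = {}
    source = margins if margins is not None else DEFAULT_FRACTION_MARGINS
    for pair, value in source.items():
        key = frozenset(pair)
        if value <= 0:
            raise ValueError(f"margin for {tuple(sorted(key))} must be positive")
        if margins is not None and not key <= set(fractions):
            raise ValueError(f"unknown fraction in thresholds: {tuple(sorted(key))}")
        table[key] = value
    return table


def pair_margin(
    a: str,
    b: str,
    margins: Mapping[tuple[str, str] | frozenset[str], float] | None = None,
    default: float = 0.30,
) -> float:
    """The symmetric enrichment margin configured for a fraction pair."""
    source = margins if margins is not None else DEFAULT_FRACTION_MARGINS
    table = {frozenset(k): v for k, v in source.items()}
    return table.get(frozenset({a, b}), default)


def assign_fractions(
    table: pd.DataFrame,
    margins: Mapping[tuple[str, str] | frozenset[str], float] | None = None,
    default_margin: float = 0.30,
    mode: str = "ratio",
) -> FractionAssignment:
    """Assign each protein to a fraction from its abundance profile.

    Enrichment of fraction A over B is ``I_A/I_B - 1`` (infinite when
    ``I_B`` is zero and ``I_A`` positive; zero when both vanish).  A
    protein is assigned to fraction F iff its enrichment over every
    other fraction meets the margin configured for that pair; otherwise
    it is labeled "non-specific".  Margins are symmetric per pair.

    ``mode="share"`` offers the alternative reading of the protocol in
    which a protein must carry at least ``margin`` more than an even
    share of its summed intensity in the winning fraction.
    """
    if mode not in ("ratio", "share"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    fractions = [c for c in table.columns]
    if len(fractions) < 2:
        raise ValueError("abundance table needs at least 2 fraction columns")
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative intensity in abundance table")
    if not np.isfinite(values).all():
        raise ValueError("non-finite intensity in abundance table")
    margin_table = _normalize_margins(fractions, margins)

    def margin_of(a: str, b: str) -> float:
        return margin_table.get(frozenset({a, b}), default_margin)

    labels: dict[str, str] = {}
    for protein, row in zip(table.index, values):
        intensities = dict(zip(fractions, row))
        winner = NON_SPECIFIC
        for cand in fractions:
            ok = True
            for other in fractions:
                if other == cand:
                    continue
                if mode == "ratio":
                    ia, ib = intensities[cand], intensities[other]
                    if ib == 0:
                        enr = math.inf if ia > 0 else 0.0
                    else:
                        enr = ia / ib - 1.0
                    if enr < margin_of(cand, other):
                        ok = False
                        break
                else:  # share mode: winning share exceeds even split by margin
                    tot = sum(intensities.values())
                    share = intensities[cand] / tot if tot > 0 else 0.0
                    if share < 1.0 / len(fractions) + margin_of(cand, other):
                        ok = False
                        break
            if ok:
                winner = cand
                break
        labels[str(protein)] = winner
    return FractionAssignment(labels=labels, fractions=tuple(fractions))


def dataset_counts(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    assignment: FractionAssignment,
    relations: frozenset[str] = DEFAULT_RELATIONS,
    count_unannotated: bool = False,
) -> dict[str, TermCountIndex]:
    """One propagated count index per dataset label (fractions + non-specific).

    ``N_exp`` of a dataset is, by default, its number of assigned proteins
    carrying at least one annotation in the namespace — unannotated
    proteins cannot contribute to any term and would only deflate all
    scores uniformly.  ``count_unannotated=True`` restores the
    "all detected proteins" semantics.
    """
    out: dict[str, TermCountIndex] = {}
    for label in assignment.dataset_names:
        proteins = assignment.proteins_of(label)
        index = propagate_counts(graph, corpus, protein_subset=proteins, relations=relations)
        if count_unannotated:
            index = TermCountIndex(counts=index.counts, total=len(proteins))
        if index.total == 0:
            logger.warning("dataset %r has no annotated proteins", label)
        out[label] = index
    return out


def read_abundance_table(source: str | IO[str]) -> pd.DataFrame:
    """Read a protein x fraction intensity TSV (first column = protein id)."""
    df = pd.read_csv(source, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError("abundance table needs at least 2 fraction columns")
    return df


def write_assignment(assignment: FractionAssignment, path: str) -> None:
    assignment.to_frame().to_csv(path, sep="\t", index=False)
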