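"""Synthetic ontologies, annotation corpora and fractionation experiments.

Everything downstream of mass-spectrometry acquisition can be exercised
without any external download: a random layered DAG stands in for one
GO namespace, a background corpus of annotated proteins stands in for
the GOA release, and per-fraction experiments are built by planting
fraction-specific signature branches — proteins annotated inside a
fraction's signature subtree receive intensities that clear the
fraction-assignment margins, all other proteins get near-flat profiles.

The generator's defaults mirror the fractionated cardiomyocyte study
the method was designed around: three fractions (cytosolic, membrane,
nucleus) with 179, 328 and 45 proteins, 1284 non-specific proteins, and
a background of 2000 annotated proteins over a 200-term DAG.

The ground truth (which terms and proteins were planted where) is
returned alongside, so recovery rates are measurable exactly.

Determinism: one integer seed drives all stages; each stage draws from
``numpy.random.default_rng([seed, stage])`` with a fixed stage index
(0 = DAG, 1 = background, 2 = experiment), so adding draws to one stage
never perturbs another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import IO, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import (
    DEFAULT_FRACTION_MARGINS,
    AnnotationCorpus,
    pair_margin,
)
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

_STAGE_DAG, _STAGE_BACKGROUND, _STAGE_EXPERIMENT = 0, 1, 2


@dataclass(frozen=True)
class FractionSpec:
    """One planted fraction dataset."""

    name: str
    n_proteins: int
    signature_terms: int = 10
    signal_prob: float = 0.8
    ratio_margin: float = 0.3  # planted enrichment above each pair's threshold


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_terms: int = 200
    depth: int = 6
    extra_parent_prob: float = 0.15
    m_goa: int = 2000
    # fraction sizes keep the 179:328:45 (+1284 non-specific) proportions
    # of the motivating fractionation study at half scale, so the
    # detected experiment stays a minority subset of the 2000-protein
    # background the way a real detected proteome is of a full GOA corpus
    # signal_prob is the share of a fraction's proteins annotated inside
    # its planted branch; the rest carry generic annotations.  The
    # cytosol is by far the least annotation-specific compartment (most
    # cytosolic proteins carry generic localization terms), membranes
    # and nuclei the most — the asymmetry that shapes real
    # fraction-by-component correlation tables.
    fractions: tuple[FractionSpec, ...] = (
        FractionSpec("cytosolic", 90, signature_terms=5, signal_prob=0.15),
        FractionSpec("membrane", 164, signature_terms=12, signal_prob=0.85),
        FractionSpec("nucleus", 22, signature_terms=10, signal_prob=0.9),
    )
    n_nonspecific: int = 642
    noise_annotations: float = 3.0
    annotation_coherence: float = 0.8  # P(extra annotation stays in home branch)
    namespace: str = "cellular_component"
    margins: Mapping[frozenset[str], float] | None = None

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticTruth:
    """What was planted: signature terms and signal proteins per fraction."""

    signature_terms: dict[str, set[str]]
    signal_proteins: dict[str, set[str]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fraction in sorted(self.signature_terms):
            for term in sorted(self.signature_terms[fraction]):
                rows.append((fraction, "term", term))
        for fraction in sorted(self.signal_proteins):
            for protein in sorted(self.signal_proteins[fraction]):
                rows.append((fraction, "protein", protein))
        return pd.DataFrame(rows, columns=["fraction", "kind", "item"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SyntheticTruth":
        truth = cls(signature_terms={}, signal_proteins={})
        for fraction, kind, item in df.itertuples(index=False):
            target = truth.signature_terms if kind == "term" else truth.signal_proteins
            target.setdefault(fraction, set()).add(item)
        return truth


def _term_id(i: int) -> str:
    return f"GO:{9000000 + i:07d}"


def _protein_id(i: int) -> str:
    return f"P{i:06d}"


def generate_dag(config: SyntheticConfig) -> OntologyGraph:
    """A single-root layered DAG of ``n_terms`` terms.

    Terms sit in depth layers 0..depth; each non-root term gets one
    ``is_a`` parent from the previous layer plus, with probability
    ``extra_parent_prob``, one extra parent from any earlier layer
    (``part_of`` with probability 1/4).  Deeper layers hold more terms,
    mimicking the fan-out of real ontologies.
    """
    if config.depth < 2:
        raise ValueError("depth must be >= 2")
    if config.n_terms < 1:
        raise ValueError("need at least one term")
    rng = np.random.default_rng([config.seed, _STAGE_DAG])

    if config.n_terms == 1:
        root = _term_id(0)
        graph = nx.MultiDiGraph()
        graph.add_node(root)
        return OntologyGraph(
            terms={root: (f"synthetic term {root[3:]} (level 0)", config.namespace)},
            graph=graph,
            roots={config.namespace: root},
            obsolete=set(),
            alt_ids={},
        )

    n_inner = config.n_terms - 1
    depth = min(config.depth, n_inner)
    # layer sizes double with depth, as in real ontologies: most terms
    # are specific leaves, so propagated counts fall steeply with depth
    weights = 2.0 ** np.arange(1, depth + 1)
    weights /= weights.sum()
    sizes = np.maximum(1, np.floor(weights * n_inner).astype(int))
    while sizes.sum() > n_inner:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_inner:
        sizes[np.argmax(weights)] += 1

    layers: list[list[str]] = [[_term_id(0)]]
    next_id = 1
    for size in sizes:
        layers.append([_term_id(next_id + i) for i in range(size)])
        next_id += size

    terms: dict[str, tuple[str, str]] = {}
    graph = nx.MultiDiGraph()
    for level, layer in enumerate(layers):
        for term in layer:
            terms[term] = (f"synthetic term {term[3:]} (level {level})", config.namespace)
            graph.add_node(term)

    # branch = depth-2 ancestor along the primary parent chain; extra
    # parents prefer the same branch, as multiple parentage in real
    # ontologies mostly stays within a functional neighbourhood
    branch_of: dict[str, str | None] = {layers[0][0]: None}
    for level in range(1, len(layers)):
        prev = layers[level - 1]
        # spread children evenly over the previous layer (random within
        # the least-loaded parents) so subtree mass decays regularly
        # with depth instead of collapsing into a few giant branches
        load = {p: 0 for p in prev}
        for term in layers[level]:
            lightest = min(load.values())
            pool_parents = [p for p in prev if load[p] == lightest]
            parent = pool_parents[rng.integers(len(pool_parents))]
            load[parent] += 1
            graph.add_edge(term, parent, key="is_a")
            if level == 1:
                branch_of[term] = None
            elif level == 2:
                branch_of[term] = term
            else:
                branch_of[term] = branch_of[parent]
            if level >= 2 and rng.random() < config.extra_parent_prob:
                extra_level = int(rng.integers(max(1, level - 2), level))
                candidates = [p for p in layers[extra_level] if p != parent]
                if candidates and rng.random() < 0.7:
                    same = [p for p in candidates if branch_of.get(p) == branch_of[term]]
                    if same:
                        candidates = same
                if candidates:
                    extra = candidates[rng.integers(len(candidates))]
                    relation = "part_of" if rng.random() < 0.25 else "is_a"
                    if not graph.has_edge(term, extra, key=relation):
                        graph.add_edge(term, extra, key=relation)

    root = layers[0][0]
    return OntologyGraph(
        terms=terms,
        graph=graph,
        roots={config.namespace: root},
        obsolete=set(),
        alt_ids={},
    )


def term_layers(graph: OntologyGraph) -> dict[str, int]:
    """Longest-path depth of every term (root = 0)."""
    depths: dict[str, int] = {}
    for term in nx.topological_sort(graph.graph.reverse()):
        parents = graph.parents(term)
        depths[term] = 0 if not parents else 1 + max(depths[p] for p in parents)
    return depths


def generate_background(config: SyntheticConfig, graph: OntologyGraph) -> AnnotationCorpus:
    """``m_goa`` proteins with coherent, depth-weighted direct annotations.

    Each protein carries ``Poisson(noise_annotations) + 1`` distinct
    direct annotations.  The first is a "home" term drawn from all
    non-root terms with probability proportional to depth; each extra
    annotation stays in the home neighbourhood (the home term's
    ancestors and descendants) with probability
    ``annotation_coherence``, otherwise it lands anywhere.  This mirrors
    the coherence of real annotation corpora, where one protein's terms
    cluster in a functional branch.  Every term is guaranteed propagated
    support (y >= 1): for a term nobody reaches, one protein's
    annotation is swapped for it (choosing a donor annotation that at
    least one other protein shares, so no term loses support).
    """
    rng = np.random.default_rng([config.seed, _STAGE_BACKGROUND])
    depths = term_layers(graph)
    root = graph.roots[config.namespace]
    pool = sorted(t for t in graph.terms if t != root)
    # deeper terms carry more direct annotation mass (curators annotate
    # the most specific applicable term), but within a depth layer the
    # heavily cross-classified terms — those with many ancestors — are
    # the most specific and the most sparsely annotated
    weights = np.array(
        [depths[t] ** 2 / max(graph.specificity_level(t), 1) for t in pool],
        dtype=float,
    )
    weights /= weights.sum()

    local_pools: dict[str, tuple[list[str], np.ndarray]] = {}

    def local_pool(home: str) -> tuple[list[str], np.ndarray]:
        got = local_pools.get(home)
        if got is None:
            terms = sorted(
                ({home} | graph.descendants(home) | graph.ancestors(home)) - {root}
            )
            w = np.array([depths[t] for t in terms], dtype=float)
            got = (terms, w / w.sum())
            local_pools[home] = got
        return got

    direct: dict[str, set[str]] = {}
    for i in range(config.m_goa):
        n_annot = int(rng.poisson(config.noise_annotations)) + 1
        home = pool[rng.choice(len(pool), p=weights)]
        annots = {home}
        neighbours, n_weights = local_pool(home)
        guard = 0
        while len(annots) < n_annot and guard < 10 * n_annot:
            guard += 1
            if rng.random() < config.annotation_coherence:
                annots.add(neighbours[rng.choice(len(neighbours), p=n_weights)])
            else:
                annots.add(pool[rng.choice(len(pool), p=weights)])
        direct[_protein_id(i)] = annots

    _ensure_coverage(graph, direct, rng)
    return AnnotationCorpus(direct=direct, namespace=config.namespace)


def _ensure_coverage(
    graph: OntologyGraph, direct: dict[str, set[str]], rng: np.random.Generator
) -> None:
    covered: set[str] = set()
    annotators: dict[str, int] = {}
    for annots in direct.values():
        for term in annots:
            annotators[term] = annotators.get(term, 0) + 1
            if term not in covered:
                covered.add(term)
                covered |= graph.ancestors(term)
    uncovered = sorted(set(graph.terms) - covered)
    if not uncovered:
        return
    proteins = sorted(direct)
    for term in uncovered:
        placed = False
        for pi in rng.permutation(len(proteins)):
            protein = proteins[pi]
            # donor annotation that another protein shares: removing it
            # cannot uncover anything
            donors = sorted(a for a in direct[protein] if annotators[a] >= 2)
            if not donors:
                continue
            donor = donors[int(rng.integers(len(donors)))]
            direct[protein].remove(donor)
            annotators[donor] -= 1
            direct[protein].add(term)
            annotators[term] = annotators.get(term, 0) + 1
            placed = True
            break
        if not placed:  # pathological tiny corpus: add rather than swap
            protein = proteins[int(rng.integers(len(proteins)))]
            direct[protein].add(term)
            annotators[term] = annotators.get(term, 0) + 1
            logger.warning("added extra annotation to cover term %s", term)


def generate_experiment(
    config: SyntheticConfig,
    graph: OntologyGraph,
    background: AnnotationCorpus,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Plant fraction-specific signatures and build the abundance table.

    Per fraction a disjoint subtree rooted at depth 2 provides the
    signature terms (the ``signature_terms`` best-supported members of
    the subtree).  A fraction's proteins are sampled from the background:
    a ``signal_prob`` share from proteins directly annotated inside the
    signature, the rest at random.  Signal proteins get an intensity in
    their fraction exceeding every pairwise assignment threshold by at
    least ``ratio_margin``; all other intensities are flat within ±5%.
    Additional ``n_nonspecific`` proteins carry flat profiles only.

    Returns the protein x fraction intensity table and the ground truth.
    """
    rng = np.random.default_rng([config.seed, _STAGE_EXPERIMENT])
    depths = term_layers(graph)
    fraction_names = [f.name for f in config.fractions]

    # --- signature branches, disjoint across fractions -------------------
    # Each fraction accumulates one or more unused subtrees rooted at
    # depth >= 2 until the direct annotators of its signature closure can
    # supply the fraction's signal proteins; the signature terms are the
    # best-supported members of the accumulated branch.
    support = _direct_support(graph, background)
    candidates = sorted(t for t, d in depths.items() if d >= 2)
    rng.shuffle(candidates)
    # compact subtrees rooted near depth 3: deep enough that the planted
    # branch is specific, shallow enough that its spine terms are
    # covered by most of the branch's proteins
    candidates.sort(key=lambda t: abs(depths[t] - 3))
    all_proteins = sorted(background.direct)

    def closure_annotators(terms: set[str]) -> set[str]:
        below: set[str] = set()
        for term in terms:
            below |= {term} | graph.descendants(term)
        return {p for p in all_proteins if background.direct[p] & below}

    used: set[str] = set()  # terms claimed by earlier branches or closures
    signature_terms: dict[str, set[str]] = {}
    earlier_annotators: set[str] = set()
    top_layer = {t for t, d in depths.items() if d == 1}
    claimed_families: set[str] = set()  # top-level ancestors of earlier branches

    def down_closure(term: str) -> set[str]:
        return {term} | graph.descendants(term)

    def family(term: str) -> frozenset[str]:
        return frozenset(graph.ancestors(term) & top_layer)

    for spec in config.fractions:
        n_signal = int(round(spec.signal_prob * spec.n_proteins))
        target = int(n_signal * 1.35) + 10  # headroom for multi-branch removal
        accumulated: set[str] = set()
        picked: set[str] | None = None
        # branches of different fractions descend from different
        # top-level families where possible: the branch's well-covered
        # ancestor spine is then specific to its fraction, as real
        # compartment branches (cytosol, membrane, nucleus) are
        own_families: set[str] = set()
        fraction_candidates = sorted(
            candidates,
            key=lambda t: bool(family(t) & claimed_families),
        )
        for root in fraction_candidates:
            if root in used or root in accumulated:
                continue
            subtree = ({root} | graph.descendants(root)) - used - accumulated
            if not any(support.get(t, 0) > 0 for t in subtree):
                continue
            accumulated |= subtree
            # signature candidates must not reach into any other branch's
            # closure, so planted branches stay pairwise disjoint even
            # across the DAG's cross-links
            # signature = the best-supported terms of the accumulated
            # branch (its spine): each branch protein then covers most
            # of the signature terms on its ancestor path, as the
            # well-covered spine of a real compartment branch would be
            supported = sorted(
                (
                    t
                    for t in accumulated
                    if support.get(t, 0) > 0 and not (down_closure(t) & used)
                ),
                key=lambda t: (-support[t], t),
            )
            if len(supported) < spec.signature_terms:
                continue
            own_families |= family(root)
            candidate_sig = set(supported[: spec.signature_terms])
            pool = closure_annotators(candidate_sig) - earlier_annotators
            if len(pool) >= target:
                picked = candidate_sig
                break
        if picked is None:
            raise ValueError(
                f"cannot assemble a signature branch for fraction {spec.name!r} "
                f"with {target} available annotators; increase n_terms or m_goa"
            )
        signature_terms[spec.name] = picked
        used |= accumulated
        for term in picked:
            used |= down_closure(term)
        earlier_annotators |= closure_annotators(picked)
        claimed_families |= own_families

    # --- protein sampling -------------------------------------------------
    # A fraction's signal proteins come from the direct annotators of its
    # signature branch.  Fraction datasets stay exclusive, as subcellular
    # fractionation makes them: a branch's annotators never enter another
    # fraction, and proteins annotated in several branches stay out of
    # the experiment entirely (an undetected part of the background).
    # The non-specific pool is unrestricted — like the study's internal
    # standard it may touch every branch.
    branch_annotators: dict[str, set[str]] = {
        spec.name: closure_annotators(signature_terms[spec.name])
        for spec in config.fractions
    }
    multi_branch = {
        p
        for a, pa in branch_annotators.items()
        for b, pb in branch_annotators.items()
        if a < b
        for p in pa & pb
    }

    taken: set[str] = set(multi_branch)
    signal_proteins: dict[str, set[str]] = {}
    fraction_proteins: dict[str, list[str]] = {}
    for spec in config.fractions:
        pool = sorted(branch_annotators[spec.name] - taken)
        n_signal = int(round(spec.signal_prob * spec.n_proteins))
        if len(pool) < n_signal:
            raise ValueError(
                f"background provides only {len(pool)} signature-branch proteins "
                f"for fraction {spec.name!r} (need {n_signal}); increase m_goa "
                "or reduce n_proteins"
            )
        # stratified first pass: every signature term keeps at least one
        # sampled annotator, so no planted term drops out of the matrix
        signal: list[str] = []
        chosen: set[str] = set()
        for term in sorted(signature_terms[spec.name]):
            below = {term} | graph.descendants(term)
            if any(background.direct[p] & below for p in chosen):
                continue
            annotators = [p for p in pool if p not in chosen and background.direct[p] & below]
            if annotators:
                pick = annotators[int(rng.integers(len(annotators)))]
                signal.append(pick)
                chosen.add(pick)
        remaining = [p for p in pool if p not in chosen]
        n_fill = n_signal - len(signal)
        fill = [remaining[i] for i in rng.choice(len(remaining), size=n_fill, replace=False)]
        signal.extend(fill)
        # unsampled branch annotators may still surface in the
        # non-specific pool, never in another fraction
        taken.update(branch_annotators[spec.name])
        signal_proteins[spec.name] = set(signal)
        fraction_proteins[spec.name] = sorted(signal)

    clean_pool = [p for p in all_proteins if p not in taken]
    for spec in config.fractions:
        n_rest = spec.n_proteins - len(fraction_proteins[spec.name])
        if len(clean_pool) < n_rest:
            raise ValueError("background too small for the requested fraction sizes")
        rest = [clean_pool[i] for i in rng.choice(len(clean_pool), size=n_rest, replace=False)]
        clean_pool = [p for p in clean_pool if p not in set(rest)]
        fraction_proteins[spec.name] = fraction_proteins[spec.name] + rest

    # The non-specific dataset mirrors a housekeeping proteome: like the
    # fractions it concentrates in compartment branches of its own
    # (ribosome-, mitochondrion-like structures outside every planted
    # signature), rather than sampling the background diffusely.  It
    # draws from branch-free proteins only, so each planted branch stays
    # exclusive to its fraction dataset; unsampled branch annotators
    # remain undetected background.
    if len(clean_pool) < config.n_nonspecific:
        raise ValueError("background too small for the requested non-specific pool")
    clean_set = set(clean_pool)
    ns_target = int(0.7 * config.n_nonspecific)
    ns_pool: set[str] = set()
    for root in candidates:
        if root in used:
            continue
        subtree = ({root} | graph.descendants(root)) - used
        if not subtree:
            continue
        used |= subtree
        below: set[str] = set()
        for term in subtree:
            below |= {term} | graph.descendants(term)
        ns_pool |= {p for p in clean_set if background.direct[p] & below}
        if len(ns_pool) >= ns_target:
            break
    ns_home = sorted(ns_pool)
    n_home = min(len(ns_home), ns_target)
    nonspecific = [ns_home[i] for i in rng.choice(len(ns_home), size=n_home, replace=False)]
    rest_ns_pool = sorted(clean_set - set(nonspecific))
    n_rest_ns = config.n_nonspecific - n_home
    if len(rest_ns_pool) < n_rest_ns:
        raise ValueError("background too small for the requested non-specific pool")
    nonspecific += [
        rest_ns_pool[i] for i in rng.choice(len(rest_ns_pool), size=n_rest_ns, replace=False)
    ]

    # --- intensities ------------------------------------------------------
    margins = config.margins if config.margins is not None else DEFAULT_FRACTION_MARGINS
    rows: dict[str, np.ndarray] = {}

    def flat_profile(base: float) -> np.ndarray:
        return base * (1.0 + rng.uniform(-0.05, 0.05, size=len(fraction_names)))

    for spec in config.fractions:
        max_thr = max(
            pair_margin(spec.name, other, margins)
            for other in fraction_names
            if other != spec.name
        )
        for protein in fraction_proteins[spec.name]:
            base = float(rng.uniform(80.0, 120.0))
            profile = flat_profile(base)
            # every protein of the fraction is abundance-enriched there,
            # clearing each pairwise threshold by >= ratio_margin even
            # against the +5% jitter of the other columns
            col = fraction_names.index(spec.name)
            profile[col] = (
                base
                * 1.05
                * (1.0 + max_thr + spec.ratio_margin + rng.uniform(0.0, 0.05))
            )
            rows[protein] = profile
    for protein in nonspecific:
        rows[protein] = flat_profile(float(rng.uniform(80.0, 120.0)))

    table = pd.DataFrame.from_dict(rows, orient="index", columns=fraction_names)
    table = table.sort_index()
    table.index.name = "protein"
    truth = SyntheticTruth(signature_terms=signature_terms, signal_proteins=signal_proteins)
    return table, truth


def _direct_support(graph: OntologyGraph, corpus: AnnotationCorpus) -> dict[str, int]:
    """Per-term count of proteins directly annotated at or below the term."""
    reached: dict[str, set[str]] = {}
    for protein, annots in corpus.direct.items():
        for term in annots:
            reached.setdefault(term, set()).add(protein)
            for anc in graph.ancestors(term):
                reached.setdefault(anc, set()).add(protein)
    return {t: len(ps) for t, ps in reached.items()}


# ---------------------------------------------------------------------------
# standard-format writers, so the pipeline consumes only ordinary files


def write_obo(graph: OntologyGraph, path: str | IO[str]) -> None:
    handle, close = (open(path, "w"), True) if isinstance(path, str) else (path, False)
    try:
        handle.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(graph.terms):
            name, ns = graph.terms[term]
            handle.write(f"\n[Term]\nid: {term}\nname: {name}\nnamespace: {ns}\n")
            for _, parent, rel in sorted(graph.graph.out_edges(term, keys=True)):
                if rel == "is_a":
                    handle.write(f"is_a: {parent} ! {graph.terms[parent][0]}\n")
                else:
                    handle.write(f"relationship: {rel} {parent} ! {graph.terms[parent][0]}\n")
    finally:
        if close:
            handle.close()


_ASPECT = {"cellular_component": "C", "biological_process": "P", "molecular_function": "F"}


def write_gaf(corpus: AnnotationCorpus, path: str | IO[str]) -> None:
    aspect = _ASPECT[corpus.namespace]
    handle, close = (open(path, "w"), True) if isinstance(path, str) else (path, False)
    try:
        handle.write("!gaf-version: 2.2\n")
        for protein in sorted(corpus.direct):
            for term in sorted(corpus.direct[protein]):
                cols = [
                    "SYNTH",  # DB
                    protein,  # DB object id
                    protein,  # symbol
                    "located_in",  # qualifier
                    term,  # GO id
                    "SYNTH:0000000",  # reference
                    "IEA",  # evidence
                    "",  # with/from
                    aspect,  # aspect
                    "",  # name
                    "",  # synonyms
                    "protein",  # type
                    "taxon:0000",  # taxon
                    "20200101",  # date
                    "SYNTH",  # assigned by
                    "",  # extension
                    "",  # gene product form
                ]
                handle.write("\t".join(cols) + "\n")
    finally:
        if close:
            handle.close()


def write_abundance(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t")


def write_truth(truth: SyntheticTruth, path: str) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> SyntheticTruth:
    return SyntheticTruth.from_frame(pd.read_csv(path, sep="\t"))


def simulate(config: SyntheticConfig):
    """Run all three stages; returns (graph, background, abundance, truth)."""
    graph = generate_dag(config)
    background = generate_background(config, graph)
    table, truth = generate_experiment(config, graph, background)
    return graph, background, table, truth
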