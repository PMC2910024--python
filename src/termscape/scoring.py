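"""The representation score R and the transformed term x dataset matrix.

For term *i* in one experimental dataset the score combines the squared
experimental relative frequency with a square-rooted background factor:

    bounded (default):   R_i = (x_i / N_exp)^2 * sqrt(y_i / M_GOA)
    reciprocal:          R_i = (x_i / N_exp)^2 * sqrt(M_GOA / y_i)

where x_i (y_i) is the number of distinct experimental (background)
proteins reaching term *i* under the true-path rule, and N_exp (M_GOA)
the corresponding totals.  Squaring the first factor spreads the
experimental frequencies; the second factor normalizes against the full
annotation corpus.  The bounded variant lies in [0, 1] by construction
and decreases from the root toward the leaves along every edge, so a
decreasing sort places the most specific terms last.  The reciprocal
variant follows the alternative reading in which the background factor
is the reciprocal relative frequency; it is min-max rescaled to [0, 1]
per dataset after the fact.

Scores of all datasets are assembled into a term x dataset matrix of
log2-transformed values; a term absent from a dataset (x = 0) receives a
finite placeholder (default -10, optionally tuned on a grid) instead of
log2(0), and the cell is flagged in an absence mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .annotation import TermCountIndex
from .ontology import OntologyGraph

VARIANTS = ("bounded", "reciprocal")

DEFAULT_PLACEHOLDER = -10.0
DEFAULT_PLACEHOLDER_GRID = tuple(float(v) for v in range(-10, -31, -1))


@dataclass
class TermScore:
    """Representation score of one term in one dataset."""

    term: str
    x: int
    y: int
    n_exp: int
    m_goa: int
    r: float

    @property
    def log_r(self) -> float | None:
        """log2(R), or None where the term is absent (x = 0)."""
        return math.log2(self.r) if self.r > 0 else None


@dataclass
class ScoreMatrix:
    """Term x dataset matrix of log2 R values with an absence mask."""

    values: pd.DataFrame
    mask: pd.DataFrame  # True where x = 0 (cell holds the placeholder)
    placeholder: float

    @property
    def terms(self) -> list[str]:
        return list(self.values.index)

    @property
    def datasets(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, values_path: str, mask_path: str | None = None) -> None:
        self.values.to_csv(values_path, sep="\t")
        if mask_path is not None:
            self.mask.astype(int).to_csv(mask_path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path: str, mask_path: str, placeholder: float) -> "ScoreMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        mask = pd.read_csv(mask_path, sep="\t", index_col=0).astype(bool)
        return cls(values=values, mask=mask, placeholder=placeholder)


def rscore(x: int, n_exp: int, y: int, m_goa: int, variant: str = "bounded") -> float:
    """Representation score of one term (before any per-dataset rescaling).

    Raises ``ValueError`` on impossible counts (x > n_exp, y = 0, y > m_goa).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if n_exp < 1:
        raise ValueError("n_exp must be >= 1")
    if not 0 <= x <= n_exp:
        raise ValueError(f"x={x} outside [0, n_exp={n_exp}]")
    if y < 1:
        raise ValueError("term absent from background (y = 0) cannot be scored")
    if y > m_goa:
        raise ValueError(f"y={y} exceeds m_goa={m_goa}")
    freq = (x / n_exp) ** 2
    if variant == "bounded":
        return freq * math.sqrt(y / m_goa)
    return freq * math.sqrt(m_goa / y)


def score_dataset(
    graph: OntologyGraph,
    background: TermCountIndex,
    experiment: TermCountIndex,
    variant: str = "bounded",
) -> list[TermScore]:
    """Score every term with background support (y >= 1) for one dataset.

    Under the reciprocal variant the raw scores are min-max rescaled to
    [0, 1] across the dataset's terms (zeros stay zero).
    """
    if background.total < 1:
        raise ValueError("background total is 0")
    if experiment.total < 1:
        raise ValueError("experiment total is 0")
    scores: list[TermScore] = []
    for term in sorted(background.counts):
        y = background.counts[term]
        x = experiment[term]
        r = rscore(x, experiment.total, y, background.total, variant=variant)
        scores.append(
            TermScore(term=term, x=x, y=y, n_exp=experiment.total, m_goa=background.total, r=r)
        )
    if variant == "reciprocal":
        positive = [s.r for s in scores if s.x > 0]
        if positive:
            lo, hi = min(positive), max(positive)
            span = hi - lo
            for s in scores:
                if s.x > 0:
                    # keep strictly positive so log2 stays defined
                    s.r = (s.r - lo) / span * 0.999 + 0.001 if span > 0 else 1.0
    return scores


def placeholder_floor(scores: Mapping[str, Sequence[TermScore]]) -> float:
    """Largest integer placeholder safely below every finite log2 score.

    The canonical starting value is -10, but on datasets whose rarest
    present terms score below 2**-10 the placeholder must sink further
    so that absence still sorts below presence.
    """
    finite_min = math.inf
    for ds_scores in scores.values():
        for s in ds_scores:
            if s.x > 0:
                finite_min = min(finite_min, math.log2(s.r))
    if not math.isfinite(finite_min):
        raise ValueError("no term is present in any dataset")
    return min(DEFAULT_PLACEHOLDER, float(math.floor(finite_min)) - 1.0)


def build_matrix(
    scores: Mapping[str, Sequence[TermScore]],
    placeholder: float = DEFAULT_PLACEHOLDER,
    strict: bool = False,
) -> ScoreMatrix:
    """Assemble per-dataset scores into the log2 matrix fed to PCA.

    Rows are the union of terms present (x > 0) in at least one dataset
    (their ancestors are included automatically, since true-path
    propagation makes ancestor counts at least as large).  Cells of
    absent terms hold ``placeholder``.

    The canonical placeholder, -10, is a *soft* sentinel: on data of
    realistic size the rarest present terms score below it, so absence
    ranks as "moderately rare" rather than as an extreme outlier, which
    keeps the leading principal component on the specificity gradient
    of the present values.  With ``strict=True`` the placeholder must
    instead lie below every finite log2 score (absence sorts strictly
    below presence), which errors out otherwise.
    """
    datasets = sorted(scores)
    present: set[str] = set()
    for ds in datasets:
        present.update(s.term for s in scores[ds] if s.x > 0)
    terms = sorted(present)
    if not terms:
        raise ValueError("no term is present in any dataset")

    values = pd.DataFrame(placeholder, index=terms, columns=datasets, dtype=float)
    mask = pd.DataFrame(True, index=terms, columns=datasets, dtype=bool)
    finite_min = math.inf
    for ds in datasets:
        for s in scores[ds]:
            if s.x > 0 and s.term in present:
                log_r = math.log2(s.r)
                values.at[s.term, ds] = log_r
                mask.at[s.term, ds] = False
                finite_min = min(finite_min, log_r)
    if strict and placeholder >= finite_min:
        raise ValueError(
            f"placeholder {placeholder} is not below the smallest finite "
            f"log2 score {finite_min:.4f}; it would scramble the ordering"
        )
    return ScoreMatrix(values=values, mask=mask, placeholder=placeholder)


def select_placeholder(
    matrix_builder: Callable[[float], ScoreMatrix],
    candidates: Iterable[float] = DEFAULT_PLACEHOLDER_GRID,
    separation: Callable[[ScoreMatrix], float] | None = None,
) -> float:
    """Pick the placeholder that best separates the term groups.

    Starting from -10 the placeholder is varied over a descending grid;
    each candidate matrix is pushed through PCA and group extraction and
    judged by the mean silhouette width of the resulting labels in the
    PC2/PC3 plane.  Ties resolve toward the candidate closest to -10.
    Returns -10 with a warning when no candidate yields more than one
    group.
    """
    from .multivariate import group_separation  # deferred: avoids import cycle

    grid = [float(c) for c in candidates]
    if not grid:
        raise ValueError("empty candidate grid")
    if any(b >= a for a, b in zip(grid, grid[1:])):
        raise ValueError("candidate grid must be strictly descending")
    judge = separation if separation is not None else group_separation

    best: float | None = None
    best_score = -math.inf
    for cand in grid:
        try:
            matrix = matrix_builder(cand)
        except ValueError:
            continue  # candidate not below the finite minimum: invalid
        score = judge(matrix)
        if score > best_score + 1e-12:
            best, best_score = cand, score
    if best is None or not math.isfinite(best_score):
        import logging

        logging.getLogger(__name__).warning(
            "no placeholder candidate produced more than one group; using %s", grid[0]
        )
        return grid[0]
    return best
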