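"""PCA of the score matrix and extraction of labeled term groups.

The matrix orientation is fixed throughout: rows are GO terms (the
observations of the computation), columns are datasets (the variables).
Each column is standardized to mean 0 and unit sample variance, the
principal axes come from the SVD of the standardized matrix, and the
eigenvalues of the sample covariance (divisor N-1) follow from the
singular values.  The first component tracks term specificity — the
number of ancestors a term has dominates the shared variation across
datasets — so group labels are read from the remaining components: a
term joins the group of every dataset whose loading direction it aligns
with (cosine similarity above a threshold), restricted to terms whose
projection is large enough to be meaningful.

The estimators follow scikit-learn conventions (``fit``, ``transform``,
``get_params``/``set_params``, trailing-underscore fitted attributes)
and compose with sklearn pipelines; the module-level functions are thin
wrappers over them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import silhouette_score

from .scoring import ScoreMatrix

UNASSIGNED = "unassigned"


@dataclass
class PCAModel:
    """Fitted PCA of a standardized term x dataset matrix.

    ``loadings`` holds one unit eigenvector per column (dataset x
    component), ``eigenvalues`` the descending variances of the sample
    covariance, and ``scores`` the term coordinates (standardized matrix
    times loadings).
    """

    loadings: pd.DataFrame  # dataset x component
    eigenvalues: np.ndarray  # descending, length = n components
    scores: pd.DataFrame  # term x component
    column_means: pd.Series
    column_sds: pd.Series
    n_rows: int

    @property
    def components(self) -> list[str]:
        return list(self.loadings.columns)

    @property
    def rank(self) -> int:
        return int(np.sum(self.eigenvalues > 1e-12))


@dataclass
class TermGroup:
    """A labeled set of GO terms.

    ``label`` is a tuple of dataset names — one name for a clean group,
    several for a mixed group — or the literal ``"unassigned"``.
    Members are sorted by decreasing score in the label's first dataset.
    """

    label: tuple[str, ...] | str
    members: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return isinstance(self.label, tuple) and len(self.label) == 1

    @property
    def is_mixed(self) -> bool:
        return isinstance(self.label, tuple) and len(self.label) > 1

    @property
    def label_text(self) -> str:
        if isinstance(self.label, str):
            return self.label
        return "+".join(self.label)


class ScorePCA(BaseEstimator, TransformerMixin):
    """Column standardization followed by PCA via SVD.

    Parameters
    ----------
    standardize:
        Standardize columns to mean 0 / sample variance 1 before the
        SVD (the default; raw log2 score columns have very different
        spreads otherwise).

    Attributes
    ----------
    mean_, scale_ : per-column standardization parameters.
    loadings_ : (p x p) array, one unit eigenvector per column, sign
        fixed so each column's largest-magnitude coefficient is positive.
    eigenvalues_ : descending eigenvalues of the sample covariance
        (divisor N-1); components beyond the rank carry 0.
    scores_ : (N x p) PC coordinates of the fitted rows.
    feature_names_in_, n_samples_ : bookkeeping.
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X, y=None):
        X = self._validate(X)
        values = X.to_numpy(dtype=float)
        n, p = values.shape
        if n < 2:
            raise ValueError("PCA needs at least 2 rows")
        if p < 2:
            raise ValueError("PCA needs at least 2 columns")
        mean = values.mean(axis=0)
        if self.standardize:
            sd = values.std(axis=0, ddof=1)
            dead = np.flatnonzero(sd == 0)
            if dead.size:
                raise ValueError(
                    f"zero-variance column(s): {[X.columns[i] for i in dead]}"
                )
        else:
            sd = np.ones(p)
        Z = (values - mean) / sd

        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        eigenvalues = s**2 / (n - 1)
        loadings = vt.T  # p x k, k = min(n, p) = p here
        # reproducible sign convention: largest |coefficient| positive
        for k in range(loadings.shape[1]):
            col = loadings[:, k]
            if col[np.argmax(np.abs(col))] < 0:
                loadings[:, k] = -col
        scores = Z @ loadings

        comp_names = [f"PC{k + 1}" for k in range(loadings.shape[1])]
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_samples_ = n
        self.mean_ = pd.Series(mean, index=X.columns)
        self.scale_ = pd.Series(sd, index=X.columns)
        self.loadings_ = pd.DataFrame(loadings, index=X.columns, columns=comp_names)
        self.eigenvalues_ = eigenvalues
        self.scores_ = pd.DataFrame(scores, index=X.index, columns=comp_names)
        return self

    def transform(self, X):
        X = self._validate(X)
        Z = (X.to_numpy(dtype=float) - self.mean_.to_numpy()) / self.scale_.to_numpy()
        return pd.DataFrame(
            Z @ self.loadings_.to_numpy(), index=X.index, columns=self.loadings_.columns
        )

    def to_model(self) -> PCAModel:
        return PCAModel(
            loadings=self.loadings_,
            eigenvalues=self.eigenvalues_,
            scores=self.scores_,
            column_means=self.mean_,
            column_sds=self.scale_,
            n_rows=self.n_samples_,
        )

    @staticmethod
    def _validate(X) -> pd.DataFrame:
        if isinstance(X, ScoreMatrix):
            X = X.values
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if not np.isfinite(X.to_numpy(dtype=float)).all():
            raise ValueError("non-finite values in score matrix")
        return X


class TermGroupExtractor(BaseEstimator):
    """Label terms by the dataset loading direction they align with.

    Works in the subspace of the selected components (PC1 excluded by
    default, since it encodes term specificity rather than dataset
    identity).  A term whose projected magnitude falls below the given
    quantile of all magnitudes stays unassigned; otherwise it receives
    every dataset label whose loading arrow has cosine similarity at or
    above ``cosine_threshold`` with the term's vector.  Loading arrows
    are taken in bi-plot display scaling (coefficients times the square
    root of each component's eigenvalue): that is the geometry in which
    term points visually accumulate along a dataset's arrow, since score
    coordinates spread with the component's standard deviation.  One
    label makes a clean group, several a mixed group, none leaves the
    term unassigned.

    ``method="kmeans"`` clusters the restricted PC coordinates instead
    (k-means with one center per dataset, labeled by the nearest loading
    direction); provided for comparison, the cosine rule is the default.
    """

    def __init__(
        self,
        cosine_threshold: float = 0.8,
        magnitude_quantile: float = 0.5,
        components: Sequence[int] | None = None,
        method: str = "cosine",
        random_state: int = 0,
    ):
        self.cosine_threshold = cosine_threshold
        self.magnitude_quantile = magnitude_quantile
        self.components = components
        self.method = method
        self.random_state = random_state

    def fit(self, model: PCAModel, matrix: ScoreMatrix | None = None):
        if not 0 < self.cosine_threshold <= 1:
            raise ValueError("cosine_threshold must lie in (0, 1]")
        if not 0 < self.magnitude_quantile <= 1:
            raise ValueError("magnitude_quantile must lie in (0, 1]")
        p = len(model.components)
        comps = (
            list(range(2, p + 1)) if self.components is None else sorted(self.components)
        )
        if any(c < 1 or c > p for c in comps):
            raise ValueError(f"components {comps} outside model rank {p}")
        if not comps:
            raise ValueError("no components selected")
        idx = [c - 1 for c in comps]

        S = model.scores.to_numpy()[:, idx]  # term vectors, restricted
        # loading arrows in bi-plot scaling: coefficient * sqrt(eigenvalue)
        lam = np.sqrt(np.maximum(np.asarray(model.eigenvalues)[idx], 0.0))
        L = model.loadings.to_numpy()[:, idx] * lam[np.newaxis, :]
        datasets = list(model.loadings.index)

        magnitudes = np.linalg.norm(S, axis=1)
        cutoff = float(np.quantile(magnitudes, self.magnitude_quantile))
        l_norm = np.linalg.norm(L, axis=1)

        labels: dict[str, tuple[str, ...] | str] = {}
        if self.method == "cosine":
            for t, term in enumerate(model.scores.index):
                v = S[t]
                mag = magnitudes[t]
                if mag < cutoff or mag == 0:
                    labels[term] = UNASSIGNED
                    continue
                hits = []
                for d, ds in enumerate(datasets):
                    if l_norm[d] == 0:
                        continue
                    cos = float(v @ L[d] / (mag * l_norm[d]))
                    if cos >= self.cosine_threshold:
                        hits.append(ds)
                labels[term] = tuple(sorted(hits)) if hits else UNASSIGNED
        elif self.method == "kmeans":
            from sklearn.cluster import KMeans

            keep = magnitudes >= cutoff
            keep &= magnitudes > 0
            kept_idx = np.flatnonzero(keep)
            for term in model.scores.index[~keep]:
                labels[term] = UNASSIGNED
            if kept_idx.size:
                km = KMeans(
                    n_clusters=min(len(datasets), kept_idx.size),
                    n_init=10,
                    random_state=self.random_state,
                ).fit(S[kept_idx])
                centers = km.cluster_centers_
                for row, t in enumerate(kept_idx):
                    c = centers[km.labels_[row]]
                    cn = np.linalg.norm(c)
                    if cn == 0:
                        labels[model.scores.index[t]] = UNASSIGNED
                        continue
                    cos = (L @ c) / (np.where(l_norm == 0, 1, l_norm) * cn)
                    d = int(np.argmax(cos))
                    labels[model.scores.index[t]] = (datasets[d],)
        else:
            raise ValueError(f"unknown method {self.method!r}")

        self.components_ = comps
        self.magnitude_cutoff_ = cutoff
        self.labels_ = labels
        self.groups_ = _collect_groups(labels, matrix)
        return self

    def fit_predict(self, model: PCAModel, matrix: ScoreMatrix | None = None):
        return self.fit(model, matrix).labels_


def _collect_groups(
    labels: Mapping[str, tuple[str, ...] | str], matrix: ScoreMatrix | None
) -> list[TermGroup]:
    by_label: dict[tuple[str, ...] | str, list[str]] = {}
    for term, label in labels.items():
        by_label.setdefault(label, []).append(term)

    def sort_key(label):
        # clean groups first, then mixed (by size then name), unassigned last
        if label == UNASSIGNED:
            return (2, 0, "")
        return (0 if len(label) == 1 else 1, len(label), "+".join(label))

    groups: list[TermGroup] = []
    for label in sorted(by_label, key=sort_key):
        members = by_label[label]
        if isinstance(label, tuple) and matrix is not None:
            first = label[0]
            members = sorted(members, key=lambda t: (-matrix.values.at[t, first], t))
        else:
            members = sorted(members)
        groups.append(TermGroup(label=label, members=members))
    return groups


# ---------------------------------------------------------------------------
# functional surface


def standardize(matrix: ScoreMatrix) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Standardize columns to mean 0 / sample variance 1 (divisor N-1)."""
    values = matrix.values.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance column(s): {[matrix.values.columns[i] for i in dead]}"
        )
    Z = pd.DataFrame(
        (values - mean) / sd, index=matrix.values.index, columns=matrix.values.columns
    )
    return Z, pd.Series(mean, index=Z.columns), pd.Series(sd, index=Z.columns)


def pca(matrix: ScoreMatrix, standardize: bool = True) -> PCAModel:
    """Standardized PCA of the score matrix (see :class:`ScorePCA`)."""
    return ScorePCA(standardize=standardize).fit(matrix).to_model()


def contribution_table(model: PCAModel, weighted: bool = False) -> pd.DataFrame:
    """Per-dataset percentage association with each principal component.

    The default entry (f, k) is the squared loading coefficient,
    100 * a_fk^2.  Because the eigenvector matrix is orthogonal the
    table is doubly stochastic: every row *and* every column sums to
    100, the structure the fraction-by-component correlation tables of
    fractionation studies exhibit.

    ``weighted=True`` instead reports the eigenvalue-weighted share
    100 * a_fk^2 λ_k / Σ_j a_fj^2 λ_j — the squared correlation between
    variable f and PC k for standardized input (rows sum to 100,
    columns do not).
    """
    A2 = model.loadings.to_numpy() ** 2
    if weighted:
        lam = np.asarray(model.eigenvalues)
        A2 = A2 * lam[np.newaxis, :]
    table = 100.0 * A2 / A2.sum(axis=1, keepdims=True)
    return pd.DataFrame(table, index=model.loadings.index, columns=model.loadings.columns)


def extract_groups(
    model: PCAModel,
    matrix: ScoreMatrix,
    cosine_threshold: float = 0.8,
    magnitude_quantile: float = 0.5,
    components: Sequence[int] | None = None,
    method: str = "cosine",
) -> list[TermGroup]:
    """Label terms by loading alignment (see :class:`TermGroupExtractor`)."""
    extractor = TermGroupExtractor(
        cosine_threshold=cosine_threshold,
        magnitude_quantile=magnitude_quantile,
        components=components,
        method=method,
    )
    return extractor.fit(model, matrix).groups_


def count_groups(groups: Iterable[TermGroup]) -> pd.DataFrame:
    """Tally of members per group label (clean, then mixed, then unassigned)."""
    rows = [(g.label_text, len(g.members)) for g in groups]
    return pd.DataFrame(rows, columns=["label", "n_terms"])


def paper_group_bound(k: int, convention: str = "ordered") -> int:
    """Number of possible group categories for ``k`` datasets.

    ``ordered``: ordered pairs of distinct datasets, k(k-1) — the
    permutation count quoted for four fractions (12).  ``unordered``:
    clean labels plus unordered pairs, k + k(k-1)/2 — the label set the
    cosine rule can actually emit when mixing is limited to pairs.
    """
    if k < 2:
        raise ValueError("need at least 2 datasets")
    if convention == "ordered":
        return k * (k - 1)
    if convention == "unordered":
        return k + k * (k - 1) // 2
    raise ValueError(f"unknown convention {convention!r}")


def biplot_data(model: PCAModel, i: int = 1, j: int = 2) -> pd.DataFrame:
    """Bi-plot coordinates: term scores plus √λ-scaled dataset loadings."""
    p = len(model.components)
    if i == j:
        raise ValueError("components must differ")
    if not (1 <= i <= p and 1 <= j <= p):
        raise ValueError(f"components ({i}, {j}) out of range 1..{p}")
    ci, cj = f"PC{i}", f"PC{j}"
    rows = []
    for term in model.scores.index:
        rows.append((term, "score", model.scores.at[term, ci], model.scores.at[term, cj]))
    lam = np.asarray(model.eigenvalues)
    for ds in model.loadings.index:
        rows.append(
            (
                ds,
                "loading",
                model.loadings.at[ds, ci] * math.sqrt(lam[i - 1]),
                model.loadings.at[ds, cj] * math.sqrt(lam[j - 1]),
            )
        )
    return pd.DataFrame(rows, columns=["point", "kind", f"coord_{ci}", f"coord_{cj}"])


def group_separation(matrix: ScoreMatrix) -> float:
    """Mean silhouette width of the group labels in the PC2/PC3 plane.

    The criterion behind the placeholder grid search: larger is better
    separated.  Returns -inf when fewer than two groups emerge.
    """
    try:
        model = pca(matrix)
    except ValueError:
        return -math.inf
    p = len(model.components)
    comps = [c for c in (2, 3) if c <= p]
    if len(comps) < 2:
        comps = [1, 2][: p]
    extractor = TermGroupExtractor(components=comps if len(comps) >= 1 else None)
    try:
        labels = extractor.fit_predict(model, matrix)
    except ValueError:
        return -math.inf
    assigned = {t: lab for t, lab in labels.items() if lab != UNASSIGNED}
    label_set = set(assigned.values())
    if len(label_set) < 2 or len(assigned) <= len(label_set):
        return -math.inf
    coords = model.scores.loc[list(assigned), [f"PC{c}" for c in comps]].to_numpy()
    y = np.asarray(["+".join(lab) for lab in assigned.values()])
    return float(silhouette_score(coords, y))
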