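"""Standardized PCA, contribution tables, and term-group extraction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.decomposition import PCA as SkPCA

from termscape.multivariate import (
    PCAModel,
    ScorePCA,
    TermGroup,
    TermGroupExtractor,
    biplot_data,
    contribution_table,
    count_groups,
    extract_groups,
    paper_group_bound,
    pca,
    standardize,
)
from termscape.scoring import ScoreMatrix


def as_matrix(values: pd.DataFrame) -> ScoreMatrix:
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return ScoreMatrix(values=values, mask=mask, placeholder=-10.0)


def random_matrix(seed, n=20, p=4):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"T{i}" for i in range(n)],
        columns=[f"ds{j}" for j in range(p)],
    )
    return as_matrix(values)


def test_standardize_symmetric_column():
    m = as_matrix(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 4.0]}))
    Z, mean, sd = standardize(m)
    assert np.allclose(Z["a"], [-1, 0, 1])
    assert np.allclose(Z.mean(), 0, atol=1e-12)
    assert np.allclose(Z.var(ddof=1), 1, atol=1e-12)


def test_standardize_matches_two_pass_oracle():
    m = random_matrix(7, n=6, p=3)
    Z, mean, sd = standardize(m)
    v = m.values.to_numpy()
    exp_mean = v.sum(axis=0) / 6
    exp_sd = np.sqrt(((v - exp_mean) ** 2).sum(axis=0) / 5)
    assert np.allclose(mean, exp_mean)
    assert np.allclose(sd, exp_sd)
    assert np.allclose(Z, (v - exp_mean) / exp_sd)


def test_zero_variance_column_named_in_error():
    m = as_matrix(pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]}))
    with pytest.raises(ValueError, match="flat"):
        standardize(m)
    with pytest.raises(ValueError, match="flat"):
        pca(m)


def test_identical_columns_give_rank_one_spectrum():
    col = [1.0, 2.0, 4.0, 0.0]
    model = pca(as_matrix(pd.DataFrame({"a": col, "b": col})))
    assert np.allclose(model.eigenvalues, [2.0, 0.0], atol=1e-12)
    assert np.allclose(model.loadings["PC1"], [1, 1] / np.sqrt(2))


def test_uncorrelated_columns_give_isotropic_spectrum():
    # orthogonal construction: exactly zero sample correlation
    a = np.array([1.0, -1.0, 1.0, -1.0])
    b = np.array([1.0, 1.0, -1.0, -1.0])
    model = pca(as_matrix(pd.DataFrame({"a": a, "b": b})))
    assert np.allclose(model.eigenvalues, [1.0, 1.0], atol=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_pca_matches_covariance_eigendecomposition(seed):
    m = random_matrix(seed)
    model = pca(m)
    Z, _, _ = standardize(m)
    S = Z.to_numpy().T @ Z.to_numpy() / (len(Z) - 1)
    lam, vec = np.linalg.eigh(S)
    lam, vec = lam[::-1], vec[:, ::-1]
    assert np.allclose(model.eigenvalues, lam, atol=1e-8)
    for k in range(vec.shape[1]):
        v = vec[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        assert np.allclose(model.loadings.iloc[:, k], v, atol=1e-8)


def test_pca_agrees_with_sklearn_spectrum():
    m = random_matrix(11)
    model = pca(m)
    Z, _, _ = standardize(m)
    sk = SkPCA().fit(Z.to_numpy())
    assert np.allclose(model.eigenvalues, sk.explained_variance_, atol=1e-8)


def test_reconstruction_at_full_rank():
    m = random_matrix(3)
    model = pca(m)
    Z, _, _ = standardize(m)
    back = model.scores.to_numpy() @ model.loadings.to_numpy().T
    assert np.allclose(back, Z.to_numpy(), atol=1e-8)


def test_scorepca_sklearn_api():
    est = ScorePCA()
    assert est.get_params() == {"standardize": True}
    est2 = clone(est).set_params(standardize=False)
    assert est2.get_params()["standardize"] is False
    m = random_matrix(5)
    fitted = est.fit(m)
    assert np.allclose(fitted.transform(m.values), fitted.scores_, atol=1e-12)
    with pytest.raises(ValueError):
        ScorePCA().fit(m.values.iloc[:1])


def test_contribution_rank_one_concentrates_on_pc1():
    # a rank-1 matrix puts all of each variable's variance on PC1: the
    # squared-correlation (weighted) table reads 100% per row there,
    # while the squared-loading table splits the unit coefficient mass
    col = [1.0, 2.0, 4.0, 0.0]
    model = pca(as_matrix(pd.DataFrame({"a": col, "b": col})))
    weighted = contribution_table(model, weighted=True)
    assert np.allclose(weighted["PC1"], 100.0, atol=1e-9)
    table = contribution_table(model)
    assert np.allclose(table.sum(axis=1), 100.0, atol=1e-9)


@pytest.mark.parametrize("seed", range(3))
def test_contribution_table_is_doubly_stochastic(seed):
    table = contribution_table(pca(random_matrix(seed)))
    assert np.allclose(table.sum(axis=1), 100.0, atol=0.1)
    assert np.allclose(table.sum(axis=0), 100.0, atol=0.1)


@pytest.mark.parametrize("seed", range(3))
def test_weighted_contribution_matches_correlation_oracle(seed):
    m = random_matrix(seed)
    model = pca(m)
    table = contribution_table(model, weighted=True)
    Z, _, _ = standardize(m)
    for f in Z.columns:
        for k, comp in enumerate(model.components):
            scores = model.scores[comp]
            if model.eigenvalues[k] < 1e-12:
                continue
            r = np.corrcoef(Z[f], scores)[0, 1]
            assert table.at[f, comp] == pytest.approx(100 * r**2, abs=1e-6)
    assert np.allclose(table.sum(axis=1), 100.0, atol=0.1)


def _toy_model(loadings, eigenvalues, scores, terms):
    p = loadings.shape[0]
    cols = [f"PC{k + 1}" for k in range(loadings.shape[1])]
    datasets = [f"ds{j}" for j in range(p)]
    return PCAModel(
        loadings=pd.DataFrame(loadings, index=datasets, columns=cols),
        eigenvalues=np.asarray(eigenvalues, dtype=float),
        scores=pd.DataFrame(scores, index=terms, columns=cols),
        column_means=pd.Series(0.0, index=datasets),
        column_sds=pd.Series(1.0, index=datasets),
        n_rows=len(terms),
    )


def test_term_along_loading_direction_forms_clean_group():
    # two components of equal spread; ds0 along PC1, ds1 along PC2
    loadings = np.array([[1.0, 0.0], [0.0, 1.0]])
    scores = np.array([[3.0, 0.0], [0.0, 3.0], [0.1, 0.0], [0.0, 0.1]])
    model = _toy_model(loadings, [1.0, 1.0], scores, ["t0", "t1", "t2", "t3"])
    labels = TermGroupExtractor(components=[1, 2]).fit_predict(model)
    assert labels["t0"] == ("ds0",)
    assert labels["t1"] == ("ds1",)
    assert labels["t2"] == "unassigned"  # below the magnitude quantile


def test_term_bisecting_two_loadings_gets_mixed_label():
    # loading directions 30 degrees apart; the bisector is within
    # acos(0.8) of both, a distant direction is within neither
    a1, a2 = 0.0, np.pi / 6
    loadings = np.array([[np.cos(a1), np.sin(a1)], [np.cos(a2), np.sin(a2)]])
    bisector = (a1 + a2) / 2
    scores = np.array(
        [
            [3 * np.cos(bisector), 3 * np.sin(bisector)],
            [3 * np.cos(bisector + np.pi / 2), 3 * np.sin(bisector + np.pi / 2)],
        ]
    )
    model = _toy_model(loadings, [1.0, 1.0], scores, ["mix", "far"])
    labels = TermGroupExtractor(components=[1, 2], magnitude_quantile=0.5).fit_predict(model)
    assert labels["mix"] == ("ds0", "ds1")
    assert labels["far"] == "unassigned"


def test_extract_groups_invariant_to_row_permutation(default_run):
    *_, result = default_run
    model, matrix = result.model, result.matrix
    groups = extract_groups(model, matrix)
    perm = np.random.default_rng(0).permutation(len(matrix.values))
    shuffled = ScoreMatrix(
        values=matrix.values.iloc[perm], mask=matrix.mask.iloc[perm], placeholder=matrix.placeholder
    )
    model2 = PCAModel(
        loadings=model.loadings,
        eigenvalues=model.eigenvalues,
        scores=model.scores.iloc[perm],
        column_means=model.column_means,
        column_sds=model.column_sds,
        n_rows=model.n_rows,
    )
    groups2 = extract_groups(model2, shuffled)
    assert {g.label_text: g.members for g in groups} == {
        g.label_text: g.members for g in groups2
    }


def test_components_outside_rank_rejected(default_run):
    *_, result = default_run
    with pytest.raises(ValueError):
        extract_groups(result.model, result.matrix, components=[5])


def test_count_groups_orders_and_tallies():
    groups = [
        TermGroup(label="unassigned", members=["u1", "u2"]),
        TermGroup(label=("b", "c"), members=["m1", "m2", "m3"]),
        TermGroup(label=("a",), members=["c1", "c2", "c3", "c4"]),
    ]
    table = count_groups(sorted(groups, key=lambda g: g.label_text))
    assert list(table.itertuples(index=False, name=None)) == [
        ("a", 4),
        ("b+c", 3),
        ("unassigned", 2),
    ]
    assert count_groups([]).empty


def test_group_bound_conventions():
    assert paper_group_bound(4, "ordered") == 12
    assert paper_group_bound(4, "unordered") == 10
    assert paper_group_bound(2, "ordered") == 2
    with pytest.raises(ValueError):
        paper_group_bound(1, "ordered")
    with pytest.raises(ValueError):
        paper_group_bound(4, "circular")


def test_biplot_rows_and_scaled_loadings():
    m = random_matrix(2)
    model = pca(m)
    data = biplot_data(model, 1, 2)
    loadings = data[data["kind"] == "loading"]
    assert len(loadings) == 4
    scores = data[data["kind"] == "score"]
    assert np.allclose(scores["coord_PC1"], model.scores["PC1"])
    lengths = np.hypot(loadings["coord_PC1"], loadings["coord_PC2"])
    expected = np.hypot(
        model.loadings["PC1"] * np.sqrt(model.eigenvalues[0]),
        model.loadings["PC2"] * np.sqrt(model.eigenvalues[1]),
    )
    assert np.allclose(sorted(lengths), sorted(expected), atol=1e-10)
    with pytest.raises(ValueError):
        biplot_data(model, 1, 1)
    with pytest.raises(ValueError):
        biplot_data(model, 1, 9)
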