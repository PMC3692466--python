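"""Spearman, correlation grids, PCA, Kruskal-Wallis."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mtsprofile.stats import (
    correlation_matrix,
    kruskal_wallis,
    pca,
    sig_class_of,
    spearman,
)


def _rank_formula_rho(x, y):
    """Independent oracle: 1 - 6*sum(d^2)/(n(n^2-1)), tie-free ranks."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    return 1.0 - 6.0 * float(((rx - ry) ** 2).sum()) / (n * (n**2 - 1))


def test_spearman_monotone_is_plus_minus_one():
    assert spearman([1, 2, 3, 4], [2, 4, 6, 8], min_n=4).rho == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [8, 6, 4, 2], min_n=4).rho == pytest.approx(-1.0)


@pytest.mark.parametrize(
    "x, y",
    [
        ([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]),
        ([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5]),
        ([3, 1, 4, 1.5, 5, 9, 2.6], [2, 7, 1, 8, 2.8, 1.7, 9]),
    ],
)
def test_spearman_matches_rank_formula_on_tie_free_data(x, y):
    cell = spearman(x, y)
    assert cell.rho == pytest.approx(_rank_formula_rho(x, y), abs=1e-12)


def test_spearman_worked_example_value():
    # ranks differ by (0,1,1,1,1): sum d^2 = 4 -> rho = 1 - 24/120 = 0.8
    assert spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]).rho == pytest.approx(0.8)


def test_spearman_p_matches_t_approximation():
    import scipy.stats

    x = [1, 2, 3, 4, 5, 6, 7, 8]
    y = [2, 1, 4, 3, 6, 5, 8, 7]
    cell = spearman(x, y)
    t = cell.rho * math.sqrt((cell.n - 2) / (1 - cell.rho**2))
    assert cell.p == pytest.approx(2 * scipy.stats.t.sf(abs(t), cell.n - 2), rel=1e-6)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.integers(-10**6, 10**6), min_size=5, max_size=30, unique=True),
    st.data(),
)
def test_spearman_symmetry_and_monotone_invariance(x, data):
    y = data.draw(st.permutations(x))
    a = spearman(x, y)
    assert spearman(y, x).rho == pytest.approx(a.rho, abs=1e-12)
    # strictly monotone transform of either margin leaves rho unchanged
    fx = [3.0 * v + 7.0 for v in x]
    gy = [math.atan(v / 1e6) for v in y]
    if a.computed:
        assert spearman(fx, gy).rho == pytest.approx(a.rho, abs=1e-9)


def test_spearman_missing_pairs_dropped_and_min_n():
    x = [1, 2, 3, 4, np.nan, 6]
    y = [2, 4, 6, 8, 10, np.nan]
    cell = spearman(x, y, min_n=4)
    assert cell.n == 4 and cell.rho == pytest.approx(1.0)
    assert not spearman([1, 2, 3], [3, 2, 1], min_n=5).computed
    assert not spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5]).computed


def test_spearman_exact_permutation_small_n():
    cell = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], method="exact")
    # only identity and full reversal reach |rho| = 1: p = 2/5!
    assert cell.p == pytest.approx(2 / 120)
    mid = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], method="exact")
    approx = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
    assert 0 < mid.p < 1 and abs(mid.p - approx.p) < 0.15
    with pytest.raises(ValueError, match="n <= 10"):
        spearman(list(range(12)), list(range(12)), method="exact")


def test_sig_classes():
    assert sig_class_of(0.005) == "p<0.01"
    assert sig_class_of(0.03) == "p<0.05"
    assert sig_class_of(0.2) == "none"


def test_correlation_matrix_cells_and_bh():
    rng = np.random.default_rng(0)
    n = 40
    base = rng.normal(size=n)
    mts = pd.DataFrame(
        {"length": base + 0.3 * rng.normal(size=n), "frac_b": rng.normal(size=n)},
        index=[f"r{i}" for i in range(n)],
    )
    mature = pd.DataFrame(
        {"frac_d": base + 0.3 * rng.normal(size=n), "const": np.ones(n)},
        index=[f"r{i}" for i in range(n)],
    )
    m = correlation_matrix(mts, mature, grouping="pooled")
    strong = m.cell("length", "frac_d")
    assert strong.computed and strong.p < 0.01 and strong.sig_class == "p<0.01"
    assert not m.cell("length", "const").computed  # zero variance never aborts
    long = m.to_long_frame()
    assert set(long.columns) >= {"mts_variable", "mature_variable", "rho", "p", "n", "sig_class", "q_bh"}
    # BH q-values attached but sig_class still derives from the raw p
    assert long.loc[long.p.notna(), "q_bh"].notna().all()
    assert (long.loc[long.p.notna()].apply(lambda r: sig_class_of(r.p) == r.sig_class, axis=1)).all()


def test_pca_rank_one_two_variables():
    rng = np.random.default_rng(1)
    x = rng.normal(size=30)
    table = pd.DataFrame({"u": x, "v": 2.0 * x + 1.0})
    res = pca(table)
    assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-9)
    assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-6)
    assert res.retained == 1


def test_pca_isotropic_variables_share_variance():
    rng = np.random.default_rng(2)
    table = pd.DataFrame(rng.normal(size=(3000, 4)), columns=list("wxyz"))
    res = pca(table)
    assert np.allclose(res.percent_variance, 25.0, atol=5.0)


def test_pca_eigenvalues_match_characteristic_polynomial_oracle():
    rng = np.random.default_rng(3)
    data = pd.DataFrame(rng.normal(size=(50, 3)) @ rng.normal(size=(3, 3)), columns=list("abc"))
    c = np.corrcoef(data.to_numpy(), rowvar=False)
    # cubic det(C - xI) coefficients written out by cofactor expansion
    m01, m02, m12 = c[0, 1], c[0, 2], c[1, 2]
    det = 1 + 2 * m01 * m02 * m12 - m01**2 - m02**2 - m12**2
    minors = 3 - m01**2 - m02**2 - m12**2
    roots = np.sort(np.roots([-1.0, 3.0, -minors, det]))[::-1]
    res = pca(data)
    assert np.allclose(res.eigenvalues, roots.real, atol=1e-9)


def test_pca_matches_sklearn_variance_ratio(synth):
    from sklearn.decomposition import PCA as SkPCA

    dataset, _ = synth
    from mtsprofile.pipeline import properties_table

    table = properties_table(dataset, "mts").iloc[:, :6]
    res = pca(table)
    z = (table - table.mean()) / table.std(ddof=1)
    ratio = SkPCA(n_components=6).fit(z.to_numpy()).explained_variance_ratio_
    assert np.allclose(res.percent_variance / 100.0, ratio, atol=1e-8)


def test_pca_eigen_sum_equals_nonconstant_variable_count():
    rng = np.random.default_rng(4)
    table = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
    table["const"] = 3.14
    res = pca(table)
    assert res.dropped_columns == ["const"]
    assert res.eigenvalues.sum() == pytest.approx(5.0, abs=1e-9)
    assert res.cumulative_percent[-1] == pytest.approx(100.0, abs=1e-6)
    assert res.loadings.shape == (5, 5)


def test_pca_fixed_retention_and_errors():
    rng = np.random.default_rng(5)
    table = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
    assert pca(table, retention=2).retained == 2
    with pytest.raises(ValueError):
        pca(table.iloc[:1])
    with pytest.raises(ValueError):
        pca(table, retention=7)


def test_kruskal_wallis_hand_formula():
    # ranks 1..6, R1=6, R2=15: H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 27/7
    h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
    assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, abs=1e-12)
    assert h == pytest.approx(3.857, abs=1e-3) and df == 1


def test_kruskal_wallis_null_and_degenerate_cases():
    h, df, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
    assert h < 1.0
    h0, df0, p0 = kruskal_wallis([[5, 5], [5, 5, 5]])
    assert (h0, p0) == (0.0, 1.0)
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2], []])
    with pytest.raises(ValueError):
        kruskal_wallis([[1], [2]])
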