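"""Statistical layer: rank correlation, correlation matrices, PCA, Kruskal–Wallis.

Spearman's rho is the product-moment correlation of mid-ranks with a
two-tailed p from the t approximation t = rho*sqrt((n-2)/(1-rho^2)) on
n-2 degrees of freedom (the behaviour of general statistics packages in
the n = 35..85 range this pipeline targets); an exact permutation p is
available for small n.  PCA operates on the sample correlation matrix
(variables standardized), reports percent variance per component and
retains components under the Kaiser rule (eigenvalue strictly > 1) by
default.  No multiple-testing correction alters significance classes;
Benjamini–Hochberg q-values are emitted alongside for transparency.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationCell",
    "CorrelationMatrix",
    "PCAResult",
    "spearman",
    "correlation_matrix",
    "pca",
    "kruskal_wallis",
    "sig_class_of",
]


def sig_class_of(p: float) -> str:
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "none"


@dataclass(frozen=True)
class CorrelationCell:
    rho: float
    p: float
    n: int
    sig_class: str
    computed: bool = True

    @classmethod
    def not_computed(cls, n: int) -> "CorrelationCell":
        return cls(rho=math.nan, p=math.nan, n=n, sig_class="none", computed=False)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-tailed exact p by full enumeration of rank permutations (n <= 10)."""
    n = len(x)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    observed = abs(float(rx @ ry) / n)
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []
    perms = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perms, 100_000))
        if not chunk:
            break
        idx = np.array(chunk)
        stats = np.abs(ry[idx] @ rx) / n
        count += int((stats >= observed - 1e-12).sum())
        total += len(chunk)
    return count / total


def spearman(
    x,
    y,
    min_n: int = 5,
    method: str = "t",
) -> CorrelationCell:
    """Spearman rank correlation with a two-tailed p-value.

    Pairs with a missing value in either variable are dropped pairwise.
    Cells with fewer than *min_n* pairs, or zero variance in either
    variable, are returned as not-computed rather than raising.
    ``method="exact"`` enumerates all rank permutations (n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < min_n or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationCell.not_computed(n)
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p limited to n <= 10")
        rho = float(scipy.stats.spearmanr(x, y).statistic)
        p = _exact_permutation_p(x, y)
    elif method == "t":
        res = scipy.stats.spearmanr(x, y)
        rho, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationCell(rho=rho, p=p, n=n, sig_class=sig_class_of(p))


@dataclass
class CorrelationMatrix:
    """Grid of Spearman cells: MTS variables (rows) x mature variables (cols)."""

    row_labels: list[str]
    col_labels: list[str]
    cells: dict[tuple[str, str], CorrelationCell]
    grouping: str = "pooled"
    q_bh: dict[tuple[str, str], float] = field(default_factory=dict)

    def cell(self, row: str, col: str) -> CorrelationCell:
        return self.cells[(row, col)]

    def rho_frame(self) -> pd.DataFrame:
        return self._frame("rho")

    def p_frame(self) -> pd.DataFrame:
        return self._frame("p")

    def _frame(self, attr: str) -> pd.DataFrame:
        data = [
            [getattr(self.cells[(r, c)], attr) for c in self.col_labels]
            for r in self.row_labels
        ]
        return pd.DataFrame(data, index=self.row_labels, columns=self.col_labels)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.row_labels:
            for c in self.col_labels:
                cell = self.cells[(r, c)]
                rows.append(
                    {
                        "mts_variable": r,
                        "mature_variable": c,
                        "rho": cell.rho,
                        "p": cell.p,
                        "n": cell.n,
                        "sig_class": cell.sig_class,
                        "q_bh": self.q_bh.get((r, c), math.nan),
                        "grouping": self.grouping,
                    }
                )
        return pd.DataFrame(rows)


def correlation_matrix(
    mts_props: pd.DataFrame,
    mature_props: pd.DataFrame,
    grouping: str = "pooled",
    min_n: int = 5,
) -> CorrelationMatrix:
    """Pairwise Spearman grid between two property tables aligned on index.

    A cell failure (too few pairs, constant variable) marks that cell as
    not-computed; it never aborts the whole matrix.  BH q-values over the
    computed cells are attached but never change ``sig_class``.
    """
    common = mts_props.index.intersection(mature_props.index)
    a = mts_props.loc[common]
    b = mature_props.loc[common]
    cells: dict[tuple[str, str], CorrelationCell] = {}
    for r in a.columns:
        for c in b.columns:
            cells[(r, c)] = spearman(a[r].to_numpy(), b[c].to_numpy(), min_n=min_n)
    matrix = CorrelationMatrix(
        row_labels=list(a.columns),
        col_labels=list(b.columns),
        cells=cells,
        grouping=grouping,
    )
    keys = [k for k, cell in cells.items() if cell.computed]
    if keys:
        _, q, _, _ = multipletests([cells[k].p for k in keys], method="fdr_bh")
        matrix.q_bh = dict(zip(keys, (float(v) for v in q)))
    return matrix


@dataclass
class PCAResult:
    """Eigendecomposition summary of a standardized property table."""

    eigenvalues: np.ndarray  # descending
    percent_variance: np.ndarray
    cumulative_percent: np.ndarray
    loadings: pd.DataFrame  # variable x component, eigvec * sqrt(eigval)
    retained: int
    dropped_columns: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        comps = [f"PC{i + 1}" for i in range(len(self.eigenvalues))]
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "percent_variance": self.percent_variance,
                "cumulative_percent": self.cumulative_percent,
            },
            index=pd.Index(comps, name="component"),
        )


def pca(props: pd.DataFrame, retention: str | int = "kaiser") -> PCAResult:
    """PCA of the sample correlation matrix of *props*.

    Columns are standardized (so the decomposition is of the correlation
    matrix); constant columns are dropped with a warning entry.  Percent
    variance per component is eigenvalue / n_variables * 100.  Retention:
    ``"kaiser"`` keeps eigenvalues strictly greater than 1; an integer
    keeps a fixed count.
    """
    data = props.dropna(axis=0, how="any")
    if len(data) < 2:
        raise ValueError("need at least 2 complete rows")
    dropped = [c for c in data.columns if np.ptp(data[c].to_numpy(dtype=float)) == 0]
    data = data.drop(columns=dropped)
    if data.shape[1] == 0:
        raise ValueError("no non-constant variables")
    values = data.to_numpy(dtype=float)
    corr = np.corrcoef(values, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # fix sign convention: largest-magnitude element of each component positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1
    p = data.shape[1]
    percent = eigval / p * 100.0
    loadings = pd.DataFrame(
        eigvec * np.sqrt(eigval),
        index=pd.Index(data.columns, name="variable"),
        columns=[f"PC{i + 1}" for i in range(p)],
    )
    if retention == "kaiser":
        retained = int((eigval > 1.0).sum())
    else:
        retained = int(retention)
        if not 1 <= retained <= p:
            raise ValueError(f"fixed retention {retained} out of 1..{p}")
    return PCAResult(
        eigenvalues=eigval,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
        loadings=loadings,
        retained=retained,
        dropped_columns=dropped,
    )


def kruskal_wallis(groups: list) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p (df = groups - 1).

    All values identical across groups is the degenerate null: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 1 for g in arrays):
        raise ValueError("each group needs at least 1 value")
    total = np.concatenate(arrays)
    if len(total) < 3:
        raise ValueError("need at least 3 values in total")
    df = len(arrays) - 1
    if np.ptp(total) == 0:
        return 0.0, df, 1.0
    h, p = scipy.stats.kruskal(*arrays)
    return float(h), df, float(p)
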