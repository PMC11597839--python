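"""Chemometric comparison layer: correlations, simple-regression reports,
hierarchical cluster analysis and principal component analysis.

The layer operates on a wide panel (compounds x variables), e.g. one
lipophilicity estimate per column. Variables are standardised to z-scores
(sample sd, n-1) before distance-based methods; constant columns are
dropped with a warning rather than poisoning the distance matrix. PCA is
the eigendecomposition of the correlation matrix — equivalent to the
covariance of the standardised panel — with component signs fixed by making
each loading vector's largest-magnitude entry positive so results are
reproducible across LAPACK builds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import DegenerateDesignError, InputError

LINKAGES = ("single", "complete", "average", "ward")


def standardize(data: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-scores (sample sd, ddof=1).

    Columns with zero variance are dropped with a warning — a constant
    variable carries no chemometric information and has no z-score.
    Idempotent up to floating error.
    """
    numeric = data.astype(float)
    sds = numeric.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping constant columns (no variance): {constant}", stacklevel=2
        )
        numeric = numeric.drop(columns=constant)
        sds = sds.drop(constant)
    return (numeric - numeric.mean()) / sds


def pearson_matrix(data: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    p-values use the t transform ``t = r sqrt((n-2)/(1-r^2))`` with n-2
    degrees of freedom. Zero-variance columns yield NaN rows/columns (and a
    warning from the underlying correlation).
    """
    numeric = data.astype(float)
    n = len(numeric)
    if n < 3:
        raise InputError(f"need >= 3 rows for correlation, got {n}")
    rmat = numeric.corr(method="pearson")
    with np.errstate(divide="ignore", invalid="ignore"):
        rv = rmat.values.clip(-1.0, 1.0)
        t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    p = np.where(np.isnan(rv), np.nan, p)
    pmat = pd.DataFrame(p, index=rmat.index, columns=rmat.columns)
    return rmat, pmat


@dataclass(frozen=True)
class RegressionReport:
    """Simple-regression report in the conventional table shape:
    coefficient (+/- SE), intercept (+/- SE), r, s, F, p, n."""

    x_name: str
    y_name: str
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r: float
    s: float
    F: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        """Conventional p < 0.05 gate."""
        return self.p < 0.05

    def equation(self, ndigits: int = 3) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return (
            f"{self.y_name} = {self.slope:.{ndigits}f}(±{self.slope_se:.{ndigits}f}) "
            f"{self.x_name} {sign} {abs(self.intercept):.{ndigits}f}"
            f"(±{self.intercept_se:.{ndigits}f})"
        )


def ols_report(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
) -> RegressionReport:
    """Classical simple regression of y on x with the full diagnostic set.

    s is the residual standard error sqrt(SSE/(n-2)); F satisfies
    ``F = (r^2/(1-r^2)) (n-2)``; p is the two-sided slope test (t, n-2 df).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya):
        raise InputError("x and y must have equal length")
    n = len(xa)
    if n < 3:
        raise InputError(f"need >= 3 observations, got {n}")
    if np.ptp(xa) == 0:
        raise DegenerateDesignError(f"regressor {x_name!r} is constant")
    fit = stats.linregress(xa, ya)
    resid = ya - (fit.slope * xa + fit.intercept)
    sse = float(np.sum(resid**2))
    s = float(np.sqrt(sse / (n - 2)))
    r2 = fit.rvalue**2
    F = float((r2 / (1.0 - r2)) * (n - 2)) if r2 < 1.0 else float("inf")
    return RegressionReport(
        x_name=x_name,
        y_name=y_name,
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
        intercept=float(fit.intercept),
        intercept_se=float(fit.intercept_stderr),
        r=float(fit.rvalue),
        s=s,
        F=F,
        p=float(fit.pvalue),
        n=n,
    )


def regression_table(
    data: pd.DataFrame, y_column: str, x_columns: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """One regression report per x column against ``y_column``."""
    xs = [c for c in (x_columns or data.columns) if c != y_column]
    rows = []
    for col in xs:
        rep = ols_report(data[col], data[y_column], x_name=col, y_name=y_column)
        rows.append(
            {
                "x": col,
                "equation": rep.equation(),
                "r": round(rep.r, 3),
                "s": round(rep.s, 3),
                "F": round(rep.F, 1),
                "p": rep.p,
                "significant": rep.significant,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history over Euclidean distances.

    ``merges`` is the (n-1, 4) linkage matrix: indices of the two clusters
    merged (original observations are 0..n-1), the merge height, and the
    size of the new cluster. Heights are non-decreasing for the monotone
    linkages offered here.
    """

    ids: Tuple[str, ...]
    linkage_method: str
    merges: np.ndarray
    leaf_order: Tuple[str, ...]

    def cut(self, n_clusters: int) -> pd.Series:
        """Cluster labels at the cut producing ``n_clusters`` groups."""
        labels = hierarchy.fcluster(self.merges, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=list(self.ids), name="cluster")

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["left", "right", "height", "size"]
        )

    def to_newick(self) -> str:
        """Nested-parenthesis text form with merge heights as labels."""
        n = len(self.ids)
        nodes = {i: self.ids[i] for i in range(n)}
        for k, (left, right, height, _size) in enumerate(self.merges):
            nodes[n + k] = f"({nodes[int(left)]},{nodes[int(right)]}):{height:.4f}"
        return nodes[n + len(self.merges) - 1] + ";"


def hcluster(data: pd.DataFrame, linkage: str = "ward") -> Dendrogram:
    """Agglomerative clustering of rows on Euclidean distance.

    Expects a standardised panel. Rows are sorted by id first so that ties
    break lexicographically regardless of input order.
    """
    if linkage not in LINKAGES:
        raise InputError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if len(data) < 2:
        raise InputError("need >= 2 rows to cluster")
    ordered = data.sort_index()
    Z = hierarchy.linkage(ordered.values, method=linkage, metric="euclidean")
    leaves = hierarchy.leaves_list(Z)
    ids = tuple(str(i) for i in ordered.index)
    return Dendrogram(
        ids=ids,
        linkage_method=linkage,
        merges=Z,
        leaf_order=tuple(ids[i] for i in leaves),
    )


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA: eigenvalues (variances of the components),
    explained-variance fractions, loadings (variables x components) and
    scores (observations x components)."""

    eigenvalues: np.ndarray
    explained: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame

    def n_components(self, method: str = "kaiser", cum_threshold: float = 0.95) -> int:
        return select_components(self.eigenvalues, method, cum_threshold)


def pca(data: pd.DataFrame) -> PCAResult:
    """PCA of a standardised panel via eigendecomposition of its
    correlation matrix.

    Components are ordered by decreasing eigenvalue; each loading vector's
    largest-magnitude entry is made positive. Scores are the projections of
    the (already centred) data; their column means are zero and scores of
    distinct components are orthogonal.
    """
    X = data.astype(float).values
    n, p = X.shape
    if n < 2:
        raise InputError("need >= 2 rows for PCA")
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(p):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comp_names = [f"PC{j + 1}" for j in range(p)]
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    scores = Xz @ eigvec
    return PCAResult(
        eigenvalues=eigval,
        explained=eigval / eigval.sum(),
        loadings=pd.DataFrame(eigvec, index=data.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=data.index, columns=comp_names),
    )


def select_components(
    eigenvalues: Sequence[float], method: str = "kaiser", cum_threshold: float = 0.95
) -> int:
    """How many components to keep.

    ``kaiser``: count of eigenvalues >= 1 (warns when none qualifies).
    ``cumulative``: smallest k whose explained-variance fraction reaches
    ``cum_threshold``.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-12):
        raise InputError("eigenvalues must be sorted non-increasing")
    if method == "kaiser":
        k = int(np.sum(ev >= 1.0))
        if k == 0:
            warnings.warn("no eigenvalue >= 1; Kaiser criterion keeps none", stacklevel=2)
        return k
    if method == "cumulative":
        frac = np.cumsum(ev) / ev.sum()
        return int(np.searchsorted(frac, cum_threshold - 1e-12) + 1)
    raise InputError(f"method must be 'kaiser' or 'cumulative', got {method!r}")
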