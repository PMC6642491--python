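"""Principal-component aggregation of output indicators with adequacy tests.

Before a DEA run, a large block of correlated output indicators is reduced
to a few principal-component scores. This module implements the pieces of
that reduction on the correlation matrix: z-standardization, the Pearson
correlation matrix, the Kaiser–Meyer–Olkin (KMO) sampling-adequacy index,
Bartlett's test of sphericity, the eigendecomposition with variance table,
loadings and score coefficients, and Kaiser's eigenvalue-greater-than-one
component selection rule.

Sign convention: each eigenvector is oriented so that its largest-absolute
entry is positive. Eigenvector signs are mathematically arbitrary, so
comparisons against published loading tables should be made on absolute
values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "PCAResult",
    "AdequacyStats",
    "zstandardize",
    "pearson_correlation",
    "kmo",
    "bartlett_sphericity",
    "eigendecompose",
    "kaiser_select",
    "component_scores",
    "load_reference_correlations",
]

_SYM_TOL = 1e-12
_PSD_TOL = -1e-8  # printed rounding may make published matrices slightly indefinite


@dataclass(frozen=True)
class CorrelationMatrix:
    """Labeled symmetric correlation matrix."""

    labels: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", R)
        p = len(self.labels)
        if R.shape != (p, p):
            raise ValueError(f"matrix shape {R.shape} does not match {p} labels")
        if not np.allclose(R, R.T, atol=_SYM_TOL):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-9):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.any(np.abs(R) > 1 + 1e-9):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if np.linalg.eigvalsh((R + R.T) / 2).min() < _PSD_TOL:
            raise ValueError("correlation matrix is not positive semi-definite")

    @property
    def p(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: list[str]) -> "CorrelationMatrix":
        idx = [self.labels.index(l) for l in labels]
        return CorrelationMatrix(tuple(labels), self.entries[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=list(self.labels),
                            columns=list(self.labels))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CorrelationMatrix":
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(float))

    @classmethod
    def read_csv(cls, path) -> "CorrelationMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.12g")


def load_reference_correlations() -> CorrelationMatrix:
    """Packaged 13×13 indicator correlation matrix (2 inputs + 11 outputs)
    from the pooled 31-province × 10-year rural health panel."""
    with resources.files("healtheff.data").joinpath(
            "indicator_correlations.csv").open() as fh:
        return CorrelationMatrix.read_csv(fh)


@dataclass(frozen=True)
class AdequacyStats:
    """Bartlett sphericity statistic with its reference distribution."""

    chi2: float
    df: int
    p_value: float
    n_obs: int


@dataclass(frozen=True)
class PCAResult:
    """Eigenstructure of a correlation matrix.

    ``eigenvalues`` are descending; ``variance_pct`` is eigenvalue / p × 100;
    ``loadings`` columns are eigenvectors scaled by sqrt(eigenvalue);
    ``score_coefficients`` columns are unit eigenvectors (so loadings column
    divided by sqrt(eigenvalue)); ``n_selected`` is the Kaiser count.
    """

    labels: tuple[str, ...]
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_selected: int

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def variance_pct(self) -> np.ndarray:
        return self.eigenvalues / self.p * 100.0

    @property
    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.variance_pct)

    @property
    def loadings(self) -> np.ndarray:
        return self.eigenvectors * np.sqrt(np.clip(self.eigenvalues, 0, None))

    @property
    def score_coefficients(self) -> np.ndarray:
        return self.eigenvectors

    def regression_coefficients(self) -> np.ndarray:
        """SPSS-style coefficients loading/eigenvalue (alternative convention)."""
        return self.loadings / self.eigenvalues

    def variance_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(1, self.p + 1),
            "eigenvalue": self.eigenvalues,
            "variance_pct": self.variance_pct,
            "cumulative_pct": self.cumulative_pct,
        })


def zstandardize(data: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Center and scale each column to mean 0, sd 1 (sample sd by default)."""
    Z = np.asarray(data, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 observations")
    sd = Z.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise ValueError(f"column {j} has zero variance")
    return (Z - Z.mean(axis=0)) / sd


def pearson_correlation(data: np.ndarray,
                        labels: list[str] | None = None) -> CorrelationMatrix:
    """Pearson correlation matrix of an observation × variable matrix."""
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.any(X.std(axis=0) == 0):
        j = int(np.argmax(X.std(axis=0) == 0))
        raise ValueError(f"column {j} has zero variance")
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2, -1.0, 1.0)
    labels = labels or [f"V{j + 1}" for j in range(X.shape[1])]
    return CorrelationMatrix(tuple(labels), R)


def kmo(R: CorrelationMatrix) -> float:
    """Kaiser–Meyer–Olkin measure of sampling adequacy.

    KMO = Σ r²_ij / (Σ r²_ij + Σ q²_ij) over i ≠ j, where q_ij are the
    anti-image partial correlations −inv_ij / sqrt(inv_ii · inv_jj) computed
    from the inverse correlation matrix. Values near 1 indicate compact
    correlation structure suitable for component extraction; for p = 2 the
    partial correlation equals the correlation, so KMO is exactly 0.5.
    """
    A = R.entries
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"correlation matrix is numerically singular (cond={cond:.3g})")
    inv = np.linalg.inv(A)
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    Q = -inv / d
    off = ~np.eye(R.p, dtype=bool)
    r2 = float(np.sum(A[off] ** 2))
    q2 = float(np.sum(Q[off] ** 2))
    if r2 + q2 == 0.0:
        raise ZeroDivisionError("KMO undefined: all off-diagonal correlations are zero")
    return r2 / (r2 + q2)


def bartlett_sphericity(R: CorrelationMatrix, n_obs: int) -> AdequacyStats:
    """Bartlett's test that R is the identity matrix.

    χ² = −(n − 1 − (2p + 5)/6) · ln det R on p(p−1)/2 degrees of freedom.
    """
    p = R.p
    if n_obs <= p:
        raise ValueError(f"need n_obs > p (got n_obs={n_obs}, p={p})")
    sign, logdet = np.linalg.slogdet(R.entries)
    if sign <= 0:
        raise np.linalg.LinAlgError("det(R) <= 0; Bartlett statistic undefined")
    chi2 = -(n_obs - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return AdequacyStats(chi2=float(chi2), df=df,
                         p_value=float(stats.chi2.sf(chi2, df)), n_obs=n_obs)


def kaiser_select(eigenvalues) -> int:
    """Count of eigenvalues strictly greater than 1 (Kaiser criterion)."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue list")
    return int(np.sum(ev > 1.0))


def _orient(V: np.ndarray) -> np.ndarray:
    # flip each column so its largest-absolute entry is positive
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def eigendecompose(R: CorrelationMatrix) -> PCAResult:
    """Full eigendecomposition of a correlation matrix, descending order."""
    A = R.entries
    w, V = np.linalg.eigh((A + A.T) / 2)
    order = np.argsort(-w, kind="stable")  # stable: ties keep eigh's order
    w, V = w[order], _orient(V[:, order])
    return PCAResult(labels=R.labels, eigenvalues=w, eigenvectors=V,
                     n_selected=kaiser_select(w))


def component_scores(Z: np.ndarray, pca: PCAResult, k: int | None = None,
                     convention: str = "eigenvector") -> np.ndarray:
    """Observation × component score matrix for the first ``k`` components.

    With the default ``eigenvector`` convention, scores = Z · V_k where V_k
    holds unit eigenvectors; component variances then equal the eigenvalues.
    The ``regression`` convention uses loading/eigenvalue columns instead
    (unit-variance scores).
    """
    Z = np.asarray(Z, dtype=float)
    k = pca.n_selected if k is None else int(k)
    if not 1 <= k <= pca.p:
        raise IndexError(f"k must be in [1, {pca.p}], got {k}")
    if Z.shape[1] != pca.p:
        raise ValueError(f"Z has {Z.shape[1]} columns, expected {pca.p}")
    if convention == "eigenvector":
        C = pca.score_coefficients[:, :k]
    elif convention == "regression":
        C = pca.regression_coefficients()[:, :k]
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return Z @ C
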