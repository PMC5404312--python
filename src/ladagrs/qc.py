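"""Population-structure and calibration diagnostics.

LD pruning (greedy sliding window on squared dosage correlation), PCA of
standardized genotypes, the genomic inflation factor lambda, and QQ-plot
coordinates.  Lambda uses the exact chi-square(1 df) median
(0.4549364...) rather than the rounded 0.456 convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import GenotypeMatrix, ValidationError

# chi2(1) median via the same upper-tail transform applied to observed p,
# so a constant p = 0.5 maps to lambda = 1 exactly
CHI2_1_MEDIAN = float(stats.chi2.isf(0.5, df=1))  # 0.45493642311957285


@dataclass
class InflationResult:
    lambda_gc: float
    n_pvalues: int

    def __post_init__(self) -> None:
        if not self.lambda_gc > 0:
            raise ValidationError("lambda must be positive")


def _imputed(G: GenotypeMatrix) -> np.ndarray:
    X = G.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    r, c = np.where(np.isnan(X))
    X[r, c] = col_mean[c]
    return X


def ld_prune(
    G: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.2
) -> list[str]:
    """Greedy sliding-window LD pruning; returns retained SNP ids.

    Within each window, while any SNP pair has squared Pearson
    correlation above ``r2_max`` (on mean-imputed dosages), the member
    with the lower minor-allele frequency is removed (tie: the later
    column).  Monomorphic SNPs are removed up front.
    """
    X = _imputed(G)
    sd = X.std(axis=0)
    alive = sd > 0
    maf = np.minimum(X.mean(axis=0) / 2.0, 1.0 - X.mean(axis=0) / 2.0)
    m = G.n_snps
    for start in range(0, max(m - 1, 1), step):
        idx = [j for j in range(start, min(start + window, m)) if alive[j]]
        if len(idx) < 2:
            continue
        while True:
            cols = np.asarray(idx)
            sub = X[:, cols]
            corr = np.corrcoef(sub, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            r2 = corr**2
            if np.nanmax(r2) <= r2_max:
                break
            a, b = np.unravel_index(np.nanargmax(r2), r2.shape)
            ja, jb = cols[a], cols[b]
            if maf[ja] < maf[jb]:
                drop = ja
            elif maf[jb] < maf[ja]:
                drop = jb
            else:
                drop = max(ja, jb)
            alive[drop] = False
            idx = [j for j in idx if j != drop]
            if len(idx) < 2:
                break
    return [s for j, s in enumerate(G.snp_ids) if alive[j]]


def pca(
    G_pruned: GenotypeMatrix, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k PCA of standardized genotypes.

    Returns (coordinates n x k, explained-variance fractions).
    Coordinates are GRM eigenvectors scaled by sqrt(eigenvalue); each
    axis's sign is fixed so its largest-magnitude entry is positive.
    """
    n, m = G_pruned.n_individuals, G_pruned.n_snps
    if k >= min(n, m):
        raise ValidationError(f"k must be < min(n, m) = {min(n, m)}")
    X = _imputed(G_pruned)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    Z = (X[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / poly.sum()
    coords = U[:, :k] * np.sqrt(eigvals[:k])
    for j in range(k):
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    explained = eigvals[:k] / eigvals.sum()
    return coords, explained


class GenotypePCA(BaseEstimator, TransformerMixin):
    """Sklearn-style PCA on a GenotypeMatrix (diagnostic use).

    Attributes after ``fit``: ``coordinates_``, ``explained_variance_ratio_``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: GenotypeMatrix, y=None):
        self.coordinates_, self.explained_variance_ratio_ = pca(
            X, self.n_components
        )
        return self

    def transform(self, X: GenotypeMatrix) -> np.ndarray:
        # diagnostic PCA: transform returns the fitted coordinates
        return self.coordinates_

    def fit_transform(self, X: GenotypeMatrix, y=None, **kwargs) -> np.ndarray:
        return self.fit(X).coordinates_


def genomic_inflation(pvalues) -> InflationResult:
    """Genomic inflation factor: median observed chi2(1) / chi2(1) median."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    chi2_obs = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2_obs) / CHI2_1_MEDIAN)
    return InflationResult(lambda_gc=lam, n_pvalues=p.size)


def qq_points(pvalues) -> np.ndarray:
    """(expected, observed) -log10 p pairs for a QQ plot.

    Observed p are sorted ascending; expected quantiles are (i - 0.5)/n.
    Returns an (n, 2) array with both columns descending.
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    return np.column_stack([expected, observed])
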