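"""Linear mixed model association for a binary phenotype on allele dosage.

The model is y = mu*1 + x*beta + g + e with g ~ N(0, sg2*K) for a
standardized genetic relationship matrix K and e ~ N(0, se2*I).  The
phenotype is kept on the 0/1 scale.  Fitting works in the eigenbasis of
K: for a variance ratio lambda = sg2/se2 the rotated observations are
independent with weights 1/(lambda*d_i + 1), so REML reduces to a 1-D
search over log(lambda) followed by generalized least squares.  Wald
chi-square tests against chi2(1) give p-values, and effect sizes are
converted to approximate odds ratios from the intercept mu.

The variance ratio is estimated once at the null model (intercept only)
and reused for every SNP; exact per-SNP re-estimation is available via
``per_snp_reml=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .containers import (
    CohortLabels,
    GenotypeMatrix,
    LocusManifest,
    ValidationError,
)

LOG_LAMBDA_BOUNDS = (-5.0, 5.0)


class DegeneratePredictorError(ValidationError):
    """Dosage vector is constant after imputation."""


@dataclass
class GRM:
    """Standardized genetic relationship matrix with aligned individual ids."""

    matrix: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValidationError("GRM must be square")
        if K.shape[0] != len(self.individual_ids):
            raise ValidationError("GRM size does not match individual ids")
        if np.abs(K - K.T).max() > 1e-10:
            raise ValidationError("GRM not symmetric within 1e-10")
        self.matrix = (K + K.T) / 2.0


@dataclass
class EigenSystem:
    """Spectral decomposition of a GRM: eigenvalues descending, clipped >= 0."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def validate(self, K: np.ndarray | None = None, tol: float = 1e-8) -> None:
        U, d = self.eigenvectors, self.eigenvalues
        if np.abs(U.T @ U - np.eye(U.shape[1])).max() > tol:
            raise ValidationError("eigenvectors not orthonormal")
        if K is not None:
            if np.abs(K - (U * d) @ U.T).max() > tol:
                raise ValidationError("eigen reconstruction error exceeds tolerance")


@dataclass
class AssociationRecord:
    """Per-SNP mixed-model association result."""

    snp_id: str
    beta: float = math.nan
    se: float = math.nan
    mu: float = math.nan
    wald_chi2: float = math.nan
    p: float = math.nan
    or_approx: float = math.nan
    freq_a: float = math.nan
    freq_b: float = math.nan
    n_used: int = 0
    significant: bool = False
    panel: str = ""
    group_a: str = ""
    group_b: str = ""
    reason: str | None = None  # non-None marks a skipped SNP


def compute_grm(G: GenotypeMatrix) -> GRM:
    """Standardized GRM: K = (1/m) sum_j z_j z_j' over polymorphic SNPs.

    z_j = (g_j - 2*p_j) / sqrt(2*p_j*(1-p_j)); missing dosages are
    mean-imputed per SNP before standardization.
    """
    if G.n_individuals < 2:
        raise ValidationError("GRM needs at least 2 individuals")
    X = G.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    p_hat = X.mean(axis=0) / 2.0
    poly = (p_hat > 0.0) & (p_hat < 1.0) & (X.std(axis=0) > 0)
    if not poly.any():
        raise ValidationError("no polymorphic SNPs for GRM")
    Xp = X[:, poly]
    p = p_hat[poly]
    Z = (Xp - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    K = (Z @ Z.T) / Z.shape[1]
    return GRM(K, G.individual_ids.copy())


def eigendecompose(K: GRM) -> EigenSystem:
    """Full spectral decomposition, eigenvalues descending and clipped to 0."""
    d, U = np.linalg.eigh(K.matrix)
    if d.min() < -1e-8:
        raise ValidationError(f"GRM not PSD: min eigenvalue {d.min():.3e}")
    d = np.clip(d, 0.0, None)
    order = np.argsort(d)[::-1]
    return EigenSystem(d[order], U[:, order])


def _gls(yt: np.ndarray, Xt: np.ndarray, w: np.ndarray):
    """Weighted LS in the rotated basis; returns (coef, cov_unscaled, rss_w)."""
    XtW = Xt * w[:, None]
    A = XtW.T @ Xt
    b = XtW.T @ yt
    coef = np.linalg.solve(A, b)
    r = yt - Xt @ coef
    rss_w = float(r @ (w * r))
    return coef, np.linalg.inv(A), rss_w, A


def _reml_neg_loglik(log_lam: float, yt: np.ndarray, Xt: np.ndarray,
                     d: np.ndarray) -> float:
    lam = math.exp(log_lam)
    v = lam * d + 1.0
    w = 1.0 / v
    n, p = Xt.shape
    _, _, rss_w, A = _gls(yt, Xt, w)
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0 or rss_w <= 0:
        return np.inf
    sigma_e2 = rss_w / (n - p)
    return 0.5 * ((n - p) * math.log(sigma_e2) + float(np.log(v).sum()) + logdet_A)


def _optimize_lambda(yt: np.ndarray, Xt: np.ndarray, d: np.ndarray) -> float:
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=LOG_LAMBDA_BOUNDS,
        args=(yt, Xt, d),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(math.exp(res.x))


def reml_lambda(y: np.ndarray, eig: EigenSystem,
                covariates: np.ndarray | None = None) -> float:
    """REML estimate of sg2/se2 at the null (intercept-only) model."""
    U = eig.eigenvectors
    yt = U.T @ np.asarray(y, dtype=float)
    X = np.ones((len(y), 1)) if covariates is None else covariates
    Xt = U.T @ X
    return _optimize_lambda(yt, Xt, eig.eigenvalues)


def fit_lmm_snp(
    y: Sequence[float],
    x: Sequence[float],
    eig: EigenSystem | None,
    lam: float | None = None,
) -> AssociationRecord:
    """Fit the mixed model for one SNP and Wald-test beta.

    ``eig=None`` means K = I (no relatedness), in which case the fit is
    exactly ordinary least squares.  ``lam`` fixes the variance ratio
    (the once-per-phenotype shortcut); ``lam=None`` re-optimizes REML
    for this SNP.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("phenotype has a single class")
    if np.isnan(x).any():
        x = x.copy()
        x[np.isnan(x)] = np.nanmean(x)
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("constant dosage vector")
    n = y.size
    X = np.column_stack([np.ones(n), x])
    if eig is None:
        yt, Xt, d = y, X, np.zeros(n)
        w_lam = 0.0
    else:
        U = eig.eigenvectors
        yt, Xt, d = U.T @ y, U.T @ X, eig.eigenvalues
        w_lam = _optimize_lambda(yt, Xt, d) if lam is None else lam
    v = w_lam * d + 1.0
    w = 1.0 / v
    coef, cov_unscaled, rss_w, _ = _gls(yt, Xt, w)
    sigma_e2 = rss_w / (n - 2)
    mu, beta = float(coef[0]), float(coef[1])
    se = math.sqrt(sigma_e2 * cov_unscaled[1, 1])
    chi2 = (beta / se) ** 2
    p = float(stats.chi2.sf(chi2, df=1))
    return AssociationRecord(
        snp_id="", beta=beta, se=se, mu=mu, wald_chi2=chi2, p=p, n_used=n
    )


def approx_or(beta: float, mu: float, mode: str = "EXPONENT") -> float:
    """Approximate odds ratio from the linear-scale effect and intercept.

    EXPONENT (default): OR = exp(beta / (mu*(1-mu))) — the standard
    conversion of a linear-probability effect to a log-odds scale at
    baseline prevalence mu.  LITERAL: OR = beta / e^{mu*(1-mu)}, retained
    for fidelity to the published formula (which returns 0 at beta = 0).
    """
    if mode == "EXPONENT":
        if not 0.0 < mu < 1.0:
            raise ValidationError("mu must be in (0, 1) for EXPONENT mode")
        return math.exp(beta / (mu * (1.0 - mu)))
    if mode == "LITERAL":
        return beta / math.exp(mu * (1.0 - mu))
    raise ValidationError(f"unknown OR mode {mode!r}")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


def association_scan(
    G: GenotypeMatrix,
    labels: CohortLabels,
    manifest: LocusManifest,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    n_tests: int | None = None,
    grm: GRM | None = None,
    per_snp_reml: bool = False,
    or_mode: str = "EXPONENT",
    panel: str | None = None,
    subset_a: str | None = None,
) -> list[AssociationRecord]:
    """Scan every manifest SNP present in G for group_a vs group_b.

    group_a is coded 1, group_b 0.  The GRM (when given) must cover the
    union of the two groups; ``grm=None`` assumes unrelated individuals
    (identity K, i.e. plain least squares).  Bonferroni significance uses
    ``alpha / n_tests`` with ``n_tests`` defaulting to the number of
    SNPs scanned.  Case-vs-case contrasts are the same scan with both
    groups being case groups.  SNPs that cannot be fit are returned with
    a reason code rather than dropped.
    """
    mask_a = labels.group_mask(group_a, G.individual_ids)
    if subset_a is not None:
        mask_a &= labels.subset_mask(subset_a, G.individual_ids)
    mask_b = labels.group_mask(group_b, G.individual_ids)
    if not mask_a.any():
        raise ValidationError(f"group {group_a} is empty")
    if not mask_b.any():
        raise ValidationError(f"group {group_b} is empty")
    union = mask_a | mask_b
    Gu = G.subset_individuals(union)
    y = mask_a[union].astype(float)

    snps = [r for r in manifest if r.snp_id in set(G.snp_ids.tolist())]
    if panel is not None:
        snps = [r for r in snps if r.disease_panel in (panel, "BOTH")]
    n_tests = n_tests if n_tests is not None else len(snps)
    threshold = bonferroni_threshold(alpha, n_tests)

    eig = None
    lam = None
    if grm is not None:
        keep = set(Gu.individual_ids.tolist())
        idx = [i for i, iid in enumerate(grm.individual_ids) if iid in keep]
        if len(idx) != Gu.n_individuals:
            raise ValidationError("GRM does not cover the contrasted groups")
        sub = GRM(grm.matrix[np.ix_(idx, idx)],
                  grm.individual_ids[idx])
        # Align genotype rows to GRM order.
        order = {iid: k for k, iid in enumerate(Gu.individual_ids)}
        perm = [order[iid] for iid in sub.individual_ids]
        Gu = GenotypeMatrix(Gu.individual_ids[perm], Gu.snp_ids,
                            Gu.dosages[perm])
        y = y[perm]
        eig = eigendecompose(sub)
        if not per_snp_reml:
            lam = reml_lambda(y, eig)

    ya = mask_a[union]
    records: list[AssociationRecord] = []
    for rec in snps:
        x = Gu.column(rec.snp_id)
        freq_a = _obs_freq(x[y == 1])
        freq_b = _obs_freq(x[y == 0])
        try:
            fit = fit_lmm_snp(y, x, eig, lam=None if per_snp_reml else lam)
        except DegeneratePredictorError:
            records.append(
                AssociationRecord(
                    rec.snp_id, freq_a=freq_a, freq_b=freq_b,
                    panel=rec.disease_panel, group_a=group_a, group_b=group_b,
                    reason="constant_dosage",
                )
            )
            continue
        fit.snp_id = rec.snp_id
        fit.freq_a, fit.freq_b = freq_a, freq_b
        fit.panel = rec.disease_panel
        fit.group_a, fit.group_b = group_a, group_b
        try:
            fit.or_approx = approx_or(fit.beta, fit.mu, or_mode)
        except ValidationError:
            fit.or_approx = math.nan
        fit.significant = fit.p < threshold
        records.append(fit)
    records.sort(key=lambda r: (math.isnan(r.p), r.p))
    return records


def _obs_freq(x: np.ndarray) -> float:
    obs = x[~np.isnan(x)]
    return float(obs.mean() / 2.0) if obs.size else math.nan


class MixedModelAssociation(BaseEstimator):
    """Sklearn-style wrapper: per-column mixed-model Wald association.

    Parameters
    ----------
    grm : GRM or None
        Relatedness kernel over the fitted individuals (None = identity).
    per_snp_reml : bool
        Re-estimate the variance ratio for every column instead of once
        at the null model.
    or_mode : {"EXPONENT", "LITERAL"}
        Odds-ratio approximation mode.

    Attributes
    ----------
    results_ : list[AssociationRecord]
        One record per fitted column.
    lambda_ : float or None
        Null-model REML variance ratio (None when grm is None).
    """

    def __init__(self, grm: GRM | None = None, per_snp_reml: bool = False,
                 or_mode: str = "EXPONENT"):
        self.grm = grm
        self.per_snp_reml = per_snp_reml
        self.or_mode = or_mode

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValidationError("X must be n x m aligned with y")
        eig = None
        lam = None
        if self.grm is not None:
            eig = eigendecompose(self.grm)
            if not self.per_snp_reml:
                lam = reml_lambda(y, eig)
        self.lambda_ = lam
        self.results_ = []
        for j in range(X.shape[1]):
            try:
                rec = fit_lmm_snp(
                    y, X[:, j], eig, lam=None if self.per_snp_reml else lam
                )
                rec.snp_id = f"col{j}"
                rec.or_approx = approx_or(rec.beta, rec.mu, self.or_mode) \
                    if self.or_mode == "LITERAL" or 0 < rec.mu < 1 else math.nan
            except DegeneratePredictorError:
                rec = AssociationRecord(f"col{j}", reason="constant_dosage")
            self.results_.append(rec)
        self.n_features_in_ = X.shape[1]
        return self

    def pvalues_(self) -> np.ndarray:
        return np.array([r.p for r in self.results_])
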