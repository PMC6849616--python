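"""PCA-loading outlier scan.

The scan standardizes a genotype matrix, fits principal components, and
tests every SNP on every retained component using its loading — the
Pearson correlation between the SNP's standardized genotypes and the
component scores — as the statistic.  A robust Gaussian null
(median/MAD-calibrated) yields component-wise p-values, converted to
q-values within each component; a Mahalanobis distance over the
robustly standardized component statistics, recalibrated with a genomic
inflation factor, yields a single global test per SNP.

Conventions
-----------
* Missing genotypes are mean-imputed (zero after centring); loadings are
  nevertheless computed over typed entries only.
* Component signs are fixed so the largest-magnitude score entry on each
  axis is positive, making score thresholds reproducible.
* p-values are two-sided throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MISSING, EmptyPanelError, GenotypeMatrix

#: MAD -> standard-deviation consistency constant for the normal.
MAD_CONSISTENCY = 0.67449


class MonomorphicError(ValueError):
    """A monomorphic SNP reached a stage that requires polymorphism."""


class DegenerateComponentError(ValueError):
    """A component's loading distribution has zero robust scale."""


# ----------------------------------------------------------------------
# Standardization
# ----------------------------------------------------------------------

def standardize(G: GenotypeMatrix) -> np.ndarray:
    """Centre and scale genotypes to unit drift variance.

    Entry ``(i, j)`` becomes ``(g_ij - 2 p_j) / sqrt(2 p_j (1 - p_j))``
    for typed calls, with ``p_j`` the alternate-allele frequency over
    typed individuals; missing entries are set to 0 after centring
    (mean imputation).

    Raises
    ------
    MonomorphicError
        If any SNP is monomorphic (p in {0, 1}) or entirely missing.
    """
    p = G.allele_freq()
    bad = ~np.isfinite(p) | (p <= 0.0) | (p >= 1.0)
    if bad.any():
        offenders = G.snps[bad].tolist()[:5]
        raise MonomorphicError(
            f"monomorphic or untyped SNPs cannot be standardized: {offenders}"
        )
    scale = np.sqrt(2.0 * p * (1.0 - p))
    X = (G.calls.astype(np.float64) - 2.0 * p) / scale
    X[~G.typed] = 0.0
    return X


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

@dataclass
class PcaModel:
    """Fitted principal components of a standardized genotype matrix.

    ``scores`` are left singular vectors scaled by singular values
    (n_samples x K); ``snp_weights`` are the right singular vectors
    (n_snps x K, unit columns); ``eigenvalues`` are singular values
    squared over (n_samples - 1), sorted non-increasing.
    """

    K: int
    scores: np.ndarray
    eigenvalues: np.ndarray
    snp_weights: np.ndarray
    singular_values: np.ndarray

    @property
    def unit_scores(self) -> np.ndarray:
        """Scores rescaled to unit norm per column (left singular vectors)."""
        norms = np.linalg.norm(self.scores, axis=0)
        return self.scores / np.where(norms > 0, norms, 1.0)


def fit_pca(X: np.ndarray, K: int) -> PcaModel:
    """Top-K SVD of the standardized matrix, deterministic up to sign.

    The sign of each component is fixed so that its largest-magnitude
    score entry is positive.
    """
    n, p = X.shape
    if K > min(n - 1, p):
        raise ValueError(f"K={K} exceeds min(n_samples-1, n_snps)={min(n - 1, p)}")
    if K < 1:
        raise ValueError("K must be >= 1")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :K], s[:K], Vt[:K]
    scores = U * s
    for k in range(K):
        i = np.argmax(np.abs(scores[:, k]))
        if scores[i, k] < 0:
            scores[:, k] *= -1.0
            Vt[k] *= -1.0
    return PcaModel(
        K=K,
        scores=scores,
        eigenvalues=s**2 / max(n - 1, 1),
        snp_weights=Vt.T.copy(),
        singular_values=s,
    )


def scree(X: np.ndarray, K_max: int) -> pd.DataFrame:
    """Eigenvalue spectrum for choosing K.

    Returns a table with columns ``eigenvalue`` and ``proportion`` (of
    total variance, so proportions sum to <= 1) for components
    1..K_max, plus a ``df.attrs["elbow"]`` advisory: the component index
    (1-based) before the largest consecutive eigenvalue drop ratio.  The
    choice of K remains the caller's.
    """
    n, p = X.shape
    if K_max > min(n - 1, p):
        raise ValueError(f"K_max={K_max} exceeds min(n-1, p)={min(n - 1, p)}")
    s = np.linalg.svd(X, compute_uv=False)
    eig = s**2 / max(n - 1, 1)
    total = eig.sum()
    table = pd.DataFrame(
        {
            "component": np.arange(1, K_max + 1),
            "eigenvalue": eig[:K_max],
            "proportion": eig[:K_max] / total if total > 0 else 0.0,
        }
    ).set_index("component")
    if K_max > 1:
        head = table["eigenvalue"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = head[:-1] / head[1:]
        elbow = int(np.nanargmax(ratios)) + 1
    else:
        elbow = 1
    table.attrs["elbow"] = elbow
    return table


# ----------------------------------------------------------------------
# Component-wise scan
# ----------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-SNP scan statistics.

    Component-wise arrays are n_snps x K: ``loadings`` (rho, the
    SNP-score correlations), ``z`` (robustly standardized), ``p``, ``q``.
    Global arrays are length n_snps: ``d2`` (Mahalanobis distance),
    ``p_global``, ``q_global``; ``inflation`` is the scalar genomic
    inflation factor lambda.  Outlier flags use q <= alpha.
    """

    snps: pd.Index
    loadings: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    alpha: float
    d2: np.ndarray | None = None
    inflation: float | None = None
    p_global: np.ndarray | None = None
    q_global: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.loadings.shape[1]

    @property
    def outliers(self) -> np.ndarray:
        """Boolean n_snps x K matrix of component-wise outlier flags."""
        return self.q <= self.alpha

    @property
    def outliers_global(self) -> np.ndarray:
        if self.q_global is None:
            raise ValueError("global scan not computed")
        return self.q_global <= self.alpha

    def outlier_flags(self, scope) -> np.ndarray:
        """Outlier indicator for a scope: 1-based component int, "global",
        or "any" (outlier on at least one component)."""
        if scope == "global":
            return self.outliers_global
        if scope == "any":
            return self.outliers.any(axis=1)
        k = int(scope)
        if not 1 <= k <= self.K:
            raise ValueError(f"component {k} out of range 1..{self.K}")
        return self.outliers[:, k - 1]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a per-SNP table (the scan-results TSV layout)."""
        cols: dict[str, np.ndarray] = {}
        for k in range(self.K):
            cols[f"loading_pc{k + 1}"] = self.loadings[:, k]
            cols[f"z_pc{k + 1}"] = self.z[:, k]
            cols[f"p_pc{k + 1}"] = self.p[:, k]
            cols[f"q_pc{k + 1}"] = self.q[:, k]
            cols[f"outlier_pc{k + 1}"] = self.outliers[:, k]
        if self.d2 is not None:
            cols["mahalanobis_d2"] = self.d2
            cols["p_global"] = self.p_global
            cols["q_global"] = self.q_global
            cols["outlier_global"] = self.outliers_global
        df = pd.DataFrame(cols, index=self.snps)
        if self.inflation is not None:
            df.attrs["inflation"] = self.inflation
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="snp_id")


def _qvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """FDR q-values: Benjamini-Hochberg (default) or Storey's method."""
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam))
        pi0 = max(pi0, 1.0 / len(p))
        return np.minimum(pi0 * multipletests(p, method="fdr_bh")[1], 1.0)
    raise ValueError(f"unknown q-value method {method!r}")


def snp_loadings(
    X: np.ndarray, model: PcaModel, typed: np.ndarray | None = None
) -> np.ndarray:
    """Correlation rho_jk of each SNP with each score, over typed entries.

    ``typed`` is the boolean non-missing mask; if None all entries count.
    """
    n, p = X.shape
    scores = model.scores
    K = model.K
    if typed is None:
        typed = np.ones_like(X, dtype=bool)
    M = typed.astype(np.float64)
    n_t = M.sum(axis=0)  # (p,)
    # X is zero at missing entries, so masked sums equal plain dot products.
    sum_x = X.sum(axis=0)
    sum_x2 = (X**2).sum(axis=0)
    rho = np.empty((p, K))
    for k in range(K):
        s = scores[:, k]
        sum_s = M.T @ s
        sum_s2 = M.T @ (s**2)
        sum_xs = X.T @ s
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sum_xs - sum_x * sum_s / n_t
            var_x = sum_x2 - sum_x**2 / n_t
            var_s = sum_s2 - sum_s**2 / n_t
            r = cov / np.sqrt(var_x * var_s)
        r[~np.isfinite(r)] = 0.0
        rho[:, k] = np.clip(r, -1.0, 1.0)
    return rho


def component_scan(
    X: np.ndarray,
    model: PcaModel,
    alpha: float = 0.05,
    typed: np.ndarray | None = None,
    snps: pd.Index | None = None,
    qvalue_method: str = "bh",
) -> ScanResult:
    """Component-wise outlier test on loadings.

    For each component k the loadings are centred on their median and
    scaled by MAD/0.67449 (a robust estimate of the null standard
    deviation), giving z-scores tested against N(0, 1) two-sided;
    q-values are computed within each component.
    """
    rho = snp_loadings(X, model, typed)
    p_cnt, K = rho.shape
    if snps is None:
        snps = pd.Index([f"snp{j}" for j in range(p_cnt)], name="snp_id")
    z = np.empty_like(rho)
    for k in range(K):
        m = np.median(rho[:, k])
        s = stats.median_abs_deviation(rho[:, k]) / MAD_CONSISTENCY
        if s == 0:
            raise DegenerateComponentError(
                f"component {k + 1} has zero robust loading scale"
            )
        z[:, k] = (rho[:, k] - m) / s
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    qvals = np.column_stack(
        [_qvalues(pvals[:, k], qvalue_method) for k in range(K)]
    )
    return ScanResult(
        snps=pd.Index(snps, name="snp_id"),
        loadings=rho,
        z=z,
        p=pvals,
        q=qvals,
        alpha=alpha,
    )


def global_scan(
    result: ScanResult,
    alpha: float | None = None,
    qvalue_method: str = "bh",
    covariance: str = "identity",
) -> ScanResult:
    """Mahalanobis global test over the component-wise z-scores.

    ``D2_j = sum_k z_jk^2`` with the default identity covariance (the
    robustly standardized component statistics are treated as
    uncorrelated); ``covariance="mcd"`` instead uses a
    minimum-covariance-determinant estimate of the z covariance.  The
    genomic inflation factor ``lambda = median(D2) / chi2_median(K)``
    recalibrates the chi-square reference:
    ``p_j = P(chi2_K >= D2_j / lambda)``.
    """
    if result.K == 0:
        raise ValueError("no components in scan result")
    if alpha is None:
        alpha = result.alpha
    if covariance == "identity":
        d2 = (result.z**2).sum(axis=1)
    elif covariance == "mcd":
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(random_state=0).fit(result.z)
        d2 = mcd.mahalanobis(result.z)
    else:
        raise ValueError(f"unknown covariance estimator {covariance!r}")
    lam = np.median(d2) / stats.chi2.median(df=result.K)
    if lam <= 0:
        raise DegenerateComponentError("non-positive genomic inflation factor")
    p_global = stats.chi2.sf(d2 / lam, df=result.K)
    q_global = _qvalues(p_global, qvalue_method)
    result.d2 = d2
    result.inflation = float(lam)
    result.p_global = p_global
    result.q_global = q_global
    result.alpha = alpha
    return result


def run_scan(
    G: GenotypeMatrix,
    K: int,
    alpha: float = 0.05,
    qvalue_method: str = "bh",
) -> tuple[ScanResult, PcaModel]:
    """Standardize, fit K components, run component-wise + global tests."""
    X = standardize(G)
    model = fit_pca(X, K)
    res = component_scan(
        X, model, alpha=alpha, typed=G.typed, snps=G.snps,
        qvalue_method=qvalue_method,
    )
    return global_scan(res, alpha, qvalue_method), model


# ----------------------------------------------------------------------
# Divergent-cluster exclusion
# ----------------------------------------------------------------------

def exclude_cluster(
    G: GenotypeMatrix,
    model: PcaModel,
    pc_index: int,
    score_threshold: float,
) -> GenotypeMatrix:
    """Drop samples whose unit-norm score on one axis exceeds a threshold.

    ``pc_index`` is 1-based.  Scores are the sign-fixed left singular
    vectors (unit norm), so thresholds like the 0.1 used to peel off a
    hyper-diverged race are reproducible across runs.  The caller is
    expected to re-fit with K reduced by one afterwards.
    """
    if not 1 <= pc_index <= model.K:
        raise ValueError(f"pc_index {pc_index} out of range 1..{model.K}")
    u = model.unit_scores[:, pc_index - 1]
    keep = u <= score_threshold
    if not keep.any():
        raise EmptyPanelError("cluster exclusion removed every sample")
    if keep.all():
        return G
    removed = G.samples[~keep].tolist()
    warnings.warn(
        f"excluding {len(removed)} samples above PC{pc_index} score "
        f"{score_threshold}",
        stacklevel=2,
    )
    return G.take_samples(keep)
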