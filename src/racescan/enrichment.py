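"""Gene-level Poisson enrichment and category proportion tests.

If outlier SNPs were false positives scattered at random, the number
falling in any one gene would be Poisson with mean ``n_g * pi`` (gene
SNP count times the panel-wide outlier proportion).  Genes with a
right-tail Poisson probability below a threshold are flagged as outlier
genes; the discreteness of the test makes the list conservative.
Category-level contrasts (e.g. chemosensory vs control) use a pooled
two-proportion z-test on outlier fractions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .scan import ScanResult


def outlier_proportion(scan: ScanResult, scope, alpha: float = 0.05) -> float:
    """Fraction of SNPs flagged at q <= alpha in a scope.

    ``scope`` is a 1-based component index, "global", or "any".
    """
    flags = _flags_at(scan, scope, alpha)
    if flags.size == 0:
        raise ValueError("no SNPs in scope")
    return float(flags.mean())


def _flags_at(scan: ScanResult, scope, alpha: float) -> np.ndarray:
    """Outlier indicator at an alpha possibly different from the scan's."""
    if scope == "global":
        if scan.q_global is None:
            raise ValueError("global scan not computed")
        return scan.q_global <= alpha
    if scope == "any":
        return (scan.q <= alpha).any(axis=1)
    k = int(scope)
    return scan.q[:, k - 1] <= alpha


def poisson_gene_test(
    gene_counts: pd.DataFrame,
    pi: float,
    p_threshold: float = 0.05,
    min_outliers: int | None = None,
) -> pd.DataFrame:
    """Right-tail Poisson test per gene.

    ``gene_counts`` has columns ``n_snps`` and ``n_outliers`` indexed by
    gene ID.  ``poisson_p = P(X >= o_g)`` with ``X ~ Poisson(n_g * pi)``
    (1 - CDF(o_g - 1)); a gene is flagged when ``poisson_p <
    p_threshold`` and, if ``min_outliers`` is set, ``o_g >=
    min_outliers`` (the three-or-more-outlier-SNPs criterion).
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi={pi} outside [0, 1]")
    n_g = gene_counts["n_snps"].to_numpy(int)
    o_g = gene_counts["n_outliers"].to_numpy(int)
    if (o_g > n_g).any():
        bad = gene_counts.index[o_g > n_g][0]
        raise ValueError(f"gene {bad!r} has more outliers than SNPs")
    lam = n_g * pi
    poisson_p = stats.poisson.sf(o_g - 1, lam)  # P(X >= o_g)
    flag = poisson_p < p_threshold
    if min_outliers is not None:
        flag &= o_g >= min_outliers
    out = gene_counts.copy()
    out["expected"] = lam
    out["poisson_p"] = poisson_p
    out["outlier_gene"] = flag
    return out


def gene_outlier_test(
    scan: ScanResult,
    annotation: pd.DataFrame,
    scope,
    alpha: float = 0.05,
    p_threshold: float = 0.05,
    min_outliers: int | None = None,
) -> pd.DataFrame:
    """Aggregate scan flags per gene and run the Poisson test.

    SNPs without a gene assignment are left out.  Each gene is tested in
    every scope where it has at least one SNP; no cross-gene
    multiplicity correction is applied by default (the conservative
    Poisson list stands on its own).
    """
    flags = _flags_at(scan, scope, alpha)
    gene_ids = annotation.reindex(scan.snps)["gene_id"]
    keep = gene_ids.notna().to_numpy()
    df = pd.DataFrame(
        {"gene_id": gene_ids.to_numpy()[keep], "outlier": flags[keep]}
    )
    counts = df.groupby("gene_id", sort=True).agg(
        n_snps=("outlier", "size"), n_outliers=("outlier", "sum")
    )
    pi = float(flags[keep].mean()) if keep.any() else 0.0
    result = poisson_gene_test(counts, pi, p_threshold, min_outliers)
    result.insert(0, "scope", str(scope))
    result.attrs["pi"] = pi
    return result


def two_proportion_ztest(
    x_a: int, n_a: int, x_b: int, n_b: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Pooled-variance z-test for equality of two proportions.

    ``z = (p_b - p_a) / sqrt(pbar (1 - pbar) (1/n_a + 1/n_b))``.  When
    the pooled proportion is degenerate (0 or 1) the test is
    uninformative and p is reported as 1 with a warning.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("both groups must be non-empty")
    p_a, p_b = x_a / n_a, x_b / n_b
    pooled = (x_a + x_b) / (n_a + n_b)
    if pooled <= 0.0 or pooled >= 1.0:
        warnings.warn("degenerate pooled proportion; test uninformative",
                      stacklevel=2)
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n_a + 1.0 / n_b))
    z = (p_b - p_a) / se
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":  # H1: p_b > p_a
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(min(p, 1.0))


def category_proportion_test(
    scan: ScanResult,
    annotation: pd.DataFrame,
    scope,
    cat_a: str = "control",
    cat_b: str = "chemosensory",
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> pd.Series:
    """Compare outlier proportions between two SNP categories.

    Returns a Series with the counts, proportions, z and p.  Swapping
    the categories negates z and preserves p (two-sided).
    """
    flags = _flags_at(scan, scope, alpha)
    cats = annotation.reindex(scan.snps)["category"].to_numpy()
    in_a, in_b = cats == cat_a, cats == cat_b
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(
            f"category {cat_a if n_a == 0 else cat_b!r} empty in scope"
        )
    x_a, x_b = int(flags[in_a].sum()), int(flags[in_b].sum())
    z, p = two_proportion_ztest(x_a, n_a, x_b, n_b, alternative)
    return pd.Series(
        {
            "scope": str(scope),
            "category_a": cat_a,
            "category_b": cat_b,
            "n_a": n_a,
            "x_a": x_a,
            "prop_a": x_a / n_a,
            "n_b": n_b,
            "x_b": x_b,
            "prop_b": x_b / n_b,
            "z": z,
            "p": p,
        }
    )
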