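"""Cross-panel concordance of two outlier scans.

Two independently genotyped panels (e.g. a dense capture panel and a
sparse assay panel) measure the same underlying axes of divergence but
may order them differently.  This module matches SNPs by ID, pairs each
axis of one scan with the axis of the other that maximizes the Pearson
correlation of squared loadings, reports the per-pair and max-loading
correlations, and tests whether the observed overlap of significant
SNPs exceeds the permutation null in which panel-B significance is
reassigned at random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scan import ScanResult


@dataclass
class SharedSnpMap:
    """SNPs present in both scans, with positional indices on each side."""

    snp_ids: pd.Index
    index_a: np.ndarray
    index_b: np.ndarray
    n_unmatched_a: int
    n_unmatched_b: int

    @property
    def n_shared(self) -> int:
        return len(self.snp_ids)


def match_snps(scan_a: ScanResult, scan_b: ScanResult) -> SharedSnpMap:
    """Exact SNP-ID matching; each SNP appears at most once."""
    shared = scan_a.snps.intersection(scan_b.snps)
    shared = pd.Index([s for s in scan_a.snps if s in set(shared)], name="snp_id")
    if shared.empty:
        raise ValueError("no shared SNPs between the two scans")
    idx_a = scan_a.snps.get_indexer(shared)
    idx_b = scan_b.snps.get_indexer(shared)
    return SharedSnpMap(
        snp_ids=shared,
        index_a=idx_a,
        index_b=idx_b,
        n_unmatched_a=len(scan_a.snps) - len(shared),
        n_unmatched_b=len(scan_b.snps) - len(shared),
    )


def pair_axes(
    scan_a: ScanResult, scan_b: ScanResult, shared: SharedSnpMap
) -> pd.DataFrame:
    """For each axis of B, the axis of A with the most correlated squared
    loadings over shared SNPs (pairing may be many-to-one).

    Axes with constant squared loadings are unpairable (NaN, warning).
    """
    if shared.n_shared < 3:
        raise ValueError("need at least 3 shared SNPs to pair axes")
    sq_a = scan_a.loadings[shared.index_a] ** 2
    sq_b = scan_b.loadings[shared.index_b] ** 2
    rows = []
    for kb in range(scan_b.K):
        yb = sq_b[:, kb]
        if np.ptp(yb) == 0:
            warnings.warn(f"axis B{kb + 1} has constant squared loadings; "
                          "unpairable", stacklevel=2)
            rows.append((kb + 1, np.nan, np.nan))
            continue
        best_r, best_ka = -np.inf, None
        for ka in range(scan_a.K):
            ya = sq_a[:, ka]
            if np.ptp(ya) == 0:
                continue
            r = stats.pearsonr(ya, yb).statistic
            if r > best_r:
                best_r, best_ka = r, ka + 1
        if best_ka is None:
            warnings.warn(f"no pairable axis in A for B{kb + 1}", stacklevel=2)
            rows.append((kb + 1, np.nan, np.nan))
        else:
            rows.append((kb + 1, best_ka, best_r))
    return pd.DataFrame(rows, columns=["axis_b", "axis_a", "r"]).set_index("axis_b")


def loading_correlations(
    scan_a: ScanResult,
    scan_b: ScanResult,
    pairing: pd.DataFrame,
    shared: SharedSnpMap,
) -> pd.Series:
    """Pearson r of squared loadings per paired axis plus the max-loading r.

    The max-loading correlation compares each SNP's maximum squared
    loading across axes in one panel with the same quantity in the
    other.
    """
    if shared.n_shared < 3:
        raise ValueError("need at least 3 shared SNPs")
    sq_a = scan_a.loadings[shared.index_a] ** 2
    sq_b = scan_b.loadings[shared.index_b] ** 2
    out = {}
    for axis_b, row in pairing.iterrows():
        if np.isnan(row["axis_a"]):
            out[f"r_b{axis_b}"] = np.nan
            continue
        ka = int(row["axis_a"]) - 1
        out[f"r_b{axis_b}"] = stats.pearsonr(
            sq_a[:, ka], sq_b[:, int(axis_b) - 1]
        ).statistic
    max_a = sq_a.max(axis=1)
    max_b = sq_b.max(axis=1)
    out["r_max_loading"] = stats.pearsonr(max_a, max_b).statistic
    return pd.Series(out)


@dataclass
class OverlapTestResult:
    """Permutation overlap test summary."""

    n_shared: int
    n_sig_a_shared: int
    n_sig_b_total: int
    observed_overlap: int
    n_perm: int
    seed: int | None
    p: float


def overlap_permutation_test(
    sig_a_shared_ids,
    sig_b_ids,
    ids_b_all,
    shared: SharedSnpMap,
    n_perm: int = 100_000,
    seed: int | None = None,
) -> OverlapTestResult:
    """Is the overlap of significant SNPs larger than chance?

    ``sig_a_shared_ids``: shared SNPs significant in scan A.
    ``sig_b_ids``: SNPs significant in scan B; their count is
    re-assigned uniformly without replacement over ALL of panel B's
    SNPs (``ids_b_all``) in each permutation — draws landing outside
    the shared set contribute zero overlap.  p uses the add-one rule,
    so it is never below 1/(1+n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if shared.n_shared == 0:
        raise ValueError("empty shared SNP set")
    ids_b_all = pd.Index(ids_b_all)
    sig_b = set(sig_b_ids)
    n_sig_b = len(sig_b)
    if n_sig_b > len(ids_b_all):
        raise ValueError("more significant B SNPs than panel-B SNPs")
    sig_a = set(sig_a_shared_ids)
    shared_set = set(shared.snp_ids)
    if not sig_a <= shared_set:
        raise ValueError("sig_a_shared_ids must be a subset of the shared SNPs")
    observed = len(sig_a & sig_b)

    # indicator over panel B: 1 where the SNP is shared AND A-significant
    hit = np.array([sid in sig_a for sid in ids_b_all], dtype=np.float64)
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = 20_000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # without-replacement draws via ranking random keys
        keys = rng.random((m, len(ids_b_all)))
        picks = np.argpartition(keys, n_sig_b - 1, axis=1)[:, :n_sig_b]
        overlaps = hit[picks].sum(axis=1)
        exceed += int((overlaps >= observed).sum())
        done += m
    p = (1.0 + exceed) / (1.0 + n_perm)
    return OverlapTestResult(
        n_shared=shared.n_shared,
        n_sig_a_shared=len(sig_a),
        n_sig_b_total=n_sig_b,
        observed_overlap=observed,
        n_perm=n_perm,
        seed=seed,
        p=p,
    )


def compare_scans(
    scan_a: ScanResult,
    scan_b: ScanResult,
    n_perm: int = 100_000,
    seed: int | None = None,
    significance: str = "any",
) -> dict:
    """End-to-end concordance: match, pair, correlate, overlap-test.

    ``significance`` selects what "significant in A/B" means: "any"
    (q <= alpha on at least one component, the default) or "global"
    (Mahalanobis q <= alpha only).
    """
    shared = match_snps(scan_a, scan_b)
    pairing = pair_axes(scan_a, scan_b, shared)
    corr = loading_correlations(scan_a, scan_b, pairing, shared)
    flags_a = scan_a.outlier_flags(significance)
    flags_b = scan_b.outlier_flags(significance)
    sig_a_shared = [
        s for s, j in zip(shared.snp_ids, shared.index_a) if flags_a[j]
    ]
    sig_b = scan_b.snps[flags_b]
    overlap = overlap_permutation_test(
        sig_a_shared, sig_b, scan_b.snps, shared, n_perm=n_perm, seed=seed
    )
    return {
        "shared": shared,
        "pairing": pairing,
        "correlations": corr,
        "overlap": overlap,
    }
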