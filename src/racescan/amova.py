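"""Locus-by-locus hierarchical analysis of molecular variance.

Three-level AMOVA on diploid SNP genotypes: variance is partitioned
among groups (host races), among populations within groups (localities
within race) and within populations.  Each typed diploid contributes two
gene copies; the analysis operates on the 0/1 allele indicator of each
copy, so all sums of squares reduce to closed forms in per-population
allele counts.  Variance components are solved from the expected mean
squares of the unbalanced nested design; significance is assessed by
permutation (whole populations among groups for the among-group
component, individuals among populations within groups for the
among-population component).

Negative variance components are reported as computed, not truncated;
percentages use the signed sums.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .scan import MAD_CONSISTENCY, PcaModel


class DesignError(ValueError):
    """Invalid race/locality hierarchy."""


@dataclass
class HierarchyDesign:
    """Per-sample group (race) and population (locality-within-race) labels.

    Every population must nest in exactly one group; at least two groups
    and one population per group are required.
    """

    groups: np.ndarray
    populations: np.ndarray
    pop_labels: pd.Index = field(init=False)
    group_labels: pd.Index = field(init=False)
    pop_index: np.ndarray = field(init=False)
    group_of_pop: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        self.populations = np.asarray(self.populations)
        if self.groups.shape != self.populations.shape:
            raise DesignError("group and population label arrays differ in length")
        pairs = pd.DataFrame({"g": self.groups, "p": self.populations})
        nest = pairs.drop_duplicates()
        if nest["p"].duplicated().any():
            bad = nest.loc[nest["p"].duplicated(), "p"].iloc[0]
            raise DesignError(f"population {bad!r} appears in more than one group")
        self.pop_labels = pd.Index(nest["p"])
        self.group_labels = pd.Index(pd.unique(self.groups))
        if len(self.group_labels) < 2:
            raise DesignError("need at least two groups")
        pop_lookup = {p: i for i, p in enumerate(self.pop_labels)}
        grp_lookup = {g: i for i, g in enumerate(self.group_labels)}
        self.pop_index = np.array([pop_lookup[p] for p in self.populations])
        self.group_of_pop = np.array([grp_lookup[g] for g in nest["g"]])

    @classmethod
    def from_meta(
        cls,
        meta: pd.DataFrame,
        group_col: str = "host_race",
        pop_col: str = "locality",
    ) -> "HierarchyDesign":
        pops = meta[group_col].astype(str) + "/" + meta[pop_col].astype(str)
        return cls(meta[group_col].to_numpy(), pops.to_numpy())

    @property
    def n_pops(self) -> int:
        return len(self.pop_labels)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


# ----------------------------------------------------------------------
# Core variance-component computation (vectorized across loci)
# ----------------------------------------------------------------------

def _pop_counts(
    calls: np.ndarray, pop_index: np.ndarray, n_pops: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-population gene-copy counts and alternate-allele counts.

    Returns ``n_p`` and ``A_p``, both (n_pops, n_loci).  Missing
    genotypes contribute nothing.
    """
    typed = calls != MISSING
    alt = np.where(typed, calls, 0).astype(np.float64)
    n_loci = calls.shape[1]
    n_p = np.zeros((n_pops, n_loci))
    A_p = np.zeros((n_pops, n_loci))
    np.add.at(n_p, pop_index, 2.0 * typed)
    np.add.at(A_p, pop_index, alt)
    return n_p, A_p


def _components_from_counts(
    n_p: np.ndarray, A_p: np.ndarray, group_of_pop: np.ndarray, n_groups: int
) -> dict[str, np.ndarray]:
    """Solve the nested-ANOVA variance components from allele counts.

    All arrays are (n_pops, n_loci); returns per-locus component arrays.
    The 0/1 allele indicators make every sum of squares a function of
    (n_p, A_p) only: sum(y^2) = sum(y) = A.
    """
    Gmat = np.zeros((n_groups, n_p.shape[0]))
    Gmat[group_of_pop, np.arange(n_p.shape[0])] = 1.0
    n_g = Gmat @ n_p
    A_g = Gmat @ A_p
    N = n_p.sum(axis=0)
    A = A_p.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        ss_pop_term = np.where(n_p > 0, A_p**2 / np.where(n_p > 0, n_p, 1.0), 0.0)
        ss_grp_term = np.where(n_g > 0, A_g**2 / np.where(n_g > 0, n_g, 1.0), 0.0)
        mean_term = np.where(N > 0, A**2 / np.where(N > 0, N, 1.0), 0.0)

        ss_c = A - ss_pop_term.sum(axis=0)                       # within pops
        ss_b = ss_pop_term.sum(axis=0) - ss_grp_term.sum(axis=0)  # pops in groups
        ss_a = ss_grp_term.sum(axis=0) - mean_term                # among groups

        P_eff = (n_p > 0).sum(axis=0)
        G_eff = (n_g > 0).sum(axis=0)
        df_a = G_eff - 1.0
        df_b = P_eff - G_eff
        df_c = N - P_eff

        # Unbalanced-design EMS coefficients.
        sum_np2_over_ng = np.where(
            n_g > 0, (Gmat @ n_p**2) / np.where(n_g > 0, n_g, 1.0), 0.0
        ).sum(axis=0)
        sum_np2_over_N = (n_p**2).sum(axis=0) / np.where(N > 0, N, 1.0)
        sum_ng2_over_N = (n_g**2).sum(axis=0) / np.where(N > 0, N, 1.0)
        n_prime = np.where(df_b > 0, (N - sum_np2_over_ng) / np.where(df_b > 0, df_b, 1.0), np.nan)
        n_dprime = np.where(df_a > 0, (sum_np2_over_ng - sum_np2_over_N) / np.where(df_a > 0, df_a, 1.0), np.nan)
        n_tprime = np.where(df_a > 0, (N - sum_ng2_over_N) / np.where(df_a > 0, df_a, 1.0), np.nan)

        ms_c = np.where(df_c > 0, ss_c / np.where(df_c > 0, df_c, 1.0), 0.0)
        ms_b = np.where(df_b > 0, ss_b / np.where(df_b > 0, df_b, 1.0), np.nan)
        ms_a = np.where(df_a > 0, ss_a / np.where(df_a > 0, df_a, 1.0), np.nan)

        sigma_c = ms_c
        sigma_b = np.where(
            (df_b > 0) & (n_prime > 0), (ms_b - sigma_c) / n_prime, 0.0
        )
        sigma_a = np.where(
            (df_a > 0) & (n_tprime > 0),
            (ms_a - sigma_c - n_dprime * sigma_b) / n_tprime,
            0.0,
        )

    # Monomorphic loci: all components zero by convention.
    mono = (A <= 0) | (A >= N)
    for arr in (sigma_a, sigma_b, sigma_c):
        arr[mono] = 0.0
    return {
        "sigma_a": sigma_a,
        "sigma_b": sigma_b,
        "sigma_c": sigma_c,
        "monomorphic": mono,
        "n_copies": N,
        "n_pops_eff": P_eff,
    }


def _phi_stats(sa: np.ndarray, sb: np.ndarray, sc: np.ndarray):
    total = sa + sb + sc
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_ct = np.where(total != 0, sa / total, np.nan)
        phi_st = np.where(total != 0, (sa + sb) / total, np.nan)
        denom = sb + sc
        phi_sc = np.where(denom != 0, sb / denom, np.nan)
        pct = np.where(
            total[None, :] != 0,
            100.0 * np.vstack([sa, sb, sc]) / total[None, :],
            np.nan,
        )
    return phi_ct, phi_sc, phi_st, pct


def amova_locus(
    genotypes: np.ndarray, design: HierarchyDesign
) -> pd.Series:
    """Three-level AMOVA for a single locus.

    ``genotypes`` is a length-n_samples vector of {0, 1, 2, MISSING}
    codes aligned with the design.  Returns the variance components,
    their percentages of total and the Phi statistics.  A monomorphic
    locus yields all-zero components and a ``monomorphic`` flag.
    """
    calls = np.asarray(genotypes).reshape(-1, 1)
    typed = calls[:, 0] != MISSING
    pops_with_data = np.unique(design.pop_index[typed])
    if typed.sum() < 1 or len(pops_with_data) < 2:
        raise DesignError("locus needs typed copies in at least two populations")
    n_p, A_p = _pop_counts(calls, design.pop_index, design.n_pops)
    comp = _components_from_counts(n_p, A_p, design.group_of_pop, design.n_groups)
    sa, sb, sc = comp["sigma_a"][0], comp["sigma_b"][0], comp["sigma_c"][0]
    phi_ct, phi_sc, phi_st, pct = _phi_stats(
        np.array([sa]), np.array([sb]), np.array([sc])
    )
    return pd.Series(
        {
            "sigma_a": sa,
            "sigma_b": sb,
            "sigma_c": sc,
            "pct_a": pct[0, 0],
            "pct_b": pct[1, 0],
            "pct_c": pct[2, 0],
            "phi_ct": phi_ct[0],
            "phi_sc": phi_sc[0],
            "phi_st": phi_st[0],
            "monomorphic": bool(comp["monomorphic"][0]),
        }
    )


# ----------------------------------------------------------------------
# Permutations
# ----------------------------------------------------------------------

def _multiset_permutations(labels: np.ndarray):
    """Distinct permutations of a label vector (dedup via sorting tree)."""
    seen = set()
    for perm in permutations(labels.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.array(perm)


def _n_distinct_group_assignments(group_of_pop: np.ndarray) -> int:
    counts = pd.Series(group_of_pop).value_counts()
    n = math.factorial(len(group_of_pop))
    for c in counts:
        n //= math.factorial(int(c))
    return n


@dataclass
class AmovaReport:
    """Per-locus components plus aggregate decomposition.

    ``per_locus`` is indexed by locus ID; ``aggregate`` holds the
    decomposition from components summed across loci (the weighted-
    average convention) with permutation p-values; ``n_perm``/``seed``
    record the permutation settings.
    """

    per_locus: pd.DataFrame
    aggregate: pd.Series
    n_perm: int
    seed: int | None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# aggregate\n")
            self.aggregate.to_frame("value").to_csv(fh, sep="\t")
            fh.write("# per-locus\n")
            self.per_locus.to_csv(fh, sep="\t", index_label="locus")


def amova_all(
    G: GenotypeMatrix,
    design: HierarchyDesign,
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaReport:
    """Locus-by-locus AMOVA with permutation significance.

    Aggregate percentages come from components summed across loci.  The
    among-group test permutes whole populations among groups; the
    among-population test permutes individuals among populations within
    their group.  p = (1 + #{perm >= obs}) / (1 + n_perm); when the
    design admits fewer distinct among-group permutations than n_perm,
    the among-group null is enumerated exhaustively instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    calls = G.calls
    n_p, A_p = _pop_counts(calls, design.pop_index, design.n_pops)
    comp = _components_from_counts(n_p, A_p, design.group_of_pop, design.n_groups)
    sa, sb, sc = comp["sigma_a"], comp["sigma_b"], comp["sigma_c"]
    phi_ct, phi_sc, phi_st, pct = _phi_stats(sa, sb, sc)

    # --- among-group permutations: shuffle pop -> group map -------------
    obs_a = sa
    agg_obs_a = sa.sum()
    n_distinct = _n_distinct_group_assignments(design.group_of_pop)
    exceed_a = np.zeros(calls.shape[1])
    agg_exceed_a = 0
    tol = 1e-12
    if n_distinct <= n_perm:
        n_done = 0
        for assignment in _multiset_permutations(design.group_of_pop):
            c = _components_from_counts(n_p, A_p, assignment, design.n_groups)
            exceed_a += c["sigma_a"] >= obs_a - tol
            agg_exceed_a += c["sigma_a"].sum() >= agg_obs_a - tol
            n_done += 1
        p_a = exceed_a / n_done
        agg_p_a = agg_exceed_a / n_done
    else:
        for _ in range(n_perm):
            assignment = rng.permutation(design.group_of_pop)
            c = _components_from_counts(n_p, A_p, assignment, design.n_groups)
            exceed_a += c["sigma_a"] >= obs_a - tol
            agg_exceed_a += c["sigma_a"].sum() >= agg_obs_a - tol
        p_a = (1.0 + exceed_a) / (1.0 + n_perm)
        agg_p_a = (1.0 + agg_exceed_a) / (1.0 + n_perm)

    # --- among-pop-within-group permutations: shuffle individuals -------
    obs_b = sb
    agg_obs_b = sb.sum()
    exceed_b = np.zeros(calls.shape[1])
    agg_exceed_b = 0
    group_of_sample = design.group_of_pop[design.pop_index]
    group_members = [
        np.flatnonzero(group_of_sample == g) for g in range(design.n_groups)
    ]
    pop_idx_work = design.pop_index.copy()
    for _ in range(n_perm):
        for members in group_members:
            pop_idx_work[members] = design.pop_index[rng.permutation(members)]
        n_pp, A_pp = _pop_counts(calls, pop_idx_work, design.n_pops)
        c = _components_from_counts(
            n_pp, A_pp, design.group_of_pop, design.n_groups
        )
        exceed_b += c["sigma_b"] >= obs_b - tol
        agg_exceed_b += c["sigma_b"].sum() >= agg_obs_b - tol
    p_b = (1.0 + exceed_b) / (1.0 + n_perm)
    agg_p_b = (1.0 + agg_exceed_b) / (1.0 + n_perm)

    per_locus = pd.DataFrame(
        {
            "sigma_a": sa,
            "sigma_b": sb,
            "sigma_c": sc,
            "pct_a": pct[0],
            "pct_b": pct[1],
            "pct_c": pct[2],
            "phi_ct": phi_ct,
            "phi_sc": phi_sc,
            "phi_st": phi_st,
            "p_a": p_a,
            "p_b": p_b,
            "monomorphic": comp["monomorphic"],
        },
        index=G.snps,
    )
    tot = sa.sum() + sb.sum() + sc.sum()
    aggregate = pd.Series(
        {
            "sigma_a": sa.sum(),
            "sigma_b": sb.sum(),
            "sigma_c": sc.sum(),
            "pct_a": 100.0 * sa.sum() / tot,
            "pct_b": 100.0 * sb.sum() / tot,
            "pct_c": 100.0 * sc.sum() / tot,
            "phi_ct": sa.sum() / tot,
            "phi_sc": sb.sum() / (sb.sum() + sc.sum()),
            "phi_st": (sa.sum() + sb.sum()) / tot,
            "p_a": agg_p_a,
            "p_b": agg_p_b,
        }
    )
    return AmovaReport(per_locus=per_locus, aggregate=aggregate,
                       n_perm=n_perm, seed=seed)


def category_summary(
    report: AmovaReport, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Unweighted per-locus mean percentage components by SNP category.

    Monomorphic loci (undefined percentages) are excluded; empty
    categories are omitted with a warning.
    """
    cats = annotation.reindex(report.per_locus.index)["category"]
    df = report.per_locus.assign(category=cats.to_numpy())
    df = df[~df["monomorphic"] & df["category"].notna()]
    if df.empty:
        warnings.warn("no polymorphic annotated loci for category summary",
                      stacklevel=2)
        return pd.DataFrame(columns=["pct_a", "pct_b", "pct_c", "n_loci"])
    out = df.groupby("category")[["pct_a", "pct_b", "pct_c"]].mean()
    out["n_loci"] = df.groupby("category").size()
    return out


# ----------------------------------------------------------------------
# Migrant reassignment and hybrid pruning
# ----------------------------------------------------------------------

@dataclass
class ClusterRules:
    """Knobs for genetic-cluster assignment on PCA scores.

    Each sample is projected onto the segment from its collection
    host's cluster centroid to the nearest other centroid; the
    fractional position t is ~0 for residents, ~0.5 for F1 hybrids and
    ~1 for migrants.  A sample is called an early-generation hybrid
    (and removed) when t falls inside ``hybrid_band`` AND its
    per-sample heterozygosity exceeds its host cluster's by more than
    ``het_excess_sd`` robust SDs — the first-generation signature.  A
    sample displaced past the midpoint (t > ``migrant_t``) and more
    than ``migrant_sd`` robust SDs from its host centroid, without
    heterozygote excess, is a migrant and is relabelled.  A call
    between two clusters separated by less than ``min_separation_sd``
    within-cluster SDs is ambiguous and the sample is left unchanged.
    """

    hybrid_band: tuple[float, float] = (0.25, 0.75)
    het_excess_sd: float = 1.0
    migrant_t: float = 0.5
    migrant_sd: float = 3.0
    min_separation_sd: float = 3.0
    n_axes: int | None = None


def _robust_sd(values: np.ndarray, floor: float = 1e-9) -> float:
    sd = np.median(np.abs(values - np.median(values))) / MAD_CONSISTENCY
    return max(float(sd), floor)


def assign_clusters(
    scores: np.ndarray,
    host_labels: np.ndarray,
    rules: ClusterRules | None = None,
    heterozygosity: np.ndarray | None = None,
) -> pd.DataFrame:
    """Genetic-cluster call per sample, anchored at the collection host.

    Centroids are per-host-label medians of the (axis-standardized)
    scores, robust to a few mislabelled migrants.  ``heterozygosity``
    is the per-sample fraction of heterozygous calls; without it the
    hybrid test falls back to position alone (t strictly inside the
    band).  Returns a frame with columns ``assigned``, ``t``,
    ``het_z``, ``ambiguous``, ``hybrid``.
    """
    if rules is None:
        rules = ClusterRules()
    host_labels = np.asarray(host_labels)
    S = np.asarray(scores, dtype=float)
    if rules.n_axes is not None:
        S = S[:, : rules.n_axes]
    # standardize axes globally so distances are comparable
    axis_scale = np.median(np.abs(S - np.median(S, axis=0)), axis=0) / MAD_CONSISTENCY
    axis_scale[axis_scale <= 0] = S.std(axis=0)[axis_scale <= 0] + 1e-12
    S = S / axis_scale
    labels = pd.unique(host_labels)
    members = {lab: np.flatnonzero(host_labels == lab) for lab in labels}
    centroids = np.vstack([np.median(S[members[lab]], axis=0) for lab in labels])
    label_pos = {lab: i for i, lab in enumerate(labels)}
    d = np.linalg.norm(S[:, None, :] - centroids[None, :, :], axis=2)
    n = len(S)
    assigned = host_labels.astype(object).copy()
    t_stat = np.zeros(n)
    het_z = np.zeros(n)
    if heterozygosity is not None:
        het = np.asarray(heterozygosity, dtype=float)
        for lab in labels:
            hc = het[members[lab]]
            het_z[members[lab]] = (hc - np.median(hc)) / _robust_sd(hc)
    ambiguous = np.zeros(n, dtype=bool)
    hybrid = np.zeros(n, dtype=bool)
    lo, hi = rules.hybrid_band
    if len(labels) > 1:
        for i in range(n):
            h = label_pos[host_labels[i]]
            c_h = centroids[h]
            d_others = d[i].copy()
            d_others[h] = np.inf
            o_near = int(np.argmin(d_others))
            # projection fraction along every well-separated axis from the
            # host centroid; the max identifies a hybrid's parent axis even
            # when the parent cluster is not the nearest centroid
            t_near = None
            t_max = -np.inf
            sd_pair = None
            for o in range(len(labels)):
                if o == h:
                    continue
                axis = centroids[o] - c_h
                length = np.linalg.norm(axis)
                if length == 0:
                    continue
                unit = axis / length
                sd_h = _robust_sd(S[members[labels[h]]] @ unit)
                sd_o = _robust_sd(S[members[labels[o]]] @ unit)
                if length < rules.min_separation_sd * max(sd_h, sd_o):
                    continue
                t = float((S[i] - c_h) @ unit / length)
                t_max = max(t_max, t)
                if o == o_near:
                    t_near = t
                    sd_pair = (length, sd_h, sd_o)
            if t_near is None:
                ambiguous[i] = True
                continue
            t_stat[i] = t_near
            if heterozygosity is not None:
                het_flag = het_z[i] > rules.het_excess_sd
            else:
                length, sd_h, sd_o = sd_pair
                het_flag = (
                    t_near * length > 3.0 * sd_h
                    and (1.0 - t_near) * length > 3.0 * sd_o
                )
            length, sd_h, _ = sd_pair
            if lo <= t_max <= hi and het_flag:
                hybrid[i] = True
            elif (
                t_near > rules.migrant_t
                and t_near * length > rules.migrant_sd * sd_h
            ):
                # past the midpoint AND significantly displaced from home
                assigned[i] = labels[o_near]
            elif t_near > lo:
                # displaced but neither clearly hybrid nor migrant
                ambiguous[i] = True
    return pd.DataFrame(
        {
            "assigned": assigned,
            "t": t_stat,
            "het_z": het_z,
            "ambiguous": ambiguous,
            "hybrid": hybrid,
        }
    )


def reassign_and_prune(
    G: GenotypeMatrix,
    cluster_assignments: pd.DataFrame | None = None,
    model: PcaModel | None = None,
    rules: ClusterRules | None = None,
    race_column: str = "host_race",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Relabel migrants to their genetic cluster's host; drop hybrids.

    ``cluster_assignments`` is the output of :func:`assign_clusters`
    (computed from ``model.scores`` if not given).  Samples whose
    cluster call disagrees with the collection host are relabelled
    (migrants); cross-cluster intermediates are removed (hybrids);
    ambiguous calls are left unchanged with a warning.  Returns the
    updated matrix and an action log.
    """
    hosts = G.sample_meta[race_column].to_numpy()
    if cluster_assignments is None:
        if model is None:
            raise ValueError("need cluster_assignments or a fitted PcaModel")
        typed = G.typed
        het = np.where(typed, G.calls == 1, False).sum(axis=1) / np.maximum(
            typed.sum(axis=1), 1
        )
        cluster_assignments = assign_clusters(model.scores, hosts, rules, het)
    assigned = cluster_assignments["assigned"].to_numpy()
    ambiguous = cluster_assignments["ambiguous"].to_numpy()
    hybrid = cluster_assignments["hybrid"].to_numpy()

    action = np.full(G.n_samples, "kept", dtype=object)
    new_label = hosts.copy()
    mism = (assigned != hosts) & ~hybrid
    action[mism & ambiguous] = "ambiguous"
    reassign = mism & ~ambiguous
    action[reassign] = "reassigned"
    new_label[reassign] = assigned[reassign]
    action[hybrid] = "removed_hybrid"
    if (mism & ambiguous).any():
        warnings.warn(
            f"{int((mism & ambiguous).sum())} ambiguous cluster calls left "
            "unchanged",
            stacklevel=2,
        )
    log = pd.DataFrame(
        {
            "sample_id": G.samples,
            "collection_host": hosts,
            "assigned_cluster": assigned,
            "action": action,
            "new_label": new_label,
        }
    ).set_index("sample_id")
    meta = G.sample_meta.copy()
    meta[race_column] = new_label
    out = G.with_sample_meta(meta).take_samples(~hybrid)
    return out, log
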