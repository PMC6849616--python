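"""Hierarchical AMOVA against a brute-force nested-ANOVA oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import racescan as rs
from racescan.io import MISSING

from conftest import POLYMORPHIC_ONLY


# ----------------------------------------------------------------------
# Independent oracle: explicit-loop nested ANOVA on gene-copy indicators
# ----------------------------------------------------------------------

def brute_force_amova(genotypes, groups, pops):
    """Textbook unbalanced two-level nested ANOVA over expanded copies.

    Expands each typed diploid into two 0/1 allele indicators and
    computes sums of squares and expected-mean-square coefficients with
    explicit Python loops — no shared code with the implementation.
    """
    copies = []  # (value, group, pop)
    for g, grp, pop in zip(genotypes, groups, pops):
        if g == MISSING:
            continue
        a = 1 if g >= 1 else 0
        b = 1 if g == 2 else 0
        copies.append((a, grp, pop))
        copies.append((b, grp, pop))
    N = len(copies)
    grand = sum(v for v, _, _ in copies) / N
    pop_ids = sorted({(grp, pop) for _, grp, pop in copies})
    grp_ids = sorted({grp for _, grp, _ in copies})

    def members(pred):
        return [v for v, grp, pop in copies if pred(grp, pop)]

    ss_a = ss_b = ss_c = 0.0
    for grp in grp_ids:
        vals_g = members(lambda g2, p2: g2 == grp)
        mean_g = sum(vals_g) / len(vals_g)
        ss_a += len(vals_g) * (mean_g - grand) ** 2
        for grp2, pop in pop_ids:
            if grp2 != grp:
                continue
            vals_p = members(lambda g2, p2: g2 == grp and p2 == pop)
            mean_p = sum(vals_p) / len(vals_p)
            ss_b += len(vals_p) * (mean_p - mean_g) ** 2
            ss_c += sum((v - mean_p) ** 2 for v in vals_p)

    G_n, P_n = len(grp_ids), len(pop_ids)
    df_a, df_b, df_c = G_n - 1, P_n - G_n, N - P_n
    n_p = {pp: len(members(lambda g2, p2: (g2, p2) == pp)) for pp in pop_ids}
    n_g = {grp: len(members(lambda g2, p2: g2 == grp)) for grp in grp_ids}
    sum_np2_over_ng = sum(
        sum(n_p[pp] ** 2 for pp in pop_ids if pp[0] == grp) / n_g[grp]
        for grp in grp_ids
    )
    sum_np2_over_N = sum(v**2 for v in n_p.values()) / N
    sum_ng2_over_N = sum(v**2 for v in n_g.values()) / N
    n1 = (N - sum_np2_over_ng) / df_b if df_b else float("nan")
    n2 = (sum_np2_over_ng - sum_np2_over_N) / df_a
    n3 = (N - sum_ng2_over_N) / df_a

    sigma_c = ss_c / df_c
    sigma_b = (ss_b / df_b - sigma_c) / n1 if df_b else 0.0
    sigma_a = (ss_a / df_a - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def _random_instance(rng, n_groups=3, pops_per_group=2, diploids=5):
    groups, pops, geno = [], [], []
    for g in range(n_groups):
        for p in range(pops_per_group):
            freq = rng.uniform(0.1, 0.9)
            for _ in range(diploids):
                groups.append(f"G{g}")
                pops.append(f"G{g}P{p}")
                geno.append(rng.binomial(2, freq))
    return np.array(geno, dtype=np.int8), np.array(groups), np.array(pops)


class TestAmovaLocusOracle:
    def test_spec_toy_counts(self):
        # 2 groups x 2 pops x 4 diploids; per-pop allele-2 counts 8,6,2,1
        geno = np.array([2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 0, 0, 1, 0, 0, 0],
                        dtype=np.int8)
        groups = np.array(["A"] * 8 + ["B"] * 8)
        pops = np.array(["A1"] * 4 + ["A2"] * 4 + ["B1"] * 4 + ["B2"] * 4)
        design = rs.HierarchyDesign(groups, pops)
        got = rs.amova_locus(geno, design)
        want = brute_force_amova(geno, groups, pops)
        np.testing.assert_allclose(
            [got["sigma_a"], got["sigma_b"], got["sigma_c"]], want, rtol=1e-9
        )

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        geno, groups, pops = _random_instance(rng)
        # sprinkle missing but keep >= 2 pops typed
        miss = rng.random(len(geno)) < 0.1
        geno[miss] = MISSING
        if len({p for g, p in zip(geno, pops) if g != MISSING}) < 2:
            return
        if not ((geno != MISSING) & (geno > 0)).any():
            return
        design = rs.HierarchyDesign(groups, pops)
        got = rs.amova_locus(geno, design)
        want = brute_force_amova(geno, groups, pops)
        np.testing.assert_allclose(
            [got["sigma_a"], got["sigma_b"], got["sigma_c"]],
            want, rtol=1e-9, atol=1e-12,
        )

    def test_no_structure_means_within_dominates(self):
        rng = np.random.default_rng(3)
        n = 40
        geno = rng.binomial(2, 0.5, 4 * n).astype(np.int8)
        groups = np.repeat(["A", "B"], 2 * n)
        pops = np.repeat(["A1", "A2", "B1", "B2"], n)
        got = rs.amova_locus(geno, rs.HierarchyDesign(groups, pops))
        assert got["pct_c"] > 90.0
        assert abs(got["sigma_a"]) < 0.05 and abs(got["sigma_b"]) < 0.05

    def test_monomorphic_locus_flagged_zero(self):
        geno = np.zeros(12, dtype=np.int8)
        design = rs.HierarchyDesign(
            np.repeat(["A", "B"], 6), np.repeat(["A1", "A2", "B1", "B2"], 3)
        )
        got = rs.amova_locus(geno, design)
        assert got["monomorphic"]
        assert got["sigma_a"] == got["sigma_b"] == got["sigma_c"] == 0.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(4)
        geno, groups, pops = _random_instance(rng)
        got = rs.amova_locus(geno, rs.HierarchyDesign(groups, pops))
        np.testing.assert_allclose(
            got["pct_a"] + got["pct_b"] + got["pct_c"], 100.0, rtol=1e-9
        )


class TestHierarchyDesign:
    def test_pop_in_two_groups_rejected(self):
        with pytest.raises(rs.amova.DesignError, match="more than one group"):
            rs.HierarchyDesign(np.array(["A", "B"]), np.array(["P1", "P1"]))

    def test_single_group_rejected(self):
        with pytest.raises(rs.amova.DesignError, match="two groups"):
            rs.HierarchyDesign(np.array(["A", "A"]), np.array(["P1", "P2"]))


class TestAmovaAll:
    def test_n_perm_zero_rejected(self, study_shaped_panel):
        G, _, _ = study_shaped_panel
        design = rs.HierarchyDesign.from_meta(G.sample_meta)
        with pytest.raises(ValueError, match="n_perm"):
            rs.amova_all(G, design, n_perm=0)

    def test_permutation_p_respects_add_one_bound(self):
        cfg = rs.SimConfig(
            seed=21, n_races=3, f_race=(0.4, 0.4, 0.4), f_loc=0.01,
            n_localities=2, n_diploids_per_locality=6,
            genes_per_category={"control": 20}, snps_per_gene=5,
            selected=None, migrant_rate=0, hybrid_rate=0, missing_rate=0.01,
        )
        G, _ = rs.simulate_panel(cfg)
        design = rs.HierarchyDesign.from_meta(G.sample_meta)
        n_perm = 39
        rep = rs.amova_all(G, design, n_perm=n_perm, seed=5)
        assert (rep.per_locus["p_a"] >= 1.0 / (1 + n_perm) - 1e-12).all()
        assert (rep.per_locus["p_b"] >= 1.0 / (1 + n_perm) - 1e-12).all()
        assert rep.aggregate["p_a"] <= 1.0 and rep.aggregate["p_b"] <= 1.0

    def test_seed_reproducibility(self, study_shaped_panel):
        G, _, _ = study_shaped_panel
        design = rs.HierarchyDesign.from_meta(G.sample_meta)
        r1 = rs.amova_all(G, design, n_perm=19, seed=7)
        r2 = rs.amova_all(G, design, n_perm=19, seed=7)
        pd.testing.assert_frame_equal(r1.per_locus, r2.per_locus)
        pd.testing.assert_series_equal(r1.aggregate, r2.aggregate)

    def test_structured_panel_significant(self, study_shaped_panel):
        G, _, _ = study_shaped_panel
        design = rs.HierarchyDesign.from_meta(G.sample_meta)
        rep = rs.amova_all(G, design, n_perm=99, seed=1)
        assert rep.aggregate["pct_a"] > 20.0
        assert rep.aggregate["p_a"] <= 0.05

    def test_phi_ct_recovery_and_monotonicity(self):
        # aggregate Phi_CT tracks the generator's F_race
        recovered = []
        for f in (0.05, 0.2, 0.5):
            cfg = rs.SimConfig(
                seed=31, n_races=3, f_race=(f, f, f), f_loc=0.02,
                n_localities=2, n_diploids_per_locality=10,
                genes_per_category={"control": 100}, snps_per_gene=5,
                selected=None, migrant_rate=0, hybrid_rate=0, missing_rate=0,
            )
            G, _ = rs.simulate_panel(cfg)
            design = rs.HierarchyDesign.from_meta(G.sample_meta)
            rep = rs.amova_all(G, design, n_perm=1, seed=0)
            recovered.append(rep.aggregate["phi_ct"])
        assert abs(recovered[1] - 0.2) < 0.05
        assert recovered[0] < recovered[1] < recovered[2]


class TestCategorySummary:
    def test_single_category_equals_overall_mean(self, study_shaped_panel):
        G, _, _ = study_shaped_panel
        design = rs.HierarchyDesign.from_meta(G.sample_meta)
        rep = rs.amova_all(G, design, n_perm=1, seed=0)
        ann = G.snp_meta.copy()
        ann["category"] = "only"
        summary = rs.category_summary(rep, ann)
        poly = rep.per_locus[~rep.per_locus["monomorphic"]]
        np.testing.assert_allclose(
            summary.loc["only", "pct_a"], poly["pct_a"].mean()
        )

    def test_planted_category_has_higher_among_group_pct(self):
        cfg = rs.SimConfig(
            seed=41, n_races=2, f_race=(0.05, 0.05), f_loc=0.01,
            n_localities=2, n_diploids_per_locality=12,
            genes_per_category={"chemosensory": 30, "control": 30},
            snps_per_gene=5,
            selected=rs.SelectedSpec(
                n_loci=40, delta=0.6, target_races=(0, 1),
                category="chemosensory", per_gene=5,
            ),
            migrant_rate=0, hybrid_rate=0, missing_rate=0,
        )
        G, _ = rs.simulate_panel(cfg)
        design = rs.HierarchyDesign.from_meta(G.sample_meta)
        rep = rs.amova_all(G, design, n_perm=1, seed=0)
        summary = rs.category_summary(rep, G.snp_meta)
        assert summary.loc["chemosensory", "pct_a"] > summary.loc["control", "pct_a"]


@pytest.fixture(scope="module")
def contaminated_panel():
    cfg = rs.SimConfig(
        seed=0, n_races=4, f_race=(0.3, 0.3, 0.25, 0.2), f_loc=0.01,
        n_localities=2, n_diploids_per_locality=8,
        genes_per_category={"control": 60}, snps_per_gene=5,
        selected=None, migrant_rate=0.05, hybrid_rate=0.03,
        missing_rate=0.01,
    )
    G, truth = rs.simulate_panel(cfg)
    G, _ = rs.filter_snps(G, POLYMORPHIC_ONLY)
    model = rs.fit_pca(rs.standardize(G), 4)
    G2, log = rs.reassign_and_prune(G, model=model)
    return truth, G2, log


class TestReassignAndPrune:
    def test_residents_mostly_untouched(self, contaminated_panel):
        truth, _, log = contaminated_panel
        resid = truth.samples.index[truth.samples["status"] == "resident"]
        wrong = log.loc[resid, "action"].isin(["reassigned", "removed_hybrid"])
        assert wrong.mean() < 0.02

    def test_migrants_relabelled_to_source_race(self, contaminated_panel):
        truth, _, log = contaminated_panel
        migrants = truth.samples.index[truth.samples["status"] == "migrant"]
        assert len(migrants) > 0
        for m in migrants:
            assert log.loc[m, "action"] == "reassigned"
            assert log.loc[m, "new_label"] == truth.samples.loc[m, "true_race"]

    def test_hybrids_removed(self, contaminated_panel):
        truth, G2, log = contaminated_panel
        hybrids = truth.samples.index[truth.samples["status"] == "hybrid"]
        assert len(hybrids) > 0
        for h in hybrids:
            assert log.loc[h, "action"] == "removed_hybrid"
            assert h not in G2.samples
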