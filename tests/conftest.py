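"""Shared fixtures: small genotype matrices and simulated panels."""

import numpy as np
import pandas as pd
import pytest

import racescan as rs

#: thresholds that only remove monomorphic SNPs (needed before PCA)
POLYMORPHIC_ONLY = rs.FilterThresholds(
    min_quality=None,
    required_copy_number=None,
    min_mac=1,
    min_call_rate=None,
    max_het_excess=None,
)


@pytest.fixture
def tiny_matrix() -> rs.GenotypeMatrix:
    """4 samples x 3 SNPs with one missing call and full metadata."""
    calls = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, rs.MISSING, 1],
            [0, 2, 2],
        ],
        dtype=np.int8,
    )
    samples = [f"ind{i}" for i in range(1, 5)]
    snps = ["snpA", "snpB", "snpC"]
    sample_meta = pd.DataFrame(
        {
            "host_race": ["r1", "r1", "r2", "r2"],
            "locality": ["L1", "L1", "L2", "L2"],
            "year": [2012, 2012, 2013, 2013],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    snp_meta = pd.DataFrame(
        {
            "gene_id": ["g1", "g1", "g2"],
            "category": ["chemosensory", "chemosensory", "control"],
            "subfamily": ["Or", "Or", ""],
            "scaffold": ["sc1", "sc1", "sc2"],
            "position": [100, 200, 50],
            "quality": [90.0, 45.0, 99.0],
            "copy_number": [1, 1, 1],
        },
        index=pd.Index(snps, name="snp_id"),
    )
    return rs.GenotypeMatrix(
        calls=calls, samples=samples, snps=snps,
        sample_meta=sample_meta, snp_meta=snp_meta,
    )


@pytest.fixture(scope="session")
def two_pop_panel():
    """Two populations, 50 diploids each, 20 planted loci at separation 0.5."""
    cfg = rs.SimConfig(
        seed=101,
        n_races=2,
        f_race=(0.02, 0.02),
        f_loc=0.0,
        n_localities=1,
        n_diploids_per_locality=50,
        genes_per_category={"chemosensory": 40, "control": 60},
        snps_per_gene=5,
        selected=rs.SelectedSpec(
            n_loci=20, delta=0.5, target_races=(0, 1), per_gene=4
        ),
        migrant_rate=0.0,
        hybrid_rate=0.0,
        missing_rate=0.02,
    )
    G, truth = rs.simulate_panel(cfg)
    G, _ = rs.filter_snps(G, POLYMORPHIC_ONLY)
    return G, truth


@pytest.fixture(scope="session")
def study_shaped_panel():
    """Default 8-race continuum panel (one hyper-diverged race)."""
    cfg = rs.SimConfig(seed=202)
    G, truth = rs.simulate_panel(cfg)
    return G, truth, cfg
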