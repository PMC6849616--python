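"""End-to-end orchestration of the scan, AMOVA and concordance stages.

Each ``run_*`` function takes a :class:`RunConfig` (loadable from YAML),
executes its stage deterministically, writes TSV outputs plus a run log
recording every threshold and seed actually applied, and returns the
in-memory results.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import amova as amova_mod
from . import concordance as conc_mod
from . import enrichment, scan as scan_mod
from .io import (
    FilterThresholds,
    GenotypeMatrix,
    filter_samples,
    filter_snps,
    read_genotype_table,
    read_sample_metadata,
    read_snp_annotation,
)
from .simulate import SelectedSpec, SimConfig, simulate_panel, write_fixture

logger = logging.getLogger("racescan")


@dataclass
class RunConfig:
    """Everything a pipeline stage needs, with study-matched defaults."""

    genotypes: str | None = None
    annotations: str | None = None
    samples: str | None = None
    out_dir: str = "racescan_out"
    missing_code: int = 9
    # filtering
    min_quality: float | None = None
    required_copy_number: int | None = None
    min_mac: int | None = 3
    min_call_rate: float | None = 0.6
    max_het_excess: float | None = 10.0
    max_missing_calls: int | None = None
    # scan
    k: int | None = None
    k_max: int = 20
    alpha: float = 0.05
    qvalue_method: str = "bh"
    exclude_pc: int | None = None
    exclude_threshold: float | None = None
    exclude_race: str | None = None
    # gene tests
    gene_p_threshold: float = 0.05
    min_outliers: int | None = None
    category_a: str = "control"
    category_b: str = "chemosensory"
    # amova
    n_perm: int = 999
    seed: int | None = 0
    reassign: bool = False
    # concordance
    scan_a: str | None = None
    scan_b: str | None = None
    significance: str = "any"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            min_quality=self.min_quality,
            required_copy_number=self.required_copy_number,
            min_mac=self.min_mac,
            min_call_rate=self.min_call_rate,
            max_het_excess=self.max_het_excess,
        )


def _load_panel(config: RunConfig) -> GenotypeMatrix:
    if config.genotypes is None:
        raise ValueError("config.genotypes is required")
    G = read_genotype_table(config.genotypes, missing_code=config.missing_code)
    if config.annotations:
        G = G.with_snp_meta(read_snp_annotation(config.annotations))
    if config.samples:
        G = G.with_sample_meta(read_sample_metadata(config.samples))
    return G


def _setup_run_log(out: Path) -> logging.FileHandler:
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def _log_config(config: RunConfig) -> None:
    for key, value in asdict(config).items():
        logger.info("config %s = %r", key, value)


def run_scan(config: RunConfig) -> dict:
    """filter -> PCA -> scree -> (optional exclusion + K-1 re-run) ->
    component & global scans -> gene & category tests; writes TSVs."""
    out = Path(config.out_dir)
    handler = _setup_run_log(out)
    try:
        _log_config(config)
        G = _load_panel(config)
        G, snp_report = filter_snps(G, config.thresholds())
        if config.max_missing_calls is not None:
            G, sample_report = filter_samples(G, config.max_missing_calls)
            logger.info("filter_samples removed %d samples",
                        sample_report.samples_removed)
        X = scan_mod.standardize(G)
        k_max = min(config.k_max, G.n_samples - 1, G.n_snps)
        scree_table = scan_mod.scree(X, k_max)
        scree_table.to_csv(out / "scree.tsv", sep="\t")
        K = config.k if config.k is not None else scree_table.attrs["elbow"]
        logger.info("scree advisory elbow = %d; using K = %d",
                    scree_table.attrs["elbow"], K)
        model = scan_mod.fit_pca(X, K)

        excluded: list = []
        if config.exclude_race is not None:
            keep = G.sample_meta["host_race"] != config.exclude_race
            excluded = G.samples[~keep].tolist()
            G = G.take_samples(keep.to_numpy())
        elif config.exclude_pc is not None and config.exclude_threshold is not None:
            before = set(G.samples)
            G = scan_mod.exclude_cluster(
                G, model, config.exclude_pc, config.exclude_threshold
            )
            excluded = sorted(before - set(G.samples))
        if excluded:
            K = max(K - 1, 1)
            logger.info("excluded %d samples (%s); re-running with K = %d",
                        len(excluded), ", ".join(map(str, excluded)), K)
            X = scan_mod.standardize(G)
            model = scan_mod.fit_pca(X, K)

        result = scan_mod.component_scan(
            X, model, alpha=config.alpha, typed=G.typed, snps=G.snps,
            qvalue_method=config.qvalue_method,
        )
        result = scan_mod.global_scan(result, config.alpha, config.qvalue_method)
        result.to_tsv(out / "scan.tsv")
        logger.info("scan: %d SNPs, K=%d, inflation=%.4f, alpha=%g",
                    len(result.snps), K, result.inflation, config.alpha)

        scopes = [k + 1 for k in range(result.K)] + ["global"]
        gene_tables = []
        cat_rows = []
        for scope in scopes:
            gene_tables.append(
                enrichment.gene_outlier_test(
                    result, G.snp_meta, scope, alpha=config.alpha,
                    p_threshold=config.gene_p_threshold,
                    min_outliers=config.min_outliers,
                )
            )
            cats = set(G.snp_meta["category"].dropna())
            if {config.category_a, config.category_b} <= cats:
                cat_rows.append(
                    enrichment.category_proportion_test(
                        result, G.snp_meta, scope,
                        cat_a=config.category_a, cat_b=config.category_b,
                        alpha=config.alpha,
                    )
                )
        genes = pd.concat(gene_tables)
        genes.to_csv(out / "gene_tests.tsv", sep="\t", index_label="gene_id")
        categories = pd.DataFrame(cat_rows)
        categories.to_csv(out / "category_tests.tsv", sep="\t", index=False)
        return {
            "genotypes": G,
            "scan": result,
            "model": model,
            "scree": scree_table,
            "genes": genes,
            "categories": categories,
            "filter_report": snp_report,
            "excluded": excluded,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_amova(config: RunConfig) -> amova_mod.AmovaReport:
    """Hierarchical AMOVA by race / locality within race."""
    out = Path(config.out_dir)
    handler = _setup_run_log(out)
    try:
        _log_config(config)
        G = _load_panel(config)
        if G.sample_meta["host_race"].nunique() < 2:
            raise amova_mod.DesignError("AMOVA needs at least two races")
        if config.reassign:
            X = scan_mod.standardize(G)
            K = min(config.k or 6, G.n_samples - 1, G.n_snps)
            model = scan_mod.fit_pca(X, K)
            G, actions = amova_mod.reassign_and_prune(G, model=model)
            actions.to_csv(out / "reassignments.tsv", sep="\t")
            logger.info("reassign_and_prune: %s",
                        actions["action"].value_counts().to_dict())
        design = amova_mod.HierarchyDesign.from_meta(G.sample_meta)
        report = amova_mod.amova_all(
            G, design, n_perm=config.n_perm, seed=config.seed
        )
        report.to_tsv(out / "amova.tsv")
        cats = set(G.snp_meta["category"].dropna())
        if len(cats) >= 2:
            summary = amova_mod.category_summary(report, G.snp_meta)
            summary.to_csv(out / "amova_categories.tsv", sep="\t")
        logger.info("amova aggregate: %s", report.aggregate.to_dict())
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_concordance(config: RunConfig) -> dict:
    """Compare two completed scan outputs (scan.tsv directories)."""
    out = Path(config.out_dir)
    handler = _setup_run_log(out)
    try:
        _log_config(config)
        if config.scan_a is None or config.scan_b is None:
            raise ValueError("scan_a and scan_b directories are required")
        scan_a = _read_scan_tsv(Path(config.scan_a) / "scan.tsv", config.alpha)
        scan_b = _read_scan_tsv(Path(config.scan_b) / "scan.tsv", config.alpha)
        result = conc_mod.compare_scans(
            scan_a, scan_b, n_perm=config.n_perm, seed=config.seed,
            significance=config.significance,
        )
        result["pairing"].to_csv(out / "axis_pairing.tsv", sep="\t")
        result["correlations"].to_frame("r").to_csv(
            out / "loading_correlations.tsv", sep="\t"
        )
        ov = result["overlap"]
        pd.Series(vars(ov)).to_frame("value").to_csv(
            out / "overlap_test.tsv", sep="\t"
        )
        logger.info("overlap: observed=%d of shared=%d, p=%g",
                    ov.observed_overlap, ov.n_shared, ov.p)
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()


def _read_scan_tsv(path, alpha: float) -> scan_mod.ScanResult:
    """Rehydrate a ScanResult from its TSV export."""
    import numpy as np

    df = pd.read_csv(path, sep="\t", index_col="snp_id")
    ks = sorted(
        int(c.split("_pc")[1]) for c in df.columns if c.startswith("loading_pc")
    )
    loadings = np.column_stack([df[f"loading_pc{k}"] for k in ks])
    z = np.column_stack([df[f"z_pc{k}"] for k in ks])
    p = np.column_stack([df[f"p_pc{k}"] for k in ks])
    q = np.column_stack([df[f"q_pc{k}"] for k in ks])
    res = scan_mod.ScanResult(
        snps=df.index, loadings=loadings, z=z, p=p, q=q, alpha=alpha
    )
    if "mahalanobis_d2" in df.columns:
        res.d2 = df["mahalanobis_d2"].to_numpy()
        res.p_global = df["p_global"].to_numpy()
        res.q_global = df["q_global"].to_numpy()
    return res


def run_simulate(sim_config: SimConfig, out_dir) -> dict:
    """Generate a panel and write the fixture files."""
    G, truth = simulate_panel(sim_config)
    paths = write_fixture(G, truth, out_dir)
    return {"genotypes": G, "truth": truth, "paths": paths}
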