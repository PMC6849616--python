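"""Synthetic host-race genotype panels with known ground truth.

The generator emulates the statistical structure the scan assumes: a
set of host races on a divergence continuum (one race hyper-diverged by
default, so the exclude-and-rerun path is exercised), hierarchical
localities within races, SNPs grouped into genes with category labels
(chemosensory / control / P450), divergently selected loci planted as
allele-frequency shifts, occasional migrants and F1 hybrids, and
missing calls.

Allele frequencies follow the Balding-Nichols model: each race's
frequency is Beta-distributed around the ancestral frequency with drift
parameter F_race, and each locality's frequency is drawn the same way
around its race's frequency with F_loc.  Selected loci are modelled as
frequency shifts between target races — the scan only sees frequencies,
so selection coefficients would add nothing testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    GenotypeMatrix,
    write_genotype_table,
    write_sample_metadata,
    write_snp_annotation,
)


@dataclass
class SelectedSpec:
    """Where and how strongly to plant divergently selected loci.

    ``delta`` is the target allele-frequency separation between the two
    ``target_races`` (each is moved delta/2 from the ancestral frequency
    in opposite directions, clipped to [0.01, 0.99]).  Loci are placed
    in genes of ``category``, clustered ``per_gene`` SNPs to a gene to
    mimic multi-SNP outlier genes.
    """

    n_loci: int = 12
    delta: float = 0.5
    target_races: tuple[int, int] = (5, 6)
    category: str = "chemosensory"
    per_gene: int = 4


@dataclass
class SimConfig:
    """Study-shaped defaults: 8 races on a divergence continuum.

    ``f_race`` spans the observed range — a hyper-diverged race at 0.8
    (the near-complete-speciation end, F_ST > 0.8 in sympatry) down to
    0.02 for the most recently diverged pair (multilocus F_ST of
    roughly 0.02-0.08); localities within a race drift with
    ``f_loc`` = 0.02, an order of magnitude below race-level
    divergence, matching the small between-locality variance fraction.
    Two localities per race and 7 diploids per locality keep a full
    default panel around 100 samples, the scale of the capture panel.
    """

    n_races: int = 8
    f_race: tuple[float, ...] = (0.8, 0.35, 0.3, 0.25, 0.15, 0.08, 0.04, 0.02)
    f_loc: float = 0.02
    n_localities: int = 2
    n_diploids_per_locality: int = 7
    genes_per_category: dict = field(
        default_factory=lambda: {"chemosensory": 30, "control": 20, "P450": 10}
    )
    snps_per_gene: int = 5
    selected: SelectedSpec | None = field(default_factory=SelectedSpec)
    migrant_rate: float = 0.02
    hybrid_rate: float = 0.01
    missing_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.f_race) != self.n_races:
            raise ValueError("f_race must have one entry per race")
        for f in self.f_race:
            if not 0.0 <= f < 1.0:
                raise ValueError(f"F_race {f} outside [0, 1)")
        for rate in (self.migrant_rate, self.hybrid_rate, self.missing_rate,
                     self.f_loc):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a config from a YAML file; ``selected`` may be a mapping
        of :class:`SelectedSpec` fields or null to disable planting."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        if "f_race" in data:
            data["f_race"] = tuple(data["f_race"])
        if "selected" in data and data["selected"] is not None:
            sel = data["selected"]
            if "target_races" in sel:
                sel["target_races"] = tuple(sel["target_races"])
            data["selected"] = SelectedSpec(**sel)
        return cls(**data)

    @property
    def race_names(self) -> list[str]:
        return [f"race{r + 1}" for r in range(self.n_races)]

    @property
    def n_loci(self) -> int:
        return sum(self.genes_per_category.values()) * self.snps_per_gene


@dataclass
class SimTruth:
    """Ground-truth ledger for a simulated panel.

    ``loci``: per-locus ancestral frequency, gene/category assignment,
    selected flag and target races.  ``race_freq``: n_races x n_loci.
    ``loc_freq``: (n_races * n_localities) x n_loci, rows ordered race-
    major.  ``samples``: per-sample true race, collection host label,
    locality, migrant/hybrid status (filled by genotype sampling).
    """

    loci: pd.DataFrame
    race_freq: np.ndarray
    loc_freq: np.ndarray | None = None
    samples: pd.DataFrame | None = None


def _balding_nichols(
    rng: np.random.Generator, parent: np.ndarray, F: float
) -> np.ndarray:
    """Beta(p (1-F)/F, (1-p)(1-F)/F) draw; F = 0 is a point mass."""
    if F <= 0.0:
        return parent.copy()
    a = parent * (1.0 - F) / F
    b = (1.0 - parent) * (1.0 - F) / F
    return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)


def _make_annotation(config: SimConfig) -> pd.DataFrame:
    gene_rows = []
    for category, n_genes in config.genes_per_category.items():
        for g in range(n_genes):
            gene_rows.append((f"{category}_g{g + 1}", category))
    snp_rows = []
    subfam = {"chemosensory": "Or", "control": "", "P450": "P450"}
    for gi, (gene_id, category) in enumerate(gene_rows):
        for s in range(config.snps_per_gene):
            snp_rows.append(
                {
                    "snp_id": f"{gene_id}_s{s + 1}",
                    "gene_id": gene_id,
                    "category": category,
                    "subfamily": subfam.get(category, ""),
                    "scaffold": f"scaffold{gi + 1}",
                    "position": 1000 * (s + 1),
                    "quality": 99.0,
                    "copy_number": 1,
                }
            )
    return pd.DataFrame(snp_rows).set_index("snp_id")


def simulate_frequencies(config: SimConfig, rng=None) -> SimTruth:
    """Draw ancestral, race and locality allele frequencies.

    Ancestral frequencies are Uniform(0.05, 0.95); race and locality
    frequencies follow the Balding-Nichols hierarchy.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    annotation = _make_annotation(config)
    n_loci = len(annotation)
    ancestral = rng.uniform(0.05, 0.95, size=n_loci)
    race_freq = np.vstack(
        [_balding_nichols(rng, ancestral, f) for f in config.f_race]
    )
    loci = annotation.reset_index().assign(
        ancestral=ancestral, selected=False, target_a=-1, target_b=-1
    ).set_index("snp_id")
    truth = SimTruth(loci=loci, race_freq=race_freq)
    _draw_locality_freqs(truth, config, rng)
    return truth


def _draw_locality_freqs(truth: SimTruth, config: SimConfig, rng) -> None:
    rows = []
    for r in range(config.n_races):
        for _ in range(config.n_localities):
            rows.append(_balding_nichols(rng, truth.race_freq[r], config.f_loc))
    truth.loc_freq = np.vstack(rows)


def plant_outliers(
    truth: SimTruth, spec: SelectedSpec, config: SimConfig, rng=None
) -> SimTruth:
    """Shift target races' frequencies apart at selected loci.

    Loci are chosen from genes of the configured category, clustered
    ``per_gene`` to a gene; the two target races move to
    ancestral +/- delta/2 (clipped to [0.01, 0.99]); locality
    frequencies of the affected races are redrawn around the shifted
    race frequencies.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if spec.delta == 0.0 or spec.n_loci == 0:
        return truth
    ra, rb = spec.target_races
    eligible_genes = truth.loci.loc[
        truth.loci["category"] == spec.category, "gene_id"
    ].unique()
    chosen: list[str] = []
    for gene in rng.permutation(eligible_genes):
        gene_snps = truth.loci.index[truth.loci["gene_id"] == gene]
        take = gene_snps[: spec.per_gene]
        chosen.extend(take)
        if len(chosen) >= spec.n_loci:
            break
    if len(chosen) < spec.n_loci:
        raise ValueError(
            f"only {len(chosen)} eligible loci in category {spec.category!r}; "
            f"{spec.n_loci} requested"
        )
    chosen = chosen[: spec.n_loci]
    idx = truth.loci.index.get_indexer(chosen)
    p0 = truth.loci["ancestral"].to_numpy()[idx]
    half = spec.delta / 2.0
    if spec.delta > 0.98:
        raise ValueError("delta must leave both frequencies inside [0.01, 0.99]")
    # recentre where needed so the full separation delta is realized
    centre = np.clip(p0, 0.01 + half, 0.99 - half)
    truth.race_freq[ra, idx] = centre + half
    truth.race_freq[rb, idx] = centre - half
    truth.loci.loc[chosen, "selected"] = True
    truth.loci.loc[chosen, "target_a"] = ra
    truth.loci.loc[chosen, "target_b"] = rb
    # redraw locality frequencies around the shifted race frequencies
    for r in (ra, rb):
        for li in range(config.n_localities):
            row = r * config.n_localities + li
            truth.loc_freq[row, idx] = _balding_nichols(
                rng, truth.race_freq[r, idx], config.f_loc
            )
    return truth


def sample_genotypes(
    truth: SimTruth, config: SimConfig, rng=None
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw diploid genotypes under Hardy-Weinberg within locality.

    Migrants (probability ``migrant_rate``) get a genotype drawn from a
    random other race while keeping the collection-host label of the
    sampling locality; hybrids (``hybrid_rate``) get one allele from
    their own locality and one from another race (F1).  Calls are
    masked missing independently at ``missing_rate``.  The sample
    metadata's ``host_race`` is the collection host, so migrants carry a
    label that disagrees with their genotype source — as in field data.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_loci = len(truth.loci)
    races = config.race_names
    sample_rows = []
    calls = []
    sid = 0
    for r in range(config.n_races):
        for li in range(config.n_localities):
            f_local = truth.loc_freq[r * config.n_localities + li]
            for _ in range(config.n_diploids_per_locality):
                sid += 1
                u = rng.random()
                status, true_race = "resident", r
                if u < config.migrant_rate and config.n_races > 1:
                    status = "migrant"
                    others = [x for x in range(config.n_races) if x != r]
                    true_race = int(rng.choice(others))
                    src = truth.loc_freq[
                        true_race * config.n_localities
                        + int(rng.integers(config.n_localities))
                    ]
                    g = rng.binomial(2, src)
                elif u < config.migrant_rate + config.hybrid_rate and config.n_races > 1:
                    status = "hybrid"
                    others = [x for x in range(config.n_races) if x != r]
                    other = int(rng.choice(others))
                    src = truth.loc_freq[
                        other * config.n_localities
                        + int(rng.integers(config.n_localities))
                    ]
                    g = rng.binomial(1, f_local) + rng.binomial(1, src)
                    true_race = r  # one parental side local
                else:
                    g = rng.binomial(2, f_local)
                g = g.astype(np.int8)
                if config.missing_rate > 0:
                    g[rng.random(n_loci) < config.missing_rate] = MISSING
                calls.append(g)
                sample_rows.append(
                    {
                        "sample_id": f"s{sid:04d}",
                        "host_race": races[r],
                        "locality": f"{races[r]}_L{li + 1}",
                        "year": 2012 + int(rng.integers(2)),
                        "true_race": races[true_race],
                        "status": status,
                        "hybrid_other_race": races[other] if status == "hybrid" else "",
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    G = GenotypeMatrix(
        calls=np.vstack(calls),
        samples=samples.index,
        snps=truth.loci.index,
        sample_meta=samples[["host_race", "locality", "year"]],
        snp_meta=truth.loci[
            ["gene_id", "category", "subfamily", "scaffold", "position",
             "quality", "copy_number"]
        ],
    )
    truth.samples = samples
    return G, truth


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Full pipeline: frequencies -> planted outliers -> genotypes."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_frequencies(config, rng)
    if config.selected is not None:
        plant_outliers(truth, config.selected, config, rng)
    return sample_genotypes(truth, config, rng)


# ----------------------------------------------------------------------
# Fixture output
# ----------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 rendering of a genotype matrix (biallelic A/T)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        scaffolds = G.snp_meta["scaffold"].fillna("chr1")
        for contig in pd.unique(scaffolds):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, G.samples))
            + "\n"
        )
        positions = pd.to_numeric(G.snp_meta["position"], errors="coerce")
        quals = pd.to_numeric(G.snp_meta["quality"], errors="coerce")
        for j, snp in enumerate(G.snps):
            pos = int(positions.iloc[j]) if np.isfinite(positions.iloc[j]) else j + 1
            qual = quals.iloc[j]
            qual_s = f"{qual:g}" if np.isfinite(qual) else "."
            gts = "\t".join(gt_strings[int(g)] for g in G.calls[:, j])
            fh.write(
                f"{scaffolds.iloc[j]}\t{pos}\t{snp}\tA\tT\t{qual_s}\t.\t.\tGT\t{gts}\n"
            )


def write_fixture(G: GenotypeMatrix, truth: SimTruth, directory) -> dict:
    """Emit the full fixture: 012 table, annotation, samples, truth, VCF."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": d / "genotypes.tsv",
        "snps": d / "snps.tsv",
        "samples": d / "samples.tsv",
        "truth_loci": d / "truth_loci.tsv",
        "truth_samples": d / "truth_samples.tsv",
        "vcf": d / "panel.vcf",
    }
    write_genotype_table(G, paths["genotypes"])
    write_snp_annotation(G.snp_meta, paths["snps"])
    write_sample_metadata(G.sample_meta, paths["samples"])
    truth.loci.to_csv(paths["truth_loci"], sep="\t")
    if truth.samples is not None:
        truth.samples.to_csv(paths["truth_samples"], sep="\t")
    write_vcf(G, paths["vcf"])
    return paths
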