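"""Reading, annotating, filtering and writing SNP genotype matrices.

Genotypes are diploid allele-dosage codes: 0 = homozygous reference (AA),
1 = heterozygous (AB), 2 = homozygous alternate (BB).  Missing calls are
stored internally as :data:`MISSING` (-1); on disk the missing code is
configurable and defaults to 9, the convention used by GoldenGate-style
genotype tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("racescan")

#: Internal missing-genotype code.
MISSING: int = -1

#: Allowed internal genotype codes.
VALID_CODES = frozenset({0, 1, 2, MISSING})

SNP_META_COLUMNS = [
    "gene_id",
    "category",
    "subfamily",
    "scaffold",
    "position",
    "quality",
    "copy_number",
]

SAMPLE_META_COLUMNS = ["host_race", "locality", "year"]


class GenotypeError(ValueError):
    """Malformed genotype input (bad codes, duplicate IDs, shape mismatch)."""


class EmptyPanelError(GenotypeError):
    """A filter removed every SNP or every sample."""


def _empty_snp_meta(snps: pd.Index) -> pd.DataFrame:
    meta = pd.DataFrame(index=snps, columns=SNP_META_COLUMNS)
    meta["category"] = "other"
    return meta


def _empty_sample_meta(samples: pd.Index) -> pd.DataFrame:
    return pd.DataFrame(index=samples, columns=SAMPLE_META_COLUMNS)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs diploid genotype matrix with metadata.

    Parameters
    ----------
    calls
        Integer array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2, MISSING}``.
    samples, snps
        Unique, ordered identifiers for the rows and columns.
    sample_meta
        Per-sample table indexed by sample ID with columns
        ``host_race``, ``locality``, ``year`` (extra columns allowed).
    snp_meta
        Per-SNP annotation indexed by SNP ID with columns ``gene_id``,
        ``category``, ``subfamily``, ``scaffold``, ``position``,
        ``quality``, ``copy_number``.  ``category`` defaults to "other".
    """

    calls: np.ndarray
    samples: pd.Index
    snps: pd.Index
    sample_meta: pd.DataFrame = None  # type: ignore[assignment]
    snp_meta: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.samples = pd.Index(self.samples, name="sample_id")
        self.snps = pd.Index(self.snps, name="snp_id")
        if self.calls.ndim != 2:
            raise GenotypeError("calls must be a 2-D array")
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.samples.has_duplicates:
            dup = self.samples[self.samples.duplicated()].tolist()
            raise GenotypeError(f"duplicate sample IDs: {dup}")
        if self.snps.has_duplicates:
            dup = self.snps[self.snps.duplicated()].tolist()
            raise GenotypeError(f"duplicate SNP IDs: {dup}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid genotype code {self.calls[i, j]} at sample "
                f"{self.samples[i]!r}, SNP {self.snps[j]!r}"
            )
        if self.sample_meta is None:
            self.sample_meta = _empty_sample_meta(self.samples)
        else:
            self.sample_meta = self.sample_meta.reindex(self.samples)
        if self.snp_meta is None:
            self.snp_meta = _empty_snp_meta(self.snps)
        else:
            self.snp_meta = self.snp_meta.reindex(self.snps)
            if "category" not in self.snp_meta.columns:
                self.snp_meta["category"] = "other"
            self.snp_meta["category"] = self.snp_meta["category"].fillna("other")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def typed(self) -> np.ndarray:
        """Boolean mask of non-missing calls, same shape as ``calls``."""
        return self.calls != MISSING

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the alternate (dosage-counted) allele.

        Computed over typed individuals only: ``p_j = sum(g_ij) / (2 n_typed)``.
        SNPs with no typed call get ``nan``.
        """
        typed = self.typed
        n_typed = typed.sum(axis=0)
        alt = np.where(typed, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_typed > 0, alt / (2.0 * n_typed), np.nan)

    def take_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            calls=self.calls[keep],
            samples=self.samples[keep],
            snps=self.snps,
            sample_meta=self.sample_meta.iloc[keep],
            snp_meta=self.snp_meta,
        )

    def take_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            calls=self.calls[:, keep],
            samples=self.samples,
            snps=self.snps[keep],
            sample_meta=self.sample_meta,
            snp_meta=self.snp_meta.iloc[keep],
        )

    def with_sample_meta(self, meta: pd.DataFrame) -> "GenotypeMatrix":
        return replace(self, sample_meta=meta.reindex(self.samples))

    def with_snp_meta(self, meta: pd.DataFrame) -> "GenotypeMatrix":
        return replace(self, snp_meta=meta.reindex(self.snps))


@dataclass
class FilterReport:
    """Bookkeeping for a filtering step.

    ``snps_removed`` maps rule name -> number of SNPs attributed to that
    rule (a SNP counts against the FIRST rule it fails, in application
    order).  Invariant: removed + survived equals the input count on each
    axis.
    """

    n_snps_in: int
    n_samples_in: int
    snps_removed: dict[str, int] = field(default_factory=dict)
    samples_removed: int = 0
    n_snps_out: int = 0
    n_samples_out: int = 0

    def validate(self) -> None:
        if self.n_snps_in - sum(self.snps_removed.values()) != self.n_snps_out:
            raise AssertionError("SNP removal counts do not sum to dimension change")
        if self.n_samples_in - self.samples_removed != self.n_samples_out:
            raise AssertionError("sample removal count does not match dimension change")


# ----------------------------------------------------------------------
# Delimited 012 tables
# ----------------------------------------------------------------------

def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_genotype_table(
    path,
    missing_code: int = 9,
    orientation: str = "samples-as-rows",
    delimiter: str | None = None,
) -> GenotypeMatrix:
    """Read a delimited 012 genotype table.

    The first column holds IDs, the header row holds the other axis's IDs.
    ``orientation`` is ``"samples-as-rows"`` (default, the supplementary
    table layout) or ``"snps-as-rows"``.
    """
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise GenotypeError(f"empty genotype table: {path}")
    try:
        values = df.to_numpy(dtype=str).astype(int)
    except ValueError:
        for col in df.columns:
            for row in df.index:
                cell = df.at[row, col]
                try:
                    int(cell)
                except (TypeError, ValueError):
                    raise GenotypeError(
                        f"non-integer genotype {cell!r} at row {row!r}, "
                        f"column {col!r} in {path}"
                    ) from None
        raise
    if orientation == "snps-as-rows":
        values = values.T
        samples, snps = pd.Index(df.columns), pd.Index(df.index)
    elif orientation == "samples-as-rows":
        samples, snps = pd.Index(df.index), pd.Index(df.columns)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    values = np.where(values == missing_code, MISSING, values)
    G = GenotypeMatrix(calls=values, samples=samples, snps=snps)
    logger.info(
        "read %d samples x %d SNPs from %s", G.n_samples, G.n_snps, path
    )
    return G


def write_genotype_table(
    G: GenotypeMatrix,
    path,
    missing_code: int = 9,
    orientation: str = "samples-as-rows",
    delimiter: str = "\t",
) -> None:
    """Write the 012 table; inverse of :func:`read_genotype_table`."""
    values = np.where(G.calls == MISSING, missing_code, G.calls)
    df = pd.DataFrame(values, index=G.samples, columns=G.snps)
    if orientation == "snps-as-rows":
        df = df.T
    df.to_csv(path, sep=delimiter)


def read_snp_annotation(path) -> pd.DataFrame:
    """Read the SNP annotation TSV (snp_id, gene_id, category, ...)."""
    meta = pd.read_csv(path, sep="\t", index_col="snp_id")
    if meta.index.has_duplicates:
        raise GenotypeError(f"duplicate snp_id in annotation {path}")
    for col in SNP_META_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    meta["category"] = meta["category"].fillna("other")
    return meta


def write_snp_annotation(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="snp_id")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, host_race, locality, year)."""
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    if meta.index.has_duplicates:
        raise GenotypeError(f"duplicate sample_id in metadata {path}")
    return meta


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def read_vcf(path) -> tuple[GenotypeMatrix, FilterReport]:
    """Read a diploid VCF into a genotype matrix.

    GT fields are converted to alternate-allele dosage (0/0 -> 0,
    0/1 -> 1, 1/1 -> 2, ./. -> MISSING).  QUAL is stored in
    ``snp_meta["quality"]``.  Multi-allelic sites are skipped with a
    warning and counted in the returned report.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = pd.Index(vcf.samples, name="sample_id")
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    quals: list[float] = []
    scaffolds: list[str] = []
    positions: list[int] = []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            warnings.warn(
                f"skipping multi-allelic site {var.CHROM}:{var.POS}",
                stacklevel=2,
            )
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
        quals.append(var.QUAL if var.QUAL is not None else np.nan)
        scaffolds.append(var.CHROM)
        positions.append(var.POS)
    vcf.close()
    if not rows:
        raise GenotypeError(f"no usable biallelic sites in {path}")
    calls = np.stack(rows, axis=1)
    snps = pd.Index(snp_ids, name="snp_id")
    meta = _empty_snp_meta(snps)
    meta["quality"] = quals
    meta["scaffold"] = scaffolds
    meta["position"] = positions
    G = GenotypeMatrix(calls=calls, samples=samples, snps=snps, snp_meta=meta)
    report = FilterReport(
        n_snps_in=len(snp_ids) + n_multiallelic,
        n_samples_in=len(samples),
        snps_removed={"multiallelic": n_multiallelic},
        n_snps_out=G.n_snps,
        n_samples_out=G.n_samples,
    )
    report.validate()
    return G, report


# ----------------------------------------------------------------------
# Filters
# ----------------------------------------------------------------------

@dataclass
class FilterThresholds:
    """Capture-style SNP filters; any threshold may be None (disabled).

    Applied in order: quality, copy number, minor allele count, call
    rate, heterozygote excess.  The heterozygote rule removes a SNP when
    the observed heterozygote count exceeds the Hardy-Weinberg
    expectation ``2 n_typed p (1-p)`` by more than ``max_het_excess``.
    """

    min_quality: float | None = 40.0
    required_copy_number: int | None = 1
    min_mac: int | None = 3
    min_call_rate: float | None = 0.6
    max_het_excess: float | None = 10.0


def filter_snps(
    G: GenotypeMatrix, thresholds: FilterThresholds | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove SNPs failing any active rule.

    Each removed SNP is attributed to the first rule it fails, in
    application order.  Raises :class:`EmptyPanelError` if nothing
    survives.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    t = thresholds
    typed = G.typed
    n_typed = typed.sum(axis=0)
    alt = np.where(typed, G.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(n_typed > 0, alt / (2.0 * n_typed), np.nan)
    removed = np.zeros(G.n_snps, dtype=bool)
    report = FilterReport(n_snps_in=G.n_snps, n_samples_in=G.n_samples)

    def apply(name: str, fails: np.ndarray) -> None:
        newly = fails & ~removed
        report.snps_removed[name] = int(newly.sum())
        removed[newly] = True

    if t.min_quality is not None:
        quality = pd.to_numeric(G.snp_meta["quality"], errors="coerce").to_numpy(float)
        apply("quality", quality < t.min_quality)
    if t.required_copy_number is not None:
        cn = pd.to_numeric(G.snp_meta["copy_number"], errors="coerce").to_numpy(float)
        apply("copy_number", ~np.isclose(cn, t.required_copy_number) | np.isnan(cn))
    if t.min_mac is not None:
        mac = np.minimum(alt, 2 * n_typed - alt)
        apply("minor_allele_count", mac < t.min_mac)
    if t.min_call_rate is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            call_rate = n_typed / max(G.n_samples, 1)
        apply("call_rate", call_rate < t.min_call_rate)
    if t.max_het_excess is not None:
        obs_het = np.where(typed, G.calls == 1, False).sum(axis=0)
        exp_het = 2.0 * n_typed * p_hat * (1.0 - p_hat)
        with np.errstate(invalid="ignore"):
            apply("het_excess", obs_het > exp_het + t.max_het_excess)

    keep = ~removed
    if not keep.any():
        raise EmptyPanelError("all SNPs removed by filters: empty panel")
    out = G.take_snps(keep)
    report.n_snps_out = out.n_snps
    report.n_samples_out = out.n_samples
    report.validate()
    logger.info(
        "filter_snps: %d -> %d SNPs (%s)",
        G.n_snps,
        out.n_snps,
        ", ".join(f"{k}={v}" for k, v in report.snps_removed.items()),
    )
    return out, report


def filter_samples(
    G: GenotypeMatrix, max_missing_calls: int
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove samples with more than ``max_missing_calls`` missing calls."""
    if max_missing_calls < 0:
        raise ValueError("max_missing_calls must be >= 0")
    n_missing = (~G.typed).sum(axis=1)
    keep = n_missing <= max_missing_calls
    if not keep.any():
        raise EmptyPanelError("all samples removed: empty panel")
    out = G.take_samples(keep)
    report = FilterReport(
        n_snps_in=G.n_snps,
        n_samples_in=G.n_samples,
        samples_removed=int((~keep).sum()),
        n_snps_out=out.n_snps,
        n_samples_out=out.n_samples,
    )
    report.validate()
    return out, report
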