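"""Shared in-memory containers for genotype, phenotype and annotation data.

Dosages are held as a dense float matrix (individuals x SNPs) with ``NaN``
marking missing genotypes; SNP metadata travels alongside in a DataFrame so
that QC and annotation can be expressed as ordinary pandas operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel chromosome label for SNPs that failed to map to the assembly
UNMAPPED = "0"

SNP_META_COLUMNS = ["snp", "chrom", "pos", "allele_counted", "allele_other"]


@dataclass
class GenotypeMatrix:
    """Additive-dosage genotypes (0/1/2, NaN = missing) plus SNP metadata.

    ``snp_meta`` has one row per column of ``dosage`` with columns
    ``snp, chrom, pos, allele_counted, allele_other``; positions are 1-based
    and strictly increasing within each mapped chromosome.
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D individuals x SNPs matrix")
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_meta)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.snp_meta)} SNPs"
            )
        missing = set(SNP_META_COLUMNS) - set(self.snp_meta.columns)
        if missing:
            raise ValueError(f"snp_meta missing columns: {sorted(missing)}")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.snp_meta["snp"])

    def counted_allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele among observed genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency; 0 where every genotype is missing."""
        p = self.counted_allele_freq()
        p = np.where(np.isnan(p), 0.0, p)
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def is_mapped(self) -> np.ndarray:
        chrom = self.snp_meta["chrom"].astype(str).to_numpy()
        pos = self.snp_meta["pos"].to_numpy()
        return (chrom != UNMAPPED) & (pos > 0)

    def take_snps(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNP columns by boolean mask or integer index array."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            snp_meta=self.snp_meta.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def take_samples(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosage=self.dosage[idx, :],
            snp_meta=self.snp_meta,
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing entries replaced by the per-SNP mean."""
        x = self.dosage.copy()
        nan = np.isnan(x)
        if nan.any():
            with np.errstate(invalid="ignore"):
                mean = np.nanmean(x, axis=0)
            mean = np.where(np.isnan(mean), 0.0, mean)
            x[nan] = np.broadcast_to(mean, x.shape)[nan]
        return x


@dataclass
class TraitSpec:
    """Per-trait analysis options: which batch factor enters the model and
    whether the trait is log-transformed before analysis."""

    batch_factor: str = "batch"
    log_transform: bool = False


@dataclass
class TraitTable:
    """Phenotypes (individuals x traits) plus the covariate factors used as
    fixed effects (sex and one of two batch factors)."""

    sample_ids: list[str]
    traits: pd.DataFrame
    covariates: pd.DataFrame
    trait_specs: dict[str, TraitSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.traits) != len(self.sample_ids):
            raise ValueError("traits rows must match sample_ids")
        if len(self.covariates) != len(self.sample_ids):
            raise ValueError("covariates rows must match sample_ids")
        for name in self.traits.columns:
            self.trait_specs.setdefault(name, TraitSpec())

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def spec(self, trait: str) -> TraitSpec:
        return self.trait_specs.get(trait, TraitSpec())

    def trait_values(self, trait: str) -> np.ndarray:
        """Analysis-ready values: log-transformed when the spec says so."""
        if trait not in self.traits.columns:
            raise KeyError(f"unknown trait {trait!r}")
        y = self.traits[trait].to_numpy(dtype=float)
        if self.spec(trait).log_transform:
            ok = ~np.isnan(y)
            if np.any(y[ok] <= 0):
                raise ValueError(
                    f"trait {trait!r} has non-positive values; cannot log-transform"
                )
            y = np.where(ok, np.log(np.where(ok, y, 1.0)), np.nan)
        return y


@dataclass
class GeneAnnotation:
    """Gene intervals (1-based, closed) with regulator flags.

    ``genes`` columns: gene_id, symbol, chrom, start, end, strand,
    is_regulator.
    """

    genes: pd.DataFrame

    REQUIRED = ["gene_id", "symbol", "chrom", "start", "end", "strand", "is_regulator"]

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.genes.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids: {sorted(set(dup))[:5]}")
        bad = self.genes["start"] > self.genes["end"]
        if bad.any():
            raise ValueError("gene intervals with start > end")
        self.genes = self.genes.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)

    def flag_regulators(self, census: list[str]) -> "GeneAnnotation":
        """Return a copy with is_regulator set by case-insensitive symbol
        match against the census."""
        wanted = {s.strip().upper() for s in census if s.strip()}
        genes = self.genes.copy()
        genes["is_regulator"] = (
            genes["symbol"].astype(str).str.upper().isin(wanted)
        )
        return GeneAnnotation(genes)
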