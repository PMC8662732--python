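"""SNP quality control.

Filtering rules, applied in order with each removed SNP attributed to the
first rule it fails: minor allele frequency below the threshold, missingness
above the threshold, and no valid map position.  Boundary conventions:
MAF >= maf_min is retained, missingness <= miss_max is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_maf: int
    removed_missing: int
    removed_unmapped: int
    maf_min: float
    miss_max: float
    removed_snps: dict[str, str] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_maf": self.removed_maf,
            "removed_missing": self.removed_missing,
            "removed_unmapped": self.removed_unmapped,
            "maf_min": self.maf_min,
            "miss_max": self.miss_max,
        }


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.10,
    mapped_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter a SNP panel; raises if nothing survives.

    A SNP with every genotype missing has MAF 0 and is removed by the MAF
    rule (first in order).
    """
    maf = geno.maf()
    missingness = 1.0 - geno.call_rate()
    mapped = geno.is_mapped()

    fail_maf = maf < maf_min
    fail_miss = (missingness > miss_max) & ~fail_maf
    fail_map = (~mapped) & ~fail_maf & ~fail_miss if mapped_only else np.zeros_like(fail_maf)
    keep = ~(fail_maf | fail_miss | fail_map)

    snp_ids = geno.snp_meta["snp"].to_numpy()
    removed: dict[str, str] = {}
    for rule, mask in (("maf", fail_maf), ("missing", fail_miss), ("unmapped", fail_map)):
        for s in snp_ids[mask]:
            removed[s] = rule

    report = QCReport(
        n_input=geno.n_snps,
        n_retained=int(keep.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_missing=int(fail_miss.sum()),
        removed_unmapped=int(fail_map.sum()),
        maf_min=maf_min,
        miss_max=miss_max,
        removed_snps=removed,
    )
    if report.n_retained == 0:
        raise ValueError(
            f"QC removed every SNP (maf: {report.removed_maf}, "
            f"missing: {report.removed_missing}, unmapped: {report.removed_unmapped})"
        )
    return geno.take_snps(keep), report
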