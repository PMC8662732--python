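"""Readers and writers for the study's on-disk formats.

Genotypes travel as PLINK text (.ped/.map) or additive dosage (.raw),
phenotypes as TSV, gene annotation as GFF3 (1-based closed; BED input is
converted on read), and the regulator census as one symbol per line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    SNP_META_COLUMNS,
    UNMAPPED,
    GeneAnnotation,
    GenotypeMatrix,
    TraitSpec,
    TraitTable,
)

PLINK_LEAD_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


# ---------------------------------------------------------------- PLINK text

def write_plink_ped_map(ped_path, map_path, geno: GenotypeMatrix) -> None:
    """Write white-space separated .ped/.map; missing genotype = '0 0'."""
    meta = geno.snp_meta
    with open(map_path, "w") as fh:
        for _, row in meta.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['pos']}\n")

    counted = meta["allele_counted"].to_numpy()
    other = meta["allele_other"].to_numpy()
    dosage = geno.dosage
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(geno.sample_ids):
            fields = [iid, iid, "0", "0", "0", "-9"]
            row = dosage[i]
            for j in range(geno.n_snps):
                d = row[j]
                if np.isnan(d):
                    fields.extend(["0", "0"])
                else:
                    d = int(round(d))
                    fields.extend([counted[j]] * d + [other[j]] * (2 - d))
            fh.write(" ".join(fields) + "\n")


def read_plink_ped_map(ped_path, map_path, counted_allele: str = "B") -> GenotypeMatrix:
    """Read .ped/.map into dosages of ``counted_allele``.

    ``counted_allele`` may be a literal allele symbol (the fixture writer
    uses B) or ``"minor"`` to count the per-SNP minor allele (ties broken
    toward the lexicographically later symbol).
    """
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos"], dtype={"chrom": str},
    )
    m = len(mp)
    raw = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    if raw.shape[1] != 6 + 2 * m:
        raise ValueError(
            f".ped has {raw.shape[1]} columns; expected {6 + 2 * m} for {m} SNPs"
        )
    sample_ids = raw.iloc[:, 1].tolist()
    a1 = raw.iloc[:, 6::2].to_numpy(dtype=object)
    a2 = raw.iloc[:, 7::2].to_numpy(dtype=object)

    counted = np.empty(m, dtype=object)
    other = np.empty(m, dtype=object)
    dosage = np.full((len(sample_ids), m), np.nan)
    for j in range(m):
        col = np.concatenate([a1[:, j], a2[:, j]])
        alleles, counts = np.unique(col[col != "0"], return_counts=True)
        if len(alleles) == 0:
            counted[j], other[j] = "B", "A"
            continue
        if counted_allele == "minor":
            ties = alleles[counts == counts.min()]
            cnt = sorted(ties)[-1]  # rarest allele, ties to the later symbol
        else:
            # literal counted allele: dosage 0 everywhere if it never occurs
            cnt = counted_allele
        oth = [a for a in alleles if a != cnt]
        counted[j] = cnt
        other[j] = oth[0] if oth else ("A" if cnt != "A" else "B")
        miss = (a1[:, j] == "0") | (a2[:, j] == "0")
        d = (a1[:, j] == cnt).astype(float) + (a2[:, j] == cnt).astype(float)
        d[miss] = np.nan
        dosage[:, j] = d

    snp_meta = pd.DataFrame(
        {
            "snp": mp["snp"],
            "chrom": mp["chrom"].astype(str),
            "pos": mp["pos"].astype(np.int64),
            "allele_counted": counted,
            "allele_other": other,
        }
    )
    return GenotypeMatrix(dosage=dosage, snp_meta=snp_meta, sample_ids=sample_ids)


def write_plink_raw(path, geno: GenotypeMatrix) -> None:
    """Write PLINK additive dosage (.raw): header then 0/1/2/NA."""
    meta = geno.snp_meta
    header = PLINK_LEAD_COLS + [
        f"{s}_{a}" for s, a in zip(meta["snp"], meta["allele_counted"])
    ]
    n = geno.n_individuals
    lead = pd.DataFrame(
        {
            "FID": geno.sample_ids,
            "IID": geno.sample_ids,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": -9,
        }
    )
    body = pd.DataFrame(geno.dosage, columns=header[6:])
    out = pd.concat([lead, body], axis=1)
    out.columns = header
    out.to_csv(path, sep=" ", index=False, na_rep="NA", float_format="%g")


def read_plink_raw(path, snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a .raw additive dosage file.

    The .raw dialect does not carry chromosome/position, so either pass
    ``snp_meta`` (e.g. from the .map) or positions default to unmapped.
    """
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    if list(df.columns[:6]) != PLINK_LEAD_COLS:
        raise ValueError(".raw header must start with FID IID PAT MAT SEX PHENOTYPE")
    sample_ids = df["IID"].astype(str).tolist()
    snp_cols = df.columns[6:]
    snps, counted = [], []
    for c in snp_cols:
        name, _, allele = c.rpartition("_")
        snps.append(name)
        counted.append(allele)
    dosage = df[snp_cols].to_numpy(dtype=float)
    if snp_meta is not None:
        meta = snp_meta.set_index("snp").loc[snps].reset_index()
        meta["allele_counted"] = counted
    else:
        meta = pd.DataFrame(
            {
                "snp": snps,
                "chrom": UNMAPPED,
                "pos": -1,
                "allele_counted": counted,
                "allele_other": "?",
            }
        )
    return GenotypeMatrix(dosage=dosage, snp_meta=meta[SNP_META_COLUMNS], sample_ids=sample_ids)


# ---------------------------------------------------------------- phenotypes

def write_phenotypes(path, traits: TraitTable) -> None:
    out = pd.concat(
        [
            pd.DataFrame({"iid": traits.sample_ids}),
            traits.covariates.reset_index(drop=True),
            traits.traits.reset_index(drop=True),
        ],
        axis=1,
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_phenotypes(
    path,
    covariate_cols: tuple[str, ...] = ("sex", "batch", "lab_batch"),
    trait_specs: dict[str, TraitSpec] | None = None,
) -> TraitTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={c: str for c in covariate_cols})
    if "iid" not in df.columns:
        raise ValueError("phenotype TSV must have an 'iid' column")
    cov = [c for c in covariate_cols if c in df.columns]
    trait_cols = [c for c in df.columns if c != "iid" and c not in cov]
    return TraitTable(
        sample_ids=df["iid"].astype(str).tolist(),
        traits=df[trait_cols].astype(float),
        covariates=df[cov],
        trait_specs=dict(trait_specs) if trait_specs else {},
    )


# ---------------------------------------------------------------- annotation

def write_gff3(path, annotation: GeneAnnotation) -> None:
    """Write gene features as GFF3 (1-based, closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in annotation.genes.iterrows():
            attrs = f"ID={g['gene_id']};Name={g['symbol']}"
            fh.write(
                f"{g['chrom']}\tawmnet\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\t{attrs}\n"
            )


def read_gff3(path) -> GeneAnnotation:
    """Read 'gene' features from GFF3 into a GeneAnnotation."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        sym = feat.attributes.get("Name", [gid])[0]
        rows.append(
            {
                "gene_id": gid,
                "symbol": sym,
                "chrom": str(feat.seqid),
                "start": int(feat.start),
                "end": int(feat.end),
                "strand": feat.strand or ".",
                "is_regulator": False,
            }
        )
    if not rows:
        raise ValueError(f"no gene features found in {path}")
    return GeneAnnotation(pd.DataFrame(rows))


def read_bed(path) -> GeneAnnotation:
    """Read a BED file (0-based half-open) as genes, converting coordinates
    to the package's 1-based closed convention."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED needs at least chrom/start/end")
    names = df[3].astype(str) if df.shape[1] > 3 else pd.Series(
        [f"gene{i + 1}" for i in range(len(df))]
    )
    strand = df[5].astype(str) if df.shape[1] > 5 else "."
    genes = pd.DataFrame(
        {
            "gene_id": names,
            "symbol": names,
            "chrom": df[0].astype(str),
            "start": df[1].astype(np.int64) + 1,
            "end": df[2].astype(np.int64),
            "strand": strand,
            "is_regulator": False,
        }
    )
    return GeneAnnotation(genes)


def read_census(path) -> list[str]:
    """One regulator symbol per line; blanks and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out
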