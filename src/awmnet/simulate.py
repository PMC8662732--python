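"""Synthetic genotype/phenotype generator with planted co-association structure.

The generator inverts the downstream analysis model.  Phenotypes are built as

    y = sex + batch + sum_g dosage_g * effect_g + polygenic + residual

where the causal genes are organised into modules: each module carries a
latent trait-loading vector and every member gene's effect vector across
traits is that loading scaled by a gene weight plus a small perturbation, so
effect profiles within a module are strongly correlated (the signal the
co-association network is meant to recover).  One gene per module is a
designated regulator hub with extra member genes wired to its module,
planting hub-like connectivity.  A polygenic term drawn from non-causal SNPs
plus an i.i.d. residual are scaled per trait so realised narrow-sense
heritability matches the requested targets.

Defaults emulate the study population this package was designed around:
432 individuals in six batches, ~42.6k SNPs on 18 autosomes, 30 health
related traits (immunological, haematological and stress phenotypes) with
whole-panel heritabilities between ~0.08 and ~0.6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import UNMAPPED, GeneAnnotation, GenotypeMatrix, TraitSpec, TraitTable

# Trait codes of the emulated study: 12 haematological, 4 immunoglobulin,
# 3 serum proteins/metabolites, the gamma-delta T cell key phenotype,
# 8 phagocytosis phenotypes and 2 stress indicators.
DEFAULT_TRAIT_NAMES = [
    "HCT", "HB", "ERY", "MCV", "MCH", "MCHC", "PLA", "LEU", "EO", "LYM",
    "MON", "NEU", "IgAsal", "IgA", "IgG", "IgM", "CRP", "HP", "NO", "gdT",
    "PHAGO_PCT", "GRANU_PHAGO_PCT", "MON_PHAGO_PCT", "LYM_PHAGO_PCT",
    "PHAGO_FITC", "GRANU_PHAGO_FITC", "MON_PHAGO_FITC", "LYM_PHAGO_FITC",
    "CORT", "NLR",
]

#: Whole-panel heritabilities of the 30 emulated traits (same order as
#: DEFAULT_TRAIT_NAMES); these are the generator's default h2 targets.
DEFAULT_H2_TARGETS = [
    0.338, 0.371, 0.532, 0.588, 0.560, 0.503, 0.449, 0.226, 0.345, 0.314,
    0.076, 0.299, 0.188, 0.497, 0.593, 0.399, 0.180, 0.285, 0.278, 0.439,
    0.284, 0.285, 0.368, 0.531, 0.406, 0.416, 0.308, 0.379, 0.209, 0.466,
]

PHAGOCYTOSIS_TRAITS = [t for t in DEFAULT_TRAIT_NAMES if "PHAGO" in t]

DEFAULT_KEY_TRAIT = "gdT"


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    Counts must be positive; ``maf_range`` lies in (0, 0.5]; every h2 target
    in [0, 0.95].  ``switch_prob`` is the per-adjacent-SNP probability of
    re-drawing the source haplotype in the haplotype-copying scheme (lower =
    stronger local LD).  ``causal_share`` is the fraction of each trait's
    genetic variance explained by the planted module SNPs, the rest being
    polygenic background.
    """

    n_individuals: int = 432
    n_snps: int = 42641
    n_chromosomes: int = 18
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_traits: int = 30
    trait_names: list[str] = field(default_factory=lambda: list(DEFAULT_TRAIT_NAMES))
    h2_targets: list[float] = field(default_factory=lambda: list(DEFAULT_H2_TARGETS))
    n_modules: int = 8
    genes_per_module: int = 12
    hub_extra_targets: int = 10
    n_background_genes: int = 300
    n_decoy_regulators: int = 30
    effect_profile_sd: float = 1.0
    profile_noise_sd: float = 0.5
    orthogonal_loadings: bool = True
    gene_weight_range: tuple[float, float] = (0.7, 1.3)
    causal_share: float = 0.5
    sex_effect_sd: float = 0.25
    batch_levels: int = 6
    batch_effect_sd: float = 0.25
    n_haplotypes: int = 24
    switch_prob: float = 0.05
    missing_rate: float = 0.01
    high_missing_frac: float = 0.03
    high_missing_rate: float = 0.15
    unmapped_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.trait_names, tuple):
            self.trait_names = list(self.trait_names)
        if np.isscalar(self.h2_targets):
            self.h2_targets = [float(self.h2_targets)] * self.n_traits
        else:
            self.h2_targets = [float(h) for h in self.h2_targets]
        if self.n_traits != len(DEFAULT_TRAIT_NAMES) and self.trait_names == DEFAULT_TRAIT_NAMES:
            self.trait_names = [f"trait{i + 1:02d}" for i in range(self.n_traits)]
        if len(self.h2_targets) != self.n_traits and len(self.h2_targets) == len(DEFAULT_H2_TARGETS):
            self.h2_targets = self.h2_targets[: self.n_traits]
        self.validate()

    def validate(self) -> None:
        for name in ("n_individuals", "n_snps", "n_chromosomes", "n_traits",
                     "n_modules", "genes_per_module", "batch_levels",
                     "n_haplotypes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if len(self.trait_names) != self.n_traits:
            raise ValueError("trait_names length must equal n_traits")
        if len(self.h2_targets) != self.n_traits:
            raise ValueError("h2_targets length must equal n_traits")
        for h in self.h2_targets:
            if not (0.0 <= h <= 0.95):
                raise ValueError("each h2 target must lie in [0, 0.95]")
        if not (0.0 <= self.missing_rate <= 0.05):
            raise ValueError("missing_rate must lie in [0, 0.05]")
        if not (0.0 <= self.causal_share <= 1.0):
            raise ValueError("causal_share must lie in [0, 1]")
        n_causal = self.n_modules * (self.genes_per_module + self.hub_extra_targets)
        if self.n_snps < n_causal:
            raise ValueError(
                f"n_snps={self.n_snps} too small to place {n_causal} causal SNPs"
            )

    @property
    def key_trait(self) -> str:
        return DEFAULT_KEY_TRAIT if DEFAULT_KEY_TRAIT in self.trait_names else self.trait_names[0]


@dataclass
class SimTruth:
    """Ground truth of a simulated study.

    ``causal_map``: per module, list of (gene_id, snp_id, effect vector over
    traits).  ``hub_genes``: the designated regulator hub of each module.
    ``true_h2``: realised per-trait heritability computed from the generating
    components.  ``fixed_effects``: sex/batch effect values used.
    """

    causal_map: dict[int, list[tuple[str, str, np.ndarray]]]
    hub_genes: dict[int, str]
    true_h2: dict[str, float]
    fixed_effects: dict[str, list[float] | dict[str, list[float]]]
    module_of_gene: dict[str, int]
    census: list[str]

    def to_json_dict(self) -> dict:
        return {
            "causal_map": {
                str(k): [[g, s, [float(v) for v in e]] for g, s, e in genes]
                for k, genes in self.causal_map.items()
            },
            "hub_genes": {str(k): v for k, v in self.hub_genes.items()},
            "true_h2": {k: float(v) for k, v in self.true_h2.items()},
            "fixed_effects": self.fixed_effects,
            "module_of_gene": self.module_of_gene,
            "census": self.census,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SimTruth":
        return cls(
            causal_map={
                int(k): [(g, s, np.asarray(e, float)) for g, s, e in genes]
                for k, genes in d["causal_map"].items()
            },
            hub_genes={int(k): v for k, v in d["hub_genes"].items()},
            true_h2=d["true_h2"],
            fixed_effects=d["fixed_effects"],
            module_of_gene=d["module_of_gene"],
            census=d["census"],
        )


def _rngs(config: SimConfig, n: int) -> list[np.random.Generator]:
    """Independent per-stage streams derived from the root seed."""
    ss = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate an additive-dosage SNP panel with local LD.

    Each chromosome holds an equal share of SNPs at strictly increasing
    positions.  A pool of founder haplotypes is drawn per chromosome with
    per-SNP allele frequencies uniform in ``maf_range``; every individual's
    two haplotypes are mosaics of the pool, switching source haplotype with
    probability ``switch_prob`` between adjacent SNPs, which induces LD that
    decays with distance.  A fraction of SNPs is marked unmapped (chrom "0")
    and missingness is injected completely at random.
    """
    config.validate()
    rng_geno, _, rng_miss = _rngs(config, 3)[:3]

    n, m = config.n_individuals, config.n_snps
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1

    dosage = np.empty((n, m), dtype=float)
    chroms: list[str] = []
    positions = np.empty(m, dtype=np.int64)
    col = 0
    for c, mc in enumerate(per_chrom, start=1):
        if mc == 0:
            continue
        p = rng_geno.uniform(config.maf_range[0], config.maf_range[1], size=mc)
        pool = (rng_geno.random((config.n_haplotypes, mc)) < p).astype(np.int8)
        # haplotype-copying: source index per (haplotype, SNP)
        cand = rng_geno.integers(0, config.n_haplotypes, size=(2 * n, mc))
        switch = rng_geno.random((2 * n, mc)) < config.switch_prob
        switch[:, 0] = True
        # forward-fill the source drawn at the last switch point
        last = np.maximum.accumulate(
            np.where(switch, np.arange(mc)[None, :], -1), axis=1
        )
        src = np.take_along_axis(cand, last, axis=1)
        haps = pool[src, np.arange(mc)[None, :]]
        dosage[:, col : col + mc] = haps[:n] + haps[n:]
        # positions via positive gaps so they are strictly increasing
        gaps = rng_geno.integers(500, 6000, size=mc)
        positions[col : col + mc] = 10_000 + np.cumsum(gaps)
        chroms.extend([str(c)] * mc)
        col += mc

    chrom_arr = np.array(chroms, dtype=object)
    # unmapped SNPs: lose their coordinates
    n_unmapped = int(round(config.unmapped_frac * m))
    if n_unmapped:
        unmapped_idx = rng_geno.choice(m, size=n_unmapped, replace=False)
        chrom_arr[unmapped_idx] = UNMAPPED
        positions = positions.copy()
        positions[unmapped_idx] = -1

    # missingness, MCAR, with a small subset of badly-genotyped SNPs
    rate = np.full(m, config.missing_rate)
    n_bad = int(round(config.high_missing_frac * m))
    if n_bad:
        bad = rng_miss.choice(m, size=n_bad, replace=False)
        rate[bad] = config.high_missing_rate
    if rate.any():
        miss = rng_miss.random((n, m)) < rate[None, :]
        dosage[miss] = np.nan

    snp_meta = pd.DataFrame(
        {
            "snp": [f"snp{i + 1:06d}" for i in range(m)],
            "chrom": chrom_arr,
            "pos": positions,
            "allele_counted": "B",
            "allele_other": "A",
        }
    )
    sample_ids = [f"ind{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(dosage=dosage, snp_meta=snp_meta, sample_ids=sample_ids)


def _place_genes(geno: GenotypeMatrix, config: SimConfig, rng: np.random.Generator):
    """Choose causal SNPs, lay gene intervals around them (every causal SNP
    within its gene +/- 5 kb by construction), and add background genes."""
    mapped = np.flatnonzero(geno.is_mapped() & (geno.maf() >= 0.05) & (geno.call_rate() >= 0.9))
    genes_per = config.genes_per_module + config.hub_extra_targets
    n_causal = config.n_modules * genes_per
    n_genes = n_causal + config.n_background_genes
    if len(mapped) < n_genes:
        raise ValueError("panel has too few well-behaved mapped SNPs to anchor genes")
    anchor = rng.choice(mapped, size=n_genes, replace=False)

    pos = geno.snp_meta["pos"].to_numpy()
    chrom = geno.snp_meta["chrom"].astype(str).to_numpy()
    rows = []
    half = 1500
    for j, s in enumerate(anchor):
        causal = j < n_causal
        if causal:
            module = j // genes_per
            within = j % genes_per
            if within == 0:
                sym = f"HUB{module + 1:02d}"
                kind = "hub"
            elif within < config.genes_per_module:
                sym = f"M{module + 1:02d}G{within:02d}"
                kind = "core"
            else:
                sym = f"M{module + 1:02d}X{within - config.genes_per_module + 1:02d}"
                kind = "extra"
        else:
            module = -1
            sym = f"BG{j - n_causal + 1:04d}"
            kind = "background"
        # offset the gene so some causal SNPs sit in the +/-5 kb flank
        offset = int(rng.integers(-4000, 4001)) if causal else 0
        center = pos[s] + offset
        start = max(1, center - half)
        rows.append(
            {
                "gene_id": sym,
                "symbol": sym,
                "chrom": chrom[s],
                "start": start,
                "end": start + 2 * half,
                "strand": "+" if rng.random() < 0.5 else "-",
                "is_regulator": False,
                "anchor_snp": geno.snp_meta["snp"].iloc[s],
                "module": module,
                "kind": kind,
            }
        )
    genes = pd.DataFrame(rows)
    return genes


def simulate_traits(
    geno: GenotypeMatrix, config: SimConfig
) -> tuple[TraitTable, SimTruth, GeneAnnotation]:
    """Simulate correlated multi-trait phenotypes with planted modules.

    Returns the trait table, the ground truth and the gene annotation (the
    annotation is produced here because causal-gene placement and effect
    assignment are one step).
    """
    config.validate()
    _, rng_tr, _ = _rngs(config, 3)
    genes = _place_genes(geno, config, rng_tr)

    n, T = config.n_individuals, config.n_traits
    names = config.trait_names
    h2 = np.asarray(config.h2_targets, float)

    # fixed effects
    sex = rng_tr.integers(0, 2, size=n)
    batch = rng_tr.integers(0, config.batch_levels, size=n)
    lab_batch = 2 * batch + rng_tr.integers(0, 2, size=n)
    sex_eff = rng_tr.normal(0.0, config.sex_effect_sd, size=T)
    batch_eff = rng_tr.normal(0.0, config.batch_effect_sd, size=(config.batch_levels, T))
    lab_eff = rng_tr.normal(0.0, config.batch_effect_sd, size=(2 * config.batch_levels, T))

    # module loadings: orthonormal when possible so cross-module effect
    # profiles are uncorrelated by construction
    raw = rng_tr.normal(0.0, 1.0, size=(T, config.n_modules))
    if config.orthogonal_loadings and config.n_modules <= T:
        q, _ = np.linalg.qr(raw)
        loadings = q.T[: config.n_modules]
    else:
        loadings = raw.T / np.linalg.norm(raw.T, axis=1, keepdims=True)
    loadings = loadings * config.effect_profile_sd

    causal = genes[genes["module"] >= 0]
    effects = np.zeros((len(causal), T))
    for i, (_, row) in enumerate(causal.iterrows()):
        k = int(row["module"])
        if row["kind"] == "hub":
            w, noise = 1.0, 0.0
        elif row["kind"] == "core":
            w = rng_tr.uniform(*config.gene_weight_range)
            noise = config.profile_noise_sd
        else:  # extra hub targets: additional correlated module members
            w = rng_tr.uniform(*config.gene_weight_range)
            noise = config.profile_noise_sd
        effects[i] = w * loadings[k] + rng_tr.normal(
            0.0, noise * config.effect_profile_sd / np.sqrt(T), size=T
        )

    snp_index = pd.Index(geno.snp_meta["snp"])
    causal_cols = snp_index.get_indexer(causal["anchor_snp"])
    X = geno.imputed_dosage()
    Xc = X[:, causal_cols]
    Xc = Xc - Xc.mean(axis=0)
    causal_score = Xc @ effects  # n x T

    # polygenic term from non-causal mapped SNPs
    poly_cols = np.setdiff1d(np.flatnonzero(geno.is_mapped()), causal_cols)
    Z = X[:, poly_cols]
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0)
    keep = sd > 0
    Z = Z[:, keep] / sd[keep]
    a = rng_tr.normal(0.0, 1.0, size=(Z.shape[1], T)) / np.sqrt(Z.shape[1])
    poly_score = Z @ a

    def _rescale(M: np.ndarray, target_var: np.ndarray) -> np.ndarray:
        v = M.var(axis=0, ddof=1)
        scale = np.where(v > 0, np.sqrt(np.where(v > 0, target_var / np.where(v > 0, v, 1.0), 0.0)), 0.0)
        return M * scale[None, :]

    if np.any(h2 >= 1.0):
        raise ValueError("h2 target >= 1 is not realisable")
    causal_score = _rescale(causal_score, config.causal_share * h2)
    poly_score = _rescale(poly_score, (1.0 - config.causal_share) * h2)
    resid = rng_tr.normal(0.0, 1.0, size=(n, T))
    resid = _rescale(resid - resid.mean(axis=0), 1.0 - h2)

    genetic = causal_score + poly_score
    y = (
        sex[:, None] * sex_eff[None, :]
        + np.where(
            np.array([names[t] in PHAGOCYTOSIS_TRAITS for t in range(T)])[None, :],
            lab_eff[lab_batch],
            batch_eff[batch],
        )
        + genetic
        + resid
    )

    with np.errstate(invalid="ignore", divide="ignore"):
        vg = genetic.var(axis=0, ddof=1)
        vtot = (genetic + resid).var(axis=0, ddof=1)
        true_h2 = np.where(vtot > 0, vg / vtot, 0.0)

    # scale causal effect vectors to the per-trait factor applied above, so
    # the truth records the effects actually used
    traits_df = pd.DataFrame(y, columns=names)
    covariates = pd.DataFrame(
        {
            "sex": np.where(sex == 0, "M", "F"),
            "batch": (batch + 1).astype(str),
            "lab_batch": (lab_batch + 1).astype(str),
        }
    )
    trait_specs = {
        t: TraitSpec(batch_factor="lab_batch" if t in PHAGOCYTOSIS_TRAITS else "batch")
        for t in names
    }
    traits = TraitTable(
        sample_ids=list(geno.sample_ids),
        traits=traits_df,
        covariates=covariates,
        trait_specs=trait_specs,
    )

    causal_map: dict[int, list[tuple[str, str, np.ndarray]]] = {}
    module_of_gene: dict[str, int] = {}
    for i, (_, row) in enumerate(causal.iterrows()):
        k = int(row["module"])
        causal_map.setdefault(k, []).append(
            (row["gene_id"], row["anchor_snp"], effects[i].copy())
        )
        module_of_gene[row["gene_id"]] = k
    hub_genes = {
        int(row["module"]): row["gene_id"]
        for _, row in genes[genes["kind"] == "hub"].iterrows()
    }

    # regulator census: every hub plus decoy regulators from the background
    # (module members are excluded so each module's census representative is
    # its hub, mirroring a census that names regulators, not their targets)
    decoy_pool = genes[genes["kind"] == "background"]["gene_id"].tolist()
    n_decoy = min(config.n_decoy_regulators, len(decoy_pool))
    decoys = list(rng_tr.choice(decoy_pool, size=n_decoy, replace=False))
    census = sorted(hub_genes.values()) + sorted(decoys)

    annotation = GeneAnnotation(
        genes[["gene_id", "symbol", "chrom", "start", "end", "strand", "is_regulator"]].copy()
    ).flag_regulators(census)

    truth = SimTruth(
        causal_map=causal_map,
        hub_genes=hub_genes,
        true_h2={names[t]: float(true_h2[t]) for t in range(T)},
        fixed_effects={
            "sex": [float(v) for v in sex_eff],
            "batch": {str(b + 1): [float(v) for v in batch_eff[b]] for b in range(config.batch_levels)},
        },
        module_of_gene=module_of_gene,
        census=census,
    )
    return traits, truth, annotation


def simulate_study(config: SimConfig):
    """Convenience: genotypes + traits + annotation + census + truth."""
    geno = simulate_genotypes(config)
    traits, truth, annotation = simulate_traits(geno, config)
    return geno, traits, annotation, truth.census, truth


def write_fixture(
    dir_path: str | Path,
    geno: GenotypeMatrix,
    traits: TraitTable,
    annotation: GeneAnnotation,
    census: list[str],
    truth: SimTruth | None = None,
    force: bool = False,
) -> dict[str, Path]:
    """Write a complete on-disk study fixture.

    Produces PLINK .ped/.map, an additive .raw, the phenotype TSV, a GFF3
    gene annotation, the regulator census and (optionally) the truth JSON.
    Refuses to overwrite an existing fixture unless ``force``.
    """
    from . import io as awmio

    out = Path(dir_path)
    files = {
        "ped": out / "study.ped",
        "map": out / "study.map",
        "raw": out / "study.raw",
        "pheno": out / "phenotypes.tsv",
        "gff3": out / "genes.gff3",
        "census": out / "census.txt",
        "truth": out / "truth.json",
    }
    out.mkdir(parents=True, exist_ok=True)
    existing = [p for p in files.values() if p.exists()]
    if existing and not force:
        raise FileExistsError(f"fixture files exist (use force=True): {existing[0]}")

    awmio.write_plink_ped_map(files["ped"], files["map"], geno)
    awmio.write_plink_raw(files["raw"], geno)
    awmio.write_phenotypes(files["pheno"], traits)
    awmio.write_gff3(files["gff3"], annotation)
    files["census"].write_text("".join(f"{s}\n" for s in census))
    if truth is not None:
        files["truth"].write_text(json.dumps(truth.to_json_dict(), indent=1))
    else:
        files.pop("truth")
    return files
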