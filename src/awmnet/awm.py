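"""Association weight matrix construction.

SNPs are selected by nominal association with the key phenotype (p < alpha)
or by pleiotropy (associated with at least ``min_traits`` of the analysed
traits), annotated to genes within a symmetric window, and collapsed to one
representative SNP per gene.  The matrix cell for (gene, trait) is the
signed t-value (beta/se) of the gene's SNP, and columns are standardised to
mean zero / unit sample variance so that gene rows are comparable effect
profiles across traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import GeneAnnotation
from .gwas import AssocResult


@dataclass
class SnpSelection:
    """Key-trait and pleiotropic SNP sets with per-SNP association counts."""

    key_trait_snps: set[str]
    pleiotropic_snps: set[str]
    key_trait: str
    alpha: float
    min_traits: int
    n_assoc_traits: pd.Series = field(repr=False)
    assoc_traits: dict[str, list[str]] = field(repr=False, default_factory=dict)

    @property
    def merged(self) -> set[str]:
        return self.key_trait_snps | self.pleiotropic_snps


@dataclass
class AWMatrix:
    """Genes x traits matrix of standardised effects.

    ``z`` is indexed by gene_id; ``gene_to_snp`` maps each gene to its
    representative SNP (genes sharing a SNP each carry that SNP's row).
    """

    z: pd.DataFrame
    gene_to_snp: pd.Series
    key_trait: str

    @property
    def genes(self) -> pd.Index:
        return self.z.index

    @property
    def traits(self) -> list[str]:
        return list(self.z.columns)


def select_snps(
    assoc: AssocResult,
    key_trait: str,
    alpha: float = 0.05,
    min_traits: int = 3,
) -> SnpSelection:
    """Select key-phenotype-associated and pleiotropic SNPs.

    Strict inequality throughout: a SNP enters the key set iff its key-trait
    p < alpha, and the pleiotropic set iff it has p < alpha for at least
    ``min_traits`` traits (the key trait counts among them).
    """
    if key_trait not in assoc.trait_names:
        raise KeyError(f"unknown key trait {key_trait!r}")
    p = assoc.p
    sig = p < alpha  # NaN (untestable) compares False
    n_assoc = sig.sum(axis=1)
    key = set(p.index[sig[key_trait]])
    pleio = set(p.index[n_assoc >= min_traits])
    traits = np.array(assoc.trait_names)
    assoc_traits = {
        s: [t for t in traits[sig.loc[s].to_numpy(dtype=bool)]]
        for s in (key | pleio)
    }
    return SnpSelection(
        key_trait_snps=key,
        pleiotropic_snps=pleio,
        key_trait=key_trait,
        alpha=alpha,
        min_traits=min_traits,
        n_assoc_traits=n_assoc,
        assoc_traits=assoc_traits,
    )


def annotate_snps(
    snp_meta: pd.DataFrame,
    genes: GeneAnnotation,
    window: int = 5000,
    snp_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Map SNPs to genes within the gene span +/- ``window`` (inclusive).

    A SNP may map to multiple genes; SNPs hitting no gene are dropped.
    Returns a DataFrame with columns (snp, gene_id) sorted by (snp, gene_id).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    meta = snp_meta
    if snp_ids is not None:
        meta = meta[meta["snp"].isin(snp_ids)]
    trees: dict[str, IntervalTree] = {}
    for _, g in genes.genes.iterrows():
        lo = g["start"] - window
        hi = g["end"] + window + 1  # IntervalTree is half-open
        trees.setdefault(str(g["chrom"]), IntervalTree()).addi(lo, hi, g["gene_id"])

    pairs = []
    for snp, chrom, pos in meta[["snp", "chrom", "pos"]].itertuples(index=False):
        tree = trees.get(str(chrom))
        if tree is None or pos < 0:
            continue
        for iv in tree.at(pos):
            pairs.append((snp, iv.data))
    return (
        pd.DataFrame(pairs, columns=["snp", "gene_id"])
        .sort_values(["snp", "gene_id"])
        .reset_index(drop=True)
    )


def build_awm(
    assoc: AssocResult,
    pairs: pd.DataFrame,
    key_trait: str,
    selection: SnpSelection | None = None,
    per_gene_rule: str = "most_pleiotropic",
) -> AWMatrix:
    """Assemble the standardised genes x traits matrix.

    Representative-SNP rule (``most_pleiotropic``): the candidate SNP
    associated with the most traits wins; ties go to the smaller key-trait
    p-value, then the smaller genomic position.  Raw cells are signed
    t-values beta/se; each trait column is then standardised to mean 0 and
    unit sample variance (ddof=1).  A constant column raises, naming the
    trait.
    """
    if per_gene_rule not in ("most_pleiotropic", "first"):
        raise ValueError(f"unknown per_gene_rule {per_gene_rule!r}")
    missing = set(pairs["snp"]) - set(assoc.snp_ids)
    if missing:
        raise ValueError(f"pairs reference SNPs absent from assoc: {sorted(missing)[:5]}")

    if selection is not None:
        n_assoc = selection.n_assoc_traits
    else:
        n_assoc = (assoc.p < 0.05).sum(axis=1)
    key_p = assoc.p[key_trait]

    pos_lookup = None
    gene_to_snp: dict[str, str] = {}
    for gene_id, grp in pairs.groupby("gene_id"):
        cands = list(grp["snp"])
        if per_gene_rule == "first" or len(cands) == 1:
            best = sorted(cands)[0]
        else:
            def rank(s: str):
                kp = key_p.get(s, np.nan)
                kp = np.inf if np.isnan(kp) else kp
                return (-int(n_assoc.get(s, 0)), kp, s)

            best = min(cands, key=rank)
        gene_to_snp[gene_id] = best

    genes = sorted(gene_to_snp)
    snps = [gene_to_snp[g] for g in genes]
    t = (assoc.beta.loc[snps] / assoc.se.loc[snps]).to_numpy()
    raw = pd.DataFrame(t, index=pd.Index(genes, name="gene_id"), columns=assoc.trait_names)
    if raw.isna().any().any():
        bad = raw.columns[raw.isna().any()].tolist()
        raise ValueError(f"untestable representative SNPs leave NaNs in traits {bad}")

    sd = raw.std(axis=0, ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        raise ValueError(f"constant AWM column(s) for trait(s) {const}")
    z = (raw - raw.mean(axis=0)) / sd
    return AWMatrix(
        z=z,
        gene_to_snp=pd.Series(gene_to_snp, name="snp").loc[genes],
        key_trait=key_trait,
    )


@dataclass
class TraitRelationships:
    """Trait-by-trait correlation structure of the AWM columns."""

    corr: pd.DataFrame
    linkage: np.ndarray
    newick: str

    def cut(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.corr.index, name="cluster")


def trait_relationships(awm: AWMatrix) -> TraitRelationships:
    """Pearson correlations between AWM columns, with average-linkage
    hierarchical clustering on the distance 1 - r and a Newick dendrogram."""
    if len(awm.traits) < 2:
        raise ValueError("need at least 2 traits")
    if len(awm.genes) < 3:
        raise ValueError("need at least 3 genes")
    corr = awm.z.corr()
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    newick = _linkage_to_newick(Z, list(corr.index))
    return TraitRelationships(corr=corr, linkage=Z, newick=newick)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
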