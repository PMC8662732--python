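"""SNP selection, gene annotation, matrix standardisation and trait
clustering, each checked against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from awmnet.awm import (
    annotate_snps,
    build_awm,
    select_snps,
    trait_relationships,
)
from awmnet.containers import GeneAnnotation
from awmnet.gwas import AssocResult


def make_assoc(p, beta=None, se=None, snps=None, traits=None) -> AssocResult:
    p = np.asarray(p, float)
    m, T = p.shape
    snps = snps or [f"s{i}" for i in range(m)]
    traits = traits or [f"t{j}" for j in range(T)]
    idx = pd.Index(snps, name="snp")
    beta = np.asarray(beta, float) if beta is not None else np.ones((m, T))
    se = np.asarray(se, float) if se is not None else np.ones((m, T))
    return AssocResult(
        beta=pd.DataFrame(beta, index=idx, columns=traits),
        se=pd.DataFrame(se, index=idx, columns=traits),
        p=pd.DataFrame(p, index=idx, columns=traits),
        n_used=pd.Series({t: m for t in traits}),
        testable=pd.DataFrame(True, index=idx, columns=traits),
    )


def make_genes(rows) -> GeneAnnotation:
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    df["symbol"] = df["gene_id"]
    df["strand"] = "+"
    df["is_regulator"] = False
    return GeneAnnotation(df)


class TestSelectSnps:
    def test_all_pvalues_one_gives_empty_sets(self):
        sel = select_snps(make_assoc(np.ones((5, 4))), "t0")
        assert not sel.key_trait_snps and not sel.pleiotropic_snps and not sel.merged

    def test_handworked_toy_selection(self):
        """s0 key-only, s1 pleiotropic (3 traits), s2 both, s3/s4 neither."""
        p = np.array(
            [
                [0.01, 0.50, 0.50, 0.50],
                [0.50, 0.01, 0.01, 0.01],
                [0.01, 0.01, 0.01, 0.50],
                [0.50, 0.50, 0.50, 0.50],
                [0.06, 0.06, 0.50, 0.50],
            ]
        )
        sel = select_snps(make_assoc(p), "t0", alpha=0.05, min_traits=3)
        assert sel.key_trait_snps == {"s0", "s2"}
        assert sel.pleiotropic_snps == {"s1", "s2"}
        assert sel.merged == {"s0", "s1", "s2"}
        assert sel.n_assoc_traits["s2"] == 3
        assert sel.assoc_traits["s1"] == ["t1", "t2", "t3"]
        # independent recount
        for i in range(5):
            expect_key = p[i, 0] < 0.05
            assert (f"s{i}" in sel.key_trait_snps) == expect_key
            assert (f"s{i}" in sel.pleiotropic_snps) == ((p[i] < 0.05).sum() >= 3)

    def test_boundary_p_exactly_alpha_excluded(self):
        p = np.full((1, 4), 0.5)
        p[0, 0] = 0.05
        sel = select_snps(make_assoc(p), "t0")
        assert not sel.key_trait_snps

    def test_unknown_key_trait_raises(self):
        with pytest.raises(KeyError):
            select_snps(make_assoc(np.ones((2, 2))), "nope")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_merged_union_identity(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((30, 6))
        sel = select_snps(make_assoc(p), "t0")
        overlap = sel.key_trait_snps & sel.pleiotropic_snps
        assert len(sel.merged) == len(sel.key_trait_snps) + len(sel.pleiotropic_snps) - len(overlap)


class TestAnnotateSnps:
    GENES = [("gA", "1", 10_000, 12_000), ("gB", "1", 11_500, 15_000), ("gC", "2", 10_000, 12_000)]

    def snp_meta(self, rows):
        return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])

    def test_window_boundary_inclusive(self):
        meta = self.snp_meta([("s1", "1", 5_000), ("s2", "1", 4_999)])
        pairs = annotate_snps(meta, make_genes(self.GENES), window=5_000)
        assert set(pairs["snp"]) == {"s1"}  # start - 5000 in, start - 5001 out

    def test_snp_can_map_to_multiple_genes(self):
        meta = self.snp_meta([("s1", "1", 11_700)])
        pairs = annotate_snps(meta, make_genes(self.GENES), window=0)
        assert set(pairs["gene_id"]) == {"gA", "gB"}

    def test_chromosome_must_match(self):
        meta = self.snp_meta([("s1", "2", 11_000), ("s2", "3", 11_000)])
        pairs = annotate_snps(meta, make_genes(self.GENES), window=0)
        assert list(pairs["gene_id"]) == ["gC"]

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            annotate_snps(self.snp_meta([]), make_genes(self.GENES), window=-1)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        genes = make_genes(
            [
                (f"g{i}", str(rng.integers(1, 4)),
                 int(s := rng.integers(1, 500_000)), int(s + rng.integers(500, 20_000)))
                for i in range(80)
            ]
        )
        meta = self.snp_meta(
            [
                (f"s{i}", str(rng.integers(1, 4)), int(rng.integers(1, 520_000)))
                for i in range(500)
            ]
        )
        w = 5_000
        pairs = annotate_snps(meta, genes, window=w)
        got = set(map(tuple, pairs.to_numpy()))
        expect = set()
        for _, s in meta.iterrows():
            for _, g in genes.genes.iterrows():
                if s["chrom"] == g["chrom"] and g["start"] - w <= s["pos"] <= g["end"] + w:
                    expect.add((s["snp"], g["gene_id"]))
        assert got == expect

    def test_window_monotonicity(self):
        rng = np.random.default_rng(9)
        genes = make_genes(
            [(f"g{i}", "1", int(s := rng.integers(1, 200_000)), int(s + 2_000)) for i in range(30)]
        )
        meta = self.snp_meta([(f"s{i}", "1", int(rng.integers(1, 210_000))) for i in range(200)])
        prev = set()
        for w in (0, 1_000, 5_000, 20_000):
            cur = set(map(tuple, annotate_snps(meta, genes, window=w).to_numpy()))
            assert prev <= cur
            prev = cur


class TestBuildAwm:
    def pairs(self, mapping):
        return pd.DataFrame(mapping, columns=["snp", "gene_id"])

    def test_standardisation_closed_form(self):
        # raw t-values 1,2,3 -> standardised -1,0,1 (sample SD)
        beta = np.array([[1.0], [2.0], [3.0]])
        assoc = make_assoc(np.full((3, 1), 0.01), beta=beta, se=np.ones((3, 1)))
        pairs = self.pairs([("s0", "gA"), ("s1", "gB"), ("s2", "gC")])
        awm = build_awm(assoc, pairs, "t0")
        np.testing.assert_allclose(awm.z["t0"].to_numpy(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_representative_snp_most_pleiotropic(self):
        p = np.array(
            [
                [0.01, 0.01, 0.01, 0.01, 0.01, 0.9],  # s0: 5 traits
                [0.01, 0.01, 0.9, 0.9, 0.9, 0.9],  # s1: 2 traits
                [0.02, 0.9, 0.9, 0.9, 0.9, 0.01],
                [0.01, 0.9, 0.9, 0.9, 0.9, 0.02],
            ]
        )
        rng = np.random.default_rng(0)
        assoc = make_assoc(p, beta=rng.normal(size=(4, 6)))
        sel = select_snps(assoc, "t0", min_traits=2)
        pairs = self.pairs([("s0", "gA"), ("s1", "gA"), ("s2", "gB"), ("s3", "gB")])
        awm = build_awm(assoc, pairs, "t0", selection=sel)
        assert awm.gene_to_snp["gA"] == "s0"
        assert awm.gene_to_snp["gB"] == "s3"  # tie on count broken by key-trait p

    def test_columns_standardised(self, ):
        rng = np.random.default_rng(1)
        assoc = make_assoc(
            rng.random((30, 5)), beta=rng.normal(size=(30, 5)),
            se=rng.uniform(0.5, 2, (30, 5)),
        )
        pairs = self.pairs([(f"s{i}", f"g{i}") for i in range(30)])
        awm = build_awm(assoc, pairs, "t0")
        assert awm.z.mean().abs().max() < 1e-10
        assert (awm.z.std(ddof=1) - 1).abs().max() < 1e-8

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        assoc = make_assoc(rng.random((10, 4)), beta=rng.normal(size=(10, 4)))
        rows = [(f"s{i}", f"g{i}") for i in range(10)]
        a = build_awm(assoc, self.pairs(rows), "t0")
        b = build_awm(assoc, self.pairs(rows[::-1]), "t0")
        pd.testing.assert_frame_equal(a.z, b.z)

    def test_genes_sharing_snp_share_row(self):
        rng = np.random.default_rng(3)
        assoc = make_assoc(rng.random((5, 4)), beta=rng.normal(size=(5, 4)))
        pairs = self.pairs([("s0", "gA"), ("s0", "gB"), ("s1", "gC")])
        awm = build_awm(assoc, pairs, "t0")
        np.testing.assert_allclose(awm.z.loc["gA"], awm.z.loc["gB"])

    def test_constant_column_raises_with_trait_name(self):
        assoc = make_assoc(np.full((3, 2), 0.01), beta=np.ones((3, 2)))
        pairs = self.pairs([("s0", "gA"), ("s1", "gB"), ("s2", "gC")])
        with pytest.raises(ValueError, match="t0"):
            build_awm(assoc, pairs, "t0")

    def test_unknown_snp_in_pairs_raises(self):
        assoc = make_assoc(np.random.default_rng(4).random((3, 4)))
        with pytest.raises(ValueError, match="absent"):
            build_awm(assoc, self.pairs([("sX", "gA")]), "t0")


class TestTraitRelationships:
    def make_awm(self, z, traits=None):
        from awmnet.awm import AWMatrix

        traits = traits or [f"t{j}" for j in range(z.shape[1])]
        df = pd.DataFrame(z, index=[f"g{i}" for i in range(z.shape[0])], columns=traits)
        return AWMatrix(z=df, gene_to_snp=pd.Series("s", index=df.index), key_trait=traits[0])

    def test_identical_columns_merge_first_at_zero(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=20)
        z = np.column_stack([a, a, rng.normal(size=20)])
        rel = trait_relationships(self.make_awm(z))
        assert rel.corr.iloc[0, 1] == pytest.approx(1.0)
        assert rel.linkage[0, 3] == 2  # first merge joins the twin columns
        assert rel.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_negated_column_distance_two(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=15)
        z = np.column_stack([a, -a, rng.normal(size=15)])
        rel = trait_relationships(self.make_awm(z))
        assert rel.corr.iloc[0, 1] == pytest.approx(-1.0)
        d = 1 - rel.corr.iloc[0, 1]
        assert d == pytest.approx(2.0)

    def test_two_block_structure_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(700 + seed)
            n_genes = 60
            lat = rng.normal(size=(n_genes, 2))
            cols = []
            for j in range(8):
                block = 0 if j < 4 else 1
                cols.append(lat[:, block] + 0.4 * rng.normal(size=n_genes))
            rel = trait_relationships(self.make_awm(np.column_stack(cols)))
            labels = rel.cut(2)
            hits += labels.iloc[:4].nunique() == 1 and labels.iloc[4:].nunique() == 1
        assert hits >= 18

    def test_newick_parses_with_dendropy(self):
        import dendropy

        rng = np.random.default_rng(7)
        rel = trait_relationships(self.make_awm(rng.normal(size=(25, 6))))
        tree = dendropy.Tree.get(data=rel.newick, schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == {f"t{j}" for j in range(6)}

    def test_too_few_traits_or_genes_raises(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            trait_relationships(self.make_awm(rng.normal(size=(10, 1))))
        with pytest.raises(ValueError):
            trait_relationships(self.make_awm(rng.normal(size=(2, 4))))
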