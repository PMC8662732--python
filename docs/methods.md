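# Methods

This note documents the models, algorithms and numerical choices behind
`awmnet`, and what the synthetic-data generator does and does not emulate.

## Analysis model

### Quality control

SNPs are retained when minor allele frequency ≥ `maf_min` (default 0.05,
computed from observed genotypes), missingness ≤ `miss_max` (default 0.10,
boundary inclusive), and a valid chromosome/position exists. Rules are
applied in that order and each removed SNP is attributed to the first rule
it fails; a SNP with no observed genotypes has MAF 0 and falls under the
MAF rule. An empty surviving panel is an error, never an empty result.

### Genomic relationships

The GRM follows the allele-frequency-standardised convention used by
GREML-style software: off-diagonals
G_ij = m⁻¹ Σ_k (x_ik − 2p_k)(x_jk − 2p_k)/(2 p_k q_k) and diagonals
G_ii = 1 + m⁻¹ Σ_k (x_ik² − (1+2p_k)x_ik + 2p_k²)/(2 p_k q_k), with p_k the
counted-allele sample frequency. Missing dosages are mean-imputed per SNP
(an imputed individual contributes 0 to its own diagonal deviation, which
is the desired behaviour). Monomorphic SNPs must be removed by QC first;
the builder refuses them.

### REML heritability

The single-random-effect animal model y = Xb + u + e, u ~ N(0, G σ²ᵤ),
e ~ N(0, I σ²ₑ), is fitted by restricted maximum likelihood. After
eigendecomposition G = U D Uᵀ, the rotated model has diagonal covariance
σ²·diag(h² d_i + 1 − h²) with σ² = σ²ᵤ + σ²ₑ, so β̂ and σ̂² have closed
forms at fixed h² and the restricted likelihood is profiled over
h² ∈ [10⁻⁶, 1−10⁻⁶] by bounded scalar optimisation (xatol 1e-8). The h²
standard error is the inverse square root of the negative numerical
curvature of the profile restricted log-likelihood at the optimum (step
10⁻³, shrunk near the boundary); with one random effect the profile is
exact, so this matches the usual information-based SE. Degenerate inputs —
a trait lying exactly in the fixed-effect space, a rank-deficient design,
or fewer complete cases than fixed effects + 2 — raise explicit errors.
Under a true h² of 0 the estimator piles up near the boundary but its null
sampling distribution at n = 600 still has roughly a quarter of its mass
above 0.05 (90th percentile ≈ 0.13); the tests assert exactly that
behaviour rather than an unrealistically tight concentration.

### Mixed-model association

Variance components are estimated once per trait under the no-SNP model and
re-used for every SNP (the EMMAX / P3D approximation); each mean-imputed
SNP then enters as one fixed covariate in a GLS fit computed in the
whitened eigenbasis, with the residual variance re-estimated per SNP and a
two-sided 1-df Wald chi-square p-value. Zero-variance SNPs are flagged
untestable, not dropped. A single whole-panel GRM is used for all SNPs;
leave-one-chromosome-out is not implemented, so tests of SNPs that are
strongly tagged by the GRM are conservative (proximal contamination). This
is a known limitation, acceptable here because the AWM uses nominal
p-values and effect profiles rather than genome-wide significance.

Fixed effects per trait are intercept + sex + batch dummies; traits tagged
as phagocytosis-type use a 12-level laboratory-batch factor (two levels per
batch) instead of the 6-level batch. A per-trait flag applies a natural-log
transform before analysis and errors on non-positive values.

### SNP selection and the AWM

The key set is {SNP : p(key trait) < α} and the pleiotropic set
{SNP : #(traits with p < α) ≥ min_traits}, defaults α = 0.05 and
min_traits = 3, both strict inequalities; the key trait counts toward the
pleiotropy tally. The merged set is their union. Note that with 30 traits
the pleiotropy rule passes ≈ 18% of null SNPs by chance — deliberate, as
the AWM tradition works with nominal evidence and relies on the network
stage to separate structure from noise.

SNPs are annotated to genes whose span ± `window` (default 5,000 bp,
inclusive on both boundaries) contains the SNP position; a SNP may hit
several genes, and "gene span" means the annotated gene feature, not
CDS-only. Strand is ignored (the window is symmetric). Coordinates are
1-based closed everywhere; BED input is converted on read.

Each gene's representative SNP is the candidate associated with the most
traits, ties broken by the smaller key-trait p-value and then the smaller
genomic position. The raw cell (gene, trait) is the signed t-value
beta/se — traits live on wildly different scales, so effect sizes are not
comparable but t-values are — and columns are then standardised to mean 0,
unit sample variance (ddof 1). A constant column is an error naming the
trait. Row z-scoring before PCIT is not applied; correlations between rows
are scale-free anyway.

Trait relationships are Pearson correlations between AWM columns, clustered
agglomeratively with average linkage on 1 − r; the dendrogram is emitted as
Newick (serialised from the scipy cluster tree; linkage and distance are
package choices, configurable, since the AWM literature varies here).

### PCIT

For every trio (x, y, z) the three first-order partials
r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)) (and rotations) define
the tolerance ε = ⅓(|r_xy·z/r_xy| + |r_xz·y/r_xz| + |r_yz·x/r_yz|); the
trio rejects edge (x, y) iff |r_xy| ≤ |ε r_xz| and |r_xy| ≤ |ε r_yz|, and
an edge is significant iff no third node rejects it. Trios with any direct
correlation below 10⁻¹² in magnitude or a non-positive denominator under
the square root are skipped: an undefined tolerance cannot support a
rejection. The production path vectorises the scan over the third node
(n passes of O(n²) work); a literal triple-loop implementation is kept as
an independent oracle and the two are asserted edge-for-edge identical on
random inputs. Above 5,000 genes the pipeline requires an explicit limit
override, as the scan is cubic.

### Network and topology

Nodes are all AWM genes (isolated nodes retained and counted), edges carry
the gene-gene correlation as weight, and regulator flags come from a
case-insensitive symbol match against the user-supplied census. Topology
statistics are computed directly from adjacency sets — mean local
clustering with degree < 2 nodes contributing 0 (the common network-analyzer
convention; an exclude mode is available), and average shortest-path length
by BFS over connected ordered pairs only, with disconnected pairs counted,
not averaged as infinite. The implementation deliberately avoids graph-
library calls for these quantities so the test suite can use networkx as an
independent cross-check.

### Regulator trios and key regulators

A regulator's target set is its network neighbourhood (self excluded,
fellow regulators included). All C(R,3) trios are scored by
|T(a) ∪ T(b) ∪ T(c) \ {a,b,c}|, ties broken by lower redundancy (targets
covered by ≥ 2 members, members excluded) and then lexicographic ids. Key
regulators come from greedy maximum coverage: repeatedly take the regulator
adding the most uncovered genes (ties to the larger total set, then the
lexicographically smaller id), stopping when no pick adds anything. Greedy
selection carries the standard (1 − 1/e) worst-case guarantee relative to
the optimal k-subset — and *only* that guarantee: instances exist where
the greedy triple covers slightly less than the best exhaustive trio, which
is why an exhaustive mode (guarded to ≤ 25 regulators) is also provided and
why the tests assert the provable bound rather than dominance.

## Synthetic studies

The generator inverts the analysis model. Its defaults emulate the
motivating population: 432 individuals in six batches, a 42,641-SNP target
panel on 18 autosomes, and 30 named immunological/haematological/stress
traits whose default heritability targets span 0.08–0.59, with the
γδ T-cell percentage as default key phenotype and the eight phagocytosis
traits tagged to the 12-level laboratory-batch factor.

* **Genotypes.** Per chromosome, allele frequencies are uniform on
  `maf_range` (default 0.01–0.5 so QC has work to do); a pool of 24 founder
  haplotypes is drawn and every individual's two haplotypes copy from the
  pool, switching founders with probability `switch_prob` (default 0.05)
  between adjacent SNPs — local LD that decays with distance, and
  population relatedness through shared founders. 2% of SNPs lose their map
  position, 1% of genotypes are missing completely at random, and 3% of
  SNPs are badly genotyped (15% missing) to exercise every QC rule.
* **Modules and hubs.** Each of `n_modules` (default 8) modules has a
  latent trait-loading vector — orthonormalised across modules so
  cross-module effect profiles are uncorrelated by construction — and
  `genes_per_module` member genes whose effect vectors are gene-weight ×
  loading + perturbation (expected within-module correlation ≈ 0.66–0.87 at
  the default weight range, ≈ 0.8 at unit weights). One gene per module is
  a hub: its profile is the loading exactly, and `hub_extra_targets` extra
  member genes enlarge its module, planting regulator-like connectivity.
  Causal SNPs sit within ±5 kb of their gene by construction; background
  genes anchor on non-causal SNPs. The census lists every hub plus decoy
  regulators drawn from background genes only — a census names regulators,
  not their targets, and module members would otherwise be
  indistinguishable from their own hub.
* **Traits.** y = sex + batch + Σ causal effects + polygenic + residual.
  The causal score is rescaled per trait to `causal_share` (default 0.5) of
  the target genetic variance, the polygenic term (drawn from standardised
  non-causal dosages) to the remainder, and the residual to 1 − h²; the
  realised heritability recorded in the truth object therefore matches the
  target up to the small covariance between causal and polygenic scores
  induced by LD (within ±0.05 in expectation).

**What passing tests do and do not show.** The generator produces
unrelated founders mixed through a haplotype pool — not a litter/pedigree
structure — so relatedness is realistic in magnitude but not in family
pattern; there is no selection, no X chromosome, no genotyping error
beyond MCAR missingness, and trait distributions are Gaussian (the
log-transform path is exercised with constructed data, not by the
generator). Results on these studies validate the machinery — estimator
calibration, selection logic, network recovery — not the biology of any
particular real population.

## Problem sizes

The test suite and the acceptance script run scaled-down studies chosen to
exercise every stage with comfortable margins: 200–432 individuals,
2,000–6,000 SNPs, 8–30 traits; REML calibration at n = 600, m = 3,000;
PCIT oracle checks at n ∈ [5, 40]; the random-subset heritability
validation at 100 iterations in the acceptance script and 20 per replicate
study in the tests. These sizes reproduce every qualitative property of
the full-scale analysis (the generator accepts the full 42,641-SNP panel
unchanged when more fidelity is wanted).

## Known limitations

* No LOCO association mode; single whole-panel GRM (see above).
* PCIT keeps many weak edges when correlations are uniformly small — an
  inherent property of the trio tolerance, visible in the liberal null
  behaviour of the network stage; downstream regulator ranking is robust
  to it because coverage is dominated by strong modules.
* `h2_se` is a curvature-based SE and degrades into NaN at the h² boundary
  rather than pretending precision.
* The exhaustive key-regulator mode is limited to 25 regulators; beyond
  that only greedy selection is offered.
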