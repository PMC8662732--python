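"""Genomic relationship matrix, REML heritability, and mixed-model GWAS.

The variance model throughout is the standard single-random-effect animal
model y = Xb + u + e with u ~ N(0, G sigma_u^2), e ~ N(0, I sigma_e^2) and G
the genomic relationship matrix.  REML profiles the restricted likelihood
over h2 = sigma_u^2 / (sigma_u^2 + sigma_e^2) after rotating into the
eigenbasis of G, which diagonalises the covariance and reduces every
evaluation to O(n).  Association tests reuse the null-model variance
components for all SNPs (the EMMAX / P3D approximation): each SNP enters as
one extra fixed covariate in a generalised least squares fit and is tested
with a 1-df Wald chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix, TraitTable

_H2_LO, _H2_HI = 1e-6, 1.0 - 1e-6


@dataclass
class GRM:
    """Genomic relationship matrix with the SNP count used to build it."""

    matrix: np.ndarray
    n_snps_used: int
    sample_ids: list[str]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float
    h2: float
    h2_se: float
    loglik: float
    converged: bool = True


@dataclass
class AssocResult:
    """Per (SNP, trait) allele-substitution effects with SE and p-values.

    Frames are SNPs x traits; untestable (zero-variance) SNPs carry NaN
    estimates and testable=False rather than being dropped.
    """

    beta: pd.DataFrame
    se: pd.DataFrame
    p: pd.DataFrame
    n_used: pd.Series
    testable: pd.DataFrame

    @property
    def snp_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def trait_names(self) -> list[str]:
        return list(self.beta.columns)


# ------------------------------------------------------------------- GRM

def build_grm(geno: GenotypeMatrix) -> GRM:
    """Allele-frequency-standardised GRM (GCTA convention).

    Off-diagonals: G_ij = (1/m) sum_k (x_ik - 2p_k)(x_jk - 2p_k) / (2 p_k q_k).
    Diagonals:     G_ii = 1 + (1/m) sum_k (x_ik^2 - (1+2p_k) x_ik + 2p_k^2) / (2 p_k q_k).
    Missing dosages are mean-imputed per SNP before use; monomorphic SNPs
    (p in {0,1}) must have been removed by QC.
    """
    x = geno.imputed_dosage()
    p = x.mean(axis=0) / 2.0
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic SNPs present; run qc_filter first")
    m = x.shape[1]
    denom = 2.0 * p * (1.0 - p)
    w = (x - 2.0 * p) / np.sqrt(denom)
    G = (w @ w.T) / m
    diag = 1.0 + ((x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom).sum(axis=1) / m
    np.fill_diagonal(G, diag)
    return GRM(matrix=G, n_snps_used=m, sample_ids=list(geno.sample_ids))


# ------------------------------------------------------------------ design

def build_design(traits: TraitTable, trait: str) -> np.ndarray:
    """Fixed-effect design for a trait: intercept + sex + batch dummies.

    The batch factor (6-level batch or 12-level laboratory batch) follows
    the trait's spec; reference levels are dropped to keep X full rank.
    """
    spec = traits.spec(trait)
    cov = traits.covariates
    cols = [np.ones(len(cov))]
    for factor in ("sex", spec.batch_factor):
        if factor not in cov.columns:
            raise KeyError(f"covariate factor {factor!r} missing from table")
        values = cov[factor].astype(str)
        levels = sorted(values.unique())
        for lev in levels[1:]:
            cols.append((values == lev).to_numpy(dtype=float))
    return np.column_stack(cols)


def _complete_cases(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return ~(np.isnan(y) | np.isnan(X).any(axis=1))


# -------------------------------------------------------------------- REML

def _profile_reml(
    h2: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Restricted log-likelihood profiled over the total variance.

    In the eigenbasis of G the covariance is sigma2_total * W with
    W = diag(h2 d_i + 1 - h2); beta and sigma2 have closed forms.
    """
    n, p = Xt.shape
    w = h2 * d + (1.0 - h2)
    if np.any(w <= 0):
        return -np.inf, np.nan, np.full(p, np.nan)
    wi = 1.0 / w
    XtW = Xt * wi[:, None]
    XWX = XtW.T @ Xt
    XWy = XtW.T @ yt
    try:
        beta = np.linalg.solve(XWX, XWy)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.full(p, np.nan)
    r = yt - Xt @ beta
    rss = float(r @ (wi * r))
    if rss <= 0:
        return -np.inf, 0.0, beta
    sigma2 = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XWX)
    if sign <= 0:
        return -np.inf, sigma2, beta
    ll = -0.5 * (
        (n - p) * np.log(sigma2)
        + np.sum(np.log(w))
        + logdet_xwx
        + (n - p)
    )
    return ll, sigma2, beta


def reml_h2(
    trait_values: np.ndarray,
    covariate_design: np.ndarray,
    grm: GRM,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """REML variance components for one trait on a GRM.

    Complete cases are extracted first; the restricted likelihood is
    maximised over h2 in (0, 1) by bounded 1-D optimisation; the SE of h2
    comes from the numerical curvature of the profile restricted
    log-likelihood at the optimum.  ``eig`` may carry a precomputed
    eigendecomposition of the (full) GRM to reuse across traits when there
    is no missingness.
    """
    y = np.asarray(trait_values, float)
    X = np.asarray(covariate_design, float)
    keep = _complete_cases(y, X)
    y, X = y[keep], X[keep]
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"too few complete cases (n={n}) for {p} fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient fixed-effect design")

    if eig is not None and keep.all():
        d, U = eig
    else:
        G = grm.matrix[np.ix_(keep, keep)]
        d, U = np.linalg.eigh(G)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    # degenerate trait: y in the column space of X
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    res_ols = y - X @ beta_ols
    if np.var(y) == 0 or float(res_ols @ res_ols) < 1e-12 * max(1.0, float(y @ y)):
        raise ValueError("trait is an exact linear function of the design; no residual variance")

    def neg_ll(h2: float) -> float:
        return -_profile_reml(h2, d, yt, Xt)[0]

    opt = optimize.minimize_scalar(
        neg_ll, bounds=(_H2_LO, _H2_HI), method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(opt.x)
    ll, sigma2, _ = _profile_reml(h2, d, yt, Xt)
    if not np.isfinite(ll):
        raise RuntimeError("REML failed to converge to a finite likelihood")

    # SE from the numerical second derivative of the profile log-likelihood
    step = min(1e-3, (h2 - _H2_LO) / 2, (_H2_HI - h2) / 2)
    if step > 1e-8:
        ll_m = _profile_reml(h2 - step, d, yt, Xt)[0]
        ll_p = _profile_reml(h2 + step, d, yt, Xt)[0]
        curv = (ll_p - 2.0 * ll + ll_m) / step**2
        h2_se = float(np.sqrt(-1.0 / curv)) if curv < 0 else float("nan")
    else:
        h2_se = float("nan")

    return VarianceComponents(
        sigma2_u=h2 * sigma2,
        sigma2_e=(1.0 - h2) * sigma2,
        h2=h2,
        h2_se=h2_se,
        loglik=float(ll),
        converged=bool(opt.success),
    )


# ----------------------------------------------------------------- MLM GWAS

def mlm_assoc(
    geno: GenotypeMatrix,
    trait_values: np.ndarray,
    covariate_design: np.ndarray,
    grm: GRM,
    vc: VarianceComponents,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-SNP mixed-model association for one trait.

    Uses the null-model variance components for every SNP: rotate into the
    GRM eigenbasis, whiten by W^{-1/2} with W = h2 D + (1-h2) I, project out
    the fixed effects, and fit each (mean-imputed) SNP by least squares in
    the whitened space.  Wald chi-square (1 df), two-sided p.  Returns a
    DataFrame (snp, beta, se, p, n_used, testable).
    """
    y = np.asarray(trait_values, float)
    X = np.asarray(covariate_design, float)
    keep = _complete_cases(y, X)
    y, X = y[keep], X[keep]
    n, p = X.shape

    if eig is not None and keep.all():
        d, U = eig
    else:
        G = grm.matrix[np.ix_(keep, keep)]
        d, U = np.linalg.eigh(G)
    d = np.maximum(d, 0.0)
    w = vc.h2 * d + (1.0 - vc.h2)
    scale = 1.0 / np.sqrt(w)

    yt = scale * (U.T @ y)
    Xt = scale[:, None] * (U.T @ X)
    S = geno.imputed_dosage()[keep, :]
    St = scale[:, None] * (U.T @ S)

    # residualise against fixed effects
    Q, _ = np.linalg.qr(Xt)
    yr = yt - Q @ (Q.T @ yt)
    Sr = St - Q @ (Q.T @ St)

    ss = np.einsum("ij,ij->j", Sr, Sr)
    testable = ss > 1e-10 * n
    beta = np.full(geno.n_snps, np.nan)
    se = np.full(geno.n_snps, np.nan)
    pval = np.full(geno.n_snps, np.nan)

    ss_safe = np.where(testable, ss, 1.0)
    b = (Sr.T @ yr) / ss_safe
    rss = float(yr @ yr) - b * b * ss_safe
    dof = n - p - 1
    if dof <= 0:
        raise ValueError("not enough observations for the association model")
    sigma2 = np.maximum(rss, 0.0) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        se_all = np.sqrt(sigma2 / ss_safe)
        chi2 = (b / se_all) ** 2
        p_all = stats.chi2.sf(chi2, df=1)
    beta[testable] = b[testable]
    se[testable] = se_all[testable]
    pval[testable] = np.maximum(p_all[testable], np.finfo(float).tiny)

    return pd.DataFrame(
        {
            "snp": geno.snp_meta["snp"].to_numpy(),
            "chrom": geno.snp_meta["chrom"].to_numpy(),
            "pos": geno.snp_meta["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": pval,
            "n_used": n,
            "testable": testable,
        }
    )


def run_gwas(
    geno: GenotypeMatrix,
    traits: TraitTable,
    grm: GRM | None = None,
    trait_names: list[str] | None = None,
) -> tuple[AssocResult, dict[str, VarianceComponents]]:
    """REML + mixed-model association for every trait; returns the combined
    AssocResult and the per-trait variance components."""
    if grm is None:
        grm = build_grm(geno)
    names = trait_names or traits.trait_names
    eig = np.linalg.eigh(grm.matrix)
    eig = (np.maximum(eig[0], 0.0), eig[1])

    betas, ses, ps, tst, n_used, vcs = {}, {}, {}, {}, {}, {}
    for t in names:
        y = traits.trait_values(t)
        X = build_design(traits, t)
        vc = reml_h2(y, X, grm, eig=eig)
        res = mlm_assoc(geno, y, X, grm, vc, eig=eig)
        betas[t] = res["beta"].to_numpy()
        ses[t] = res["se"].to_numpy()
        ps[t] = res["p"].to_numpy()
        tst[t] = res["testable"].to_numpy()
        n_used[t] = int(res["n_used"].iloc[0])
        vcs[t] = vc

    idx = pd.Index(geno.snp_meta["snp"], name="snp")
    assoc = AssocResult(
        beta=pd.DataFrame(betas, index=idx),
        se=pd.DataFrame(ses, index=idx),
        p=pd.DataFrame(ps, index=idx),
        n_used=pd.Series(n_used),
        testable=pd.DataFrame(tst, index=idx),
    )
    return assoc, vcs


# ----------------------------------------------------- subset h2 validation

def subset_h2_validation(
    geno: GenotypeMatrix,
    traits: TraitTable,
    subset_ids: list[str],
    n_iter: int = 100,
    seed: int | None = None,
    trait_names: list[str] | None = None,
) -> pd.DataFrame:
    """Compare subset-GRM heritability against the whole panel and random
    same-size subsets.

    For each trait, h2 is estimated with (a) a GRM from ``subset_ids``,
    (b) the whole-panel GRM, and (c) ``n_iter`` GRMs from random subsets of
    the same size.  Returns per-trait h2 values, the count of random
    iterations whose h2 falls below the focal subset's, and the focal
    subset's rank fraction among the random draws.
    """
    panel = set(geno.snp_meta["snp"])
    missing = [s for s in subset_ids if s not in panel]
    if missing:
        raise ValueError(f"subset SNPs not in panel: {missing[:5]}")
    k = len(subset_ids)
    if k > geno.n_snps:
        raise ValueError("subset larger than panel")
    names = trait_names or traits.trait_names
    rng = np.random.default_rng(seed)

    def h2_for(panel_geno: GenotypeMatrix) -> dict[str, VarianceComponents]:
        grm = build_grm(panel_geno)
        eig = np.linalg.eigh(grm.matrix)
        eig = (np.maximum(eig[0], 0.0), eig[1])
        return {
            t: reml_h2(traits.trait_values(t), build_design(traits, t), grm, eig=eig)
            for t in names
        }

    idx = geno.snp_ids.get_indexer(subset_ids)
    focal = h2_for(geno.take_snps(idx))
    whole = h2_for(geno)

    rand_h2 = {t: [] for t in names}
    for _ in range(n_iter):
        ridx = rng.choice(geno.n_snps, size=k, replace=False)
        vcs = h2_for(geno.take_snps(np.sort(ridx)))
        for t in names:
            rand_h2[t].append(vcs[t].h2)

    rows = []
    for t in names:
        r = np.asarray(rand_h2[t])
        below = int((r < focal[t].h2).sum())
        rows.append(
            {
                "trait": t,
                "h2_subset": focal[t].h2,
                "se_subset": focal[t].h2_se,
                "h2_whole": whole[t].h2,
                "se_whole": whole[t].h2_se,
                "h2_random_mean": float(r.mean()) if n_iter else np.nan,
                "h2_random_max": float(r.max()) if n_iter else np.nan,
                "n_random_below": below,
                "n_iter": n_iter,
                "rank_fraction": below / n_iter if n_iter else np.nan,
            }
        )
    return pd.DataFrame(rows)
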