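"""Association statistics for depot fatty-acid traits.

Single-variant ordinary least squares on inverse-normal-transformed traits
(per-variant OLS is the correct reduction of whole-genome regression when
individuals are unrelated and unstructured, as the synthetic cohort is),
variant QC filters (MAF > 0.01, INFO > 0.9), Cochran's Q depot
heterogeneity with I-squared, fixed-effect inverse-variance meta-analysis,
an in-module IRLS logistic regression for gene-diet interactions, and
multiple-testing thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Genome-wide significance threshold for flagging associations.
GENOME_WIDE_P = 5e-8

#: QC cutoffs: retain strictly above both.
MAF_CUTOFF = 0.01
INFO_CUTOFF = 0.9

#: Depot-specificity rule on the heterogeneity test.
HET_P_CUTOFF = 0.05
HET_I2_CUTOFF = 75.0


@dataclass(frozen=True)
class VariantAssociation:
    rsid: str
    chrom: int
    bp: int
    ea: str
    oa: str
    beta: float
    se: float
    p: float
    eaf: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")
        if not 0 <= self.eaf <= 1:
            raise ValueError("eaf must lie in [0, 1]")

    @property
    def genome_wide(self) -> bool:
        return self.p <= GENOME_WIDE_P

    def flipped(self) -> "VariantAssociation":
        """Same association expressed for the other allele."""
        return VariantAssociation(
            rsid=self.rsid,
            chrom=self.chrom,
            bp=self.bp,
            ea=self.oa,
            oa=self.ea,
            beta=-self.beta,
            se=self.se,
            p=self.p,
            eaf=1.0 - self.eaf,
            n=self.n,
        )


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    het_pval: float
    i_squared: float  # percent

    @property
    def depot_specific(self) -> bool:
        """Depot-specific effect: HetPval < 0.05 and I^2 > 75%."""
        return self.het_pval < HET_P_CUTOFF and self.i_squared > HET_I2_CUTOFF


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    p: float
    inputs: tuple[VariantAssociation, ...]


@dataclass(frozen=True)
class StratifiedEffect:
    genotype: int
    n: int
    effect: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class InteractionResult:
    gamma_hat: float
    se: float
    p: float
    coefficients: dict
    stratified: tuple[StratifiedEffect, ...]
    n_iterations: int


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Maps ranks through ``Phi^-1((r - 3/8) / (n + 1/4))``; ties receive
    average ranks, order is preserved.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or np.sum(np.isfinite(arr)) < 2:
        raise ValueError("need at least 2 finite values")
    if np.nanmax(arr) == np.nanmin(arr):
        raise ValueError("degenerate trait: all values identical")
    out = np.full(arr.shape, np.nan)
    finite = np.isfinite(arr)
    ranks = stats.rankdata(arr[finite], method="average")
    n = ranks.size
    out[finite] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def filter_variants(annotations: pd.DataFrame) -> pd.DataFrame:
    """Apply the QC filters MAF > 0.01 and INFO > 0.9 (strict inequalities).

    Expects columns EAF and INFO; returns the retained rows and logs how
    many variants each criterion removed.
    """
    for col in ("EAF", "INFO"):
        if col not in annotations.columns:
            raise KeyError(f"annotations table is missing required column {col!r}")
    eaf = annotations["EAF"].to_numpy(dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    pass_maf = maf > MAF_CUTOFF
    pass_info = annotations["INFO"].to_numpy(dtype=float) > INFO_CUTOFF
    keep = pass_maf & pass_info
    logger.info(
        "filter_variants: %d/%d retained (%d fail MAF, %d fail INFO)",
        keep.sum(),
        len(keep),
        (~pass_maf).sum(),
        (~pass_info).sum(),
    )
    return annotations.loc[keep]


def _design(dosage, covariates, n):
    cols = [np.ones(n), np.asarray(dosage, dtype=float)]
    names = ["intercept", "dosage"]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(f"cov{j}")
    return np.column_stack(cols), names


def _check_collinear(X, names):
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 100
    bad = [names[i] for i in np.nonzero(diag < tol)[0]]
    if bad:
        raise ValueError(f"collinear design; offending columns: {bad}")


def linear_assoc(
    dosage,
    trait_z,
    covariates=None,
    *,
    rsid: str = "var",
    chrom: int = 0,
    bp: int = 0,
    ea: str = "A",
    oa: str = "G",
) -> VariantAssociation:
    """Per-variant OLS of a transformed trait on dosage plus covariates.

    The dosage coefficient's p-value uses the large-sample normal
    approximation of the t statistic, as is conventional for GWAS output.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(trait_z, dtype=float)
    n = y.size
    X, names = _design(g, covariates, n)
    if n <= X.shape[1] + 1:
        raise ValueError("too few observations for the design")
    _check_collinear(X, names)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    z = beta / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    return VariantAssociation(
        rsid=rsid,
        chrom=chrom,
        bp=bp,
        ea=ea,
        oa=oa,
        beta=beta,
        se=se,
        p=p,
        eaf=float(g.mean() / 2.0),
        n=n,
    )


def linear_assoc_many(dosages, trait_z, covariates=None) -> pd.DataFrame:
    """Vectorized per-variant OLS across the columns of ``dosages``.

    Equivalent to calling :func:`linear_assoc` per column (Frisch-Waugh
    partialling-out of the covariates); returns a BETA/SE/P/EAF/N frame in
    variant order.
    """
    G = np.asarray(dosages, dtype=float)
    y = np.asarray(trait_z, dtype=float)
    n, m = G.shape
    C = [np.ones(n)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        C.append(cov[:, None] if cov.ndim == 1 else cov)
    C = np.column_stack(C)
    q, _ = np.linalg.qr(C)
    y_r = y - q @ (q.T @ y)
    G_r = G - q @ (q.T @ G)
    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_r
    beta = gy / gg
    dof = n - C.shape[1] - 1
    rss = (y_r @ y_r) - beta * gy
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / gg)
    z = beta / se
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    return pd.DataFrame(
        {"BETA": beta, "SE": se, "P": p, "EAF": G.mean(axis=0) / 2.0, "N": n}
    )


def _harmonize(a: VariantAssociation, b: VariantAssociation) -> VariantAssociation:
    """Express ``b`` on ``a``'s effect allele; error on allele mismatch."""
    if a.rsid != b.rsid:
        raise ValueError(f"variant mismatch: {a.rsid} vs {b.rsid}")
    if (a.ea, a.oa) == (b.ea, b.oa):
        return b
    if (a.ea, a.oa) == (b.oa, b.ea):
        return b.flipped()
    raise ValueError(
        f"{a.rsid}: alleles {b.ea}/{b.oa} cannot be harmonized to {a.ea}/{a.oa}"
    )


def cochran_q(
    assoc_sat: VariantAssociation, assoc_vat: VariantAssociation
) -> HeterogeneityResult:
    """Cochran's Q test between the two depot estimates, with I-squared.

    Q = sum w_i (beta_i - beta_pooled)^2 with w_i = 1/se_i^2 and one degree
    of freedom for two depots; I^2 = max(0, (Q - df)/Q) * 100.
    """
    assoc_vat = _harmonize(assoc_sat, assoc_vat)
    betas = np.array([assoc_sat.beta, assoc_vat.beta])
    w = 1.0 / np.array([assoc_sat.se, assoc_vat.se]) ** 2
    pooled = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - pooled) ** 2))
    df = 1
    het_pval = float(stats.chi2.sf(q, df))
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, het_pval=het_pval, i_squared=i2)


def ivw_meta(assocs) -> MetaResult:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    A single study passes through unchanged with a warning.
    """
    assocs = list(assocs)
    if not assocs:
        raise ValueError("no associations to meta-analyze")
    ref = assocs[0]
    assocs = [ref] + [_harmonize(ref, a) for a in assocs[1:]]
    if len(assocs) == 1:
        warnings.warn("ivw_meta called with a single study; passing through")
        a = assocs[0]
        return MetaResult(beta=a.beta, se=a.se, p=a.p, inputs=tuple(assocs))
    w = 1.0 / np.array([a.se for a in assocs]) ** 2
    betas = np.array([a.beta for a in assocs])
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    return MetaResult(beta=beta, se=se, p=p, inputs=tuple(assocs))


def _irls_logistic(X, y, max_iter=100, tol=1e-10):
    """Maximum-likelihood logistic fit by iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if np.any(w < 1e-12) and np.max(np.abs(beta)) > 30:
            raise ValueError(
                "separation detected (diverging coefficients); consider a "
                "penalized fit"
            )
        Xw = X * w[:, None]
        hess = X.T @ Xw
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix in IRLS") from exc
        beta = beta + step
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 50:
            raise ValueError(
                "separation detected (diverging coefficients); consider a "
                "penalized fit"
            )
        if np.max(np.abs(step)) < tol:
            cov = np.linalg.inv(hess)
            return beta, cov, it
    raise ValueError(f"IRLS did not converge in {max_iter} iterations")


def interaction_logistic(
    disease,
    dosage,
    diet_std,
    age,
    sex,
    max_iter: int = 100,
    stratified: bool = True,
) -> InteractionResult:
    """Gene-diet interaction logistic regression, adjusted for age and sex.

    Fits ``logit P(disease) = a + b_g*g + b_d*diet + gamma*(g*diet) + b_age*age
    + b_sex*sex`` by in-module IRLS and reports the Wald statistics of the
    interaction coefficient, plus diet effects stratified by rounded
    genotype (0/1/2 copies) in the style of a forest plot.
    """
    y = np.asarray(disease, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("disease outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; model is not estimable")
    g = np.asarray(dosage, dtype=float)
    d = np.asarray(diet_std, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    age_c = age - age.mean()
    X = np.column_stack([np.ones_like(y), g, d, g * d, age_c, sex])
    names = ["intercept", "genotype", "diet", "genotype_x_diet", "age", "sex"]
    beta, cov, n_iter = _irls_logistic(X, y, max_iter=max_iter)
    j = names.index("genotype_x_diet")
    se = float(np.sqrt(cov[j, j]))
    gamma_hat = float(beta[j])
    p = float(max(2.0 * stats.norm.sf(abs(gamma_hat / se)), np.finfo(float).tiny))

    strata = []
    hard = np.clip(np.rint(g), 0, 2).astype(int)
    for geno in (0, 1, 2) if stratified else ():
        sel = hard == geno
        if sel.sum() < 30 or y[sel].min() == y[sel].max():
            continue
        Xs = np.column_stack(
            [np.ones(sel.sum()), d[sel], age_c[sel], sex[sel]]
        )
        try:
            bs, cs, _ = _irls_logistic(Xs, y[sel], max_iter=max_iter)
        except ValueError:
            continue
        eff, eff_se = float(bs[1]), float(np.sqrt(cs[1, 1]))
        strata.append(
            StratifiedEffect(
                genotype=geno,
                n=int(sel.sum()),
                effect=eff,
                se=eff_se,
                ci_low=eff - 1.959963984540054 * eff_se,
                ci_high=eff + 1.959963984540054 * eff_se,
            )
        )
    return InteractionResult(
        gamma_hat=gamma_hat,
        se=se,
        p=p,
        coefficients=dict(zip(names, map(float, beta))),
        stratified=tuple(strata),
        n_iterations=n_iter,
    )


def significance_thresholds(n_tests: int, alpha: float = 0.05):
    """Per-test threshold alpha/m and its 1-significant-figure rounding.

    For 17 tests at alpha = 0.05 this is 0.00294..., conventionally quoted
    as p < 0.003.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    exact = alpha / n_tests
    rounded = float(f"{exact:.1g}")
    return exact, rounded


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    from statsmodels.stats.multitest import multipletests

    arr = np.asarray(pvalues, dtype=float)
    return multipletests(arr, method="fdr_bh")[1]


def lead_variant(assocs) -> VariantAssociation:
    """Variant with the lowest p; ties by larger |beta|, then lower bp."""
    assocs = list(assocs)
    if not assocs:
        raise ValueError("empty association list")
    return min(assocs, key=lambda a: (a.p, -abs(a.beta), a.bp))


def logistic_assoc(
    dosage,
    outcome,
    covariates=None,
    *,
    rsid: str = "var",
    chrom: int = 0,
    bp: int = 0,
    ea: str = "A",
    oa: str = "G",
) -> VariantAssociation:
    """Per-variant logistic association for a binary outcome (log-odds beta)."""
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(dosage, dtype=float)
    X, names = _design(g, covariates, y.size)
    _check_collinear(X, names)
    beta, cov, _ = _irls_logistic(X, y)
    se = float(np.sqrt(cov[1, 1]))
    b = float(beta[1])
    p = float(max(2.0 * stats.norm.sf(abs(b / se)), np.finfo(float).tiny))
    return VariantAssociation(
        rsid=rsid,
        chrom=chrom,
        bp=bp,
        ea=ea,
        oa=oa,
        beta=b,
        se=se,
        p=p,
        eaf=float(g.mean() / 2.0),
        n=int(y.size),
    )
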