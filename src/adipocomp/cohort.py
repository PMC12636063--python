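"""Synthetic cohort generator for the genetics statistics layer.

Produces the inputs a depot-fatty-acid GWAS consumes: Hardy-Weinberg
genotype dosages with an imputation-quality (INFO) score, depot fatty-acid
traits with effects planted on the latent NDB scale, covariates mirroring a
standard imaging-cohort GWAS (age, age squared, sex, genotyping array,
imaging centre, 10 principal components), dietary intakes, and binary
disease outcomes with an optional planted genotype x diet interaction.

Planting effects on latent NDB rather than directly on the fractions
exercises the full nonlinearity of the NDB -> fraction mapping, mirroring
the causal chain the imaging model assumes.  Because the fractions are
monotone in NDB and the traits are inverse-normal transformed downstream, a
planted effect of ``beta`` latent-noise SDs per allele is recovered on the
transformed-trait scale as approximately ``-beta`` for fSFA (decreasing in
NDB) and ``+beta`` for fPUFA.

Dosage model: the imputed dosage is the posterior mean of the genotype given
a noisy read of the hard call (``hard + Normal(0, sd)``) under the HWE
prior.  Like real imputation posterior means it lives in [0, 2] without
clipping, is unbiased for 2p, and has var(dosage) <= 2pq, so the standard
INFO ratio var(dosage)/(2*phat*qhat) sits in [0, 1] and decreases as the
noise scale grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitting import fractions_from_ndb

#: Dietary intake means/SDs (grams/day) typical of an imaging cohort.
DIET_DEFAULTS = {
    "sfa": (27.54, 11.78),
    "mufa": (26.96, 10.73),
    "pufa": (19.90, 7.51),
}


@dataclass(frozen=True)
class VariantSpec:
    """One simulated variant; betas are planted effects on latent depot NDB,
    expressed in units of the latent noise SD per effect-allele dosage."""

    rsid: str
    chrom: int
    bp: int
    ea: str
    oa: str
    maf: float
    beta_sat: float = 0.0
    beta_vat: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"{self.rsid}: maf must lie in (0, 0.5]")
        pair = frozenset((self.ea, self.oa))
        if pair in (frozenset("AT"), frozenset("CG")):
            raise ValueError(f"{self.rsid}: strand-ambiguous allele pair")


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic disease model with genotype, diet and interaction terms.

    P(disease) = logistic(intercept + beta_g*g + beta_diet*z(diet)
                 + gamma*g*z(diet) + beta_age*(age-60) + beta_sex*sex)
    """

    name: str
    intercept: float
    variant: str
    diet: str = "sfa"
    beta_g: float = 0.0
    beta_diet: float = 0.0
    gamma: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    n: int
    variants: tuple[VariantSpec, ...]
    diseases: tuple[DiseaseModel, ...] = ()
    dosage_noise_sd: float = 0.05
    sat_ndb_mean: float = 2.1
    vat_ndb_mean: float = 1.9
    ndb_noise_sd: float = 0.2
    #: covariate effects on latent NDB (both depots)
    age_effect: float = -0.003
    sex_effect: float = 0.04
    age_mean: float = 64.5
    age_sd: float = 7.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 50:
            raise ValueError("cohort size must be at least 50")
        object.__setattr__(self, "variants", tuple(self.variants))
        object.__setattr__(self, "diseases", tuple(self.diseases))


@dataclass
class GenotypeMatrix:
    dosage: np.ndarray  # (n, m) in [0, 2]
    hard_calls: np.ndarray  # (n, m) integer
    eaf: np.ndarray  # (m,) dosage-based effect-allele frequency
    info: np.ndarray  # (m,) imputation quality
    variants: tuple[VariantSpec, ...]

    def annotations(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsID": [v.rsid for v in self.variants],
                "CHR": [v.chrom for v in self.variants],
                "BP": [v.bp for v in self.variants],
                "EA": [v.ea for v in self.variants],
                "OA": [v.oa for v in self.variants],
                "EAF": self.eaf,
                "INFO": self.info,
            }
        )


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent named streams so each sub-generator is reproducible."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """HWE hard calls plus shrunken noisy dosages and INFO scores."""
    rng = rng or _child_rngs(spec.seed, 4)[0]
    mafs = np.array([v.maf for v in spec.variants])
    n, m = spec.n, len(spec.variants)
    hard = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
    sd = spec.dosage_noise_sd
    if sd > 0:
        noisy = hard + rng.normal(0.0, sd, size=(n, m))
        # posterior mean of g in {0,1,2} given the noisy read, HWE prior
        p = mafs[None, :]
        prior = np.stack(
            [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        )  # (3, 1, m)
        loglik = np.stack(
            [-((noisy - k) ** 2) / (2 * sd**2) for k in (0.0, 1.0, 2.0)]
        )
        loglik -= loglik.max(axis=0, keepdims=True)
        w = prior * np.exp(loglik)
        dosage = (w[1] + 2.0 * w[2]) / w.sum(axis=0)
    else:
        dosage = hard.copy()
    phat = dosage.mean(axis=0) / 2.0
    denom = 2.0 * phat * (1.0 - phat)
    with np.errstate(invalid="ignore", divide="ignore"):
        info = np.where(denom > 0, dosage.var(axis=0, ddof=1) / denom, 0.0)
    return GenotypeMatrix(
        dosage=dosage,
        hard_calls=hard.astype(int),
        eaf=phat,
        info=info,
        variants=spec.variants,
    )


def simulate_traits(
    genotypes: GenotypeMatrix,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Covariates plus depot fatty-acid fraction traits with planted effects.

    Latent depot NDB = depot baseline + sum(beta * ndb_noise_sd * dosage)
    + covariate effects + Gaussian noise, mapped through the NDB -> fraction
    formulas; depot-specific genetics arise from beta_sat != beta_vat.
    """
    rng = rng or _child_rngs(spec.seed, 4)[1]
    n = spec.n
    if genotypes.dosage.shape[0] != n:
        raise ValueError("genotype matrix does not match cohort size")
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 45, 82)
    sex = rng.binomial(1, 0.49, n)  # 1 = female
    pcs = rng.standard_normal((n, 10))
    array = rng.integers(0, 2, n)
    centre = rng.integers(0, 3, n)

    cov_effect = spec.age_effect * (age - spec.age_mean) + spec.sex_effect * sex
    df = pd.DataFrame(
        {
            "iid": [f"S{i:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "array": array,
            "centre": centre,
        }
    )
    for k in range(10):
        df[f"pc{k + 1}"] = pcs[:, k]

    betas = {
        "sat": np.array([v.beta_sat for v in spec.variants]),
        "vat": np.array([v.beta_vat for v in spec.variants]),
    }
    means = {"sat": spec.sat_ndb_mean, "vat": spec.vat_ndb_mean}
    for depot in ("sat", "vat"):
        genetic = genotypes.dosage @ (betas[depot] * spec.ndb_noise_sd)
        latent = (
            means[depot]
            + genetic
            + cov_effect
            + rng.normal(0.0, spec.ndb_noise_sd, n)
        )
        latent = np.clip(latent, 0.05, 5.95)
        fs, fm, fp = fractions_from_ndb(latent)
        df[f"{depot}_ndb"] = latent
        df[f"{depot}_fsfa"] = fs
        df[f"{depot}_fmufa"] = fm
        df[f"{depot}_fpufa"] = fp
    return df


def simulate_diet_disease(
    genotypes: GenotypeMatrix,
    traits: pd.DataFrame,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Add dietary intakes and binary disease outcomes to the trait table.

    Diets are Gaussian with cohort-typical means; each disease follows its
    logistic model with the diet standardized (z-scored) before forming the
    genotype x diet interaction term.
    """
    rng = rng or _child_rngs(spec.seed, 4)[2]
    df = traits.copy()
    n = len(df)
    for name, (mean, sd) in DIET_DEFAULTS.items():
        df[f"diet_{name}"] = np.clip(rng.normal(mean, sd, n), 0.0, None)
    rsid_index = {v.rsid: j for j, v in enumerate(genotypes.variants)}
    for model in spec.diseases:
        if model.variant not in rsid_index:
            raise KeyError(f"disease model references unknown variant {model.variant}")
        g = genotypes.dosage[:, rsid_index[model.variant]]
        diet = df[f"diet_{model.diet}"].to_numpy()
        diet_z = (diet - diet.mean()) / diet.std(ddof=0)
        eta = (
            model.intercept
            + model.beta_g * g
            + model.beta_diet * diet_z
            + model.gamma * g * diet_z
            + model.beta_age * (df["age"].to_numpy() - 60.0)
            + model.beta_sex * df["sex"].to_numpy()
        )
        p = 1.0 / (1.0 + np.exp(-eta))
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError(f"disease model {model.name} yields degenerate risk")
        df[model.name] = rng.binomial(1, p)
        df[f"{model.name}_risk"] = p
    return df


def simulate_ld_block(
    n: int,
    m: int,
    maf: float = 0.3,
    rho: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Genotypes for one LD block via correlated latent haplotypes.

    Each haplotype's allele indicators come from thresholding an
    exchangeable-correlation Gaussian (pairwise latent correlation ``rho``),
    giving pairwise allelic r^2 well below rho^2 at typical frequencies.
    Used by colocalization simulations only.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    thresh = _norm_ppf(maf)
    g = np.zeros((n, m))
    for _hap in range(2):
        shared = rng.standard_normal((n, 1))
        indiv = rng.standard_normal((n, m))
        latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indiv
        g += (latent < thresh).astype(float)
    return g


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))
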