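"""Approximate-Bayes-factor colocalization and a single-causal-variant PIP.

Per-variant evidence is the Wakefield approximate Bayes factor computed from
(beta, se) and a prior effect-size scale.  Colocalization enumerates the
five standard hypotheses for a locus shared between two traits:

  H0 no association; H1/H2 association with one trait only; H3 two distinct
  causal variants; H4 one shared causal variant.

All probability arithmetic is carried in log space with log-sum-exp, so
z-scores up to ~40 cannot underflow.  The per-variant posterior inclusion
probability offered here assumes a single causal variant per locus (a
softmax over log-ABFs) — an explicit simplification of multi-signal
fine mapping, and labelled as such wherever it is written out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: Default locus half-width: 100 kb each side of the lead variant (200 kb total).
DEFAULT_HALF_WIDTH_BP = 100_000

#: Default per-variant prior probabilities (the conventional coloc defaults).
P1_DEFAULT = 1e-4
P2_DEFAULT = 1e-4
P12_DEFAULT = 1e-5

#: Prior effect-size scales for quantitative and binary traits.
PRIOR_SD_QUANT = 0.15
PRIOR_SD_BINARY = 0.2

#: LD pruning threshold: drop variants with r^2 above this to any kept one.
R2_PRUNE_DEFAULT = 0.5


def log_abf(beta, se, prior_sd: float = PRIOR_SD_QUANT):
    """Wakefield log approximate Bayes factor for one association.

    With shrinkage ``r = prior_sd^2 / (prior_sd^2 + se^2)`` and ``z =
    beta/se``:  ``0.5 * (log(1 - r) + r * z^2)``.  Positive values favour
    association over the null.  Vectorized over beta/se.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    r = prior_sd**2 / (prior_sd**2 + se**2)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ColocResult:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    labf1: np.ndarray
    labf2: np.ndarray
    priors: tuple[float, float, float]
    n_variants: int

    def posteriors(self) -> dict:
        return {
            "PP.H0": self.pp_h0,
            "PP.H1": self.pp_h1,
            "PP.H2": self.pp_h2,
            "PP.H3": self.pp_h3,
            "PP.H4": self.pp_h4,
        }

    def colocalizes(self, threshold: float = 0.95) -> bool:
        """Shared-causal-variant call: PP.H4 at or above the threshold.

        The conventional primary rule uses 0.95; 0.70 is the usual
        sensitivity re-analysis and can only flag more loci.
        """
        return self.pp_h4 >= threshold


def coloc_pp(
    labf_trait1,
    labf_trait2,
    p1: float = P1_DEFAULT,
    p2: float = P2_DEFAULT,
    p12: float = P12_DEFAULT,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Standard single-causal-per-trait enumeration over variants i, j:
    H1 ~ p1 * sum_i ABF1_i; H2 ~ p2 * sum_j ABF2_j;
    H3 ~ p1*p2 * sum_{i != j} ABF1_i * ABF2_j; H4 ~ p12 * sum_i ABF1_i*ABF2_i;
    H0 ~ 1.  Computed with log-sum-exp throughout.
    """
    l1 = np.asarray(labf_trait1, dtype=float)
    l2 = np.asarray(labf_trait2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1 or l1.size == 0:
        raise ValueError("log-ABF vectors must be equal-length, 1-D, non-empty")
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    h0 = 0.0
    h1 = np.log(p1) + s1
    h2 = np.log(p2) + s2
    # off-diagonal double sum: exp(s1 + s2) - exp(s12), in log space
    if l1.size == 1:
        h3 = -np.inf
    else:
        diff = s12 - (s1 + s2)
        # diff <= 0 up to rounding; a non-negative value means the diagonal
        # carries all the mass and the off-diagonal sum underflows
        h3 = (
            -np.inf
            if diff >= 0
            else np.log(p1) + np.log(p2) + s1 + s2 + np.log1p(-np.exp(diff))
        )
    h4 = np.log(p12) + s12
    logs = np.array([h0, h1, h2, h3, h4])
    post = np.exp(logs - logsumexp(logs))
    return ColocResult(
        pp_h0=float(post[0]),
        pp_h1=float(post[1]),
        pp_h2=float(post[2]),
        pp_h3=float(post[3]),
        pp_h4=float(post[4]),
        labf1=l1,
        labf2=l2,
        priors=(p1, p2, p12),
        n_variants=int(l1.size),
    )


def ld_prune(pvalues, r2_matrix, threshold: float = R2_PRUNE_DEFAULT) -> np.ndarray:
    """Greedy LD pruning: indices of retained variants.

    Variants are visited in ascending p-value order; one is kept iff its
    r^2 with every previously kept variant stays at or below the threshold.
    Deterministic (ties resolved by original index order).
    """
    p = np.asarray(pvalues, dtype=float)
    r2 = np.asarray(r2_matrix, dtype=float)
    if r2.shape != (p.size, p.size):
        raise ValueError("r2 matrix shape does not match p-value vector")
    if not np.allclose(r2, r2.T, atol=1e-8):
        raise ValueError("r2 matrix must be symmetric")
    order = np.lexsort((np.arange(p.size), p))
    kept: list[int] = []
    for i in order:
        if all(r2[i, j] <= threshold for j in kept):
            kept.append(int(i))
    return np.array(sorted(kept), dtype=int)


def single_causal_pip(labf) -> np.ndarray:
    """Per-variant posterior inclusion probability, one-causal-variant model.

    Softmax of the log-ABFs under a flat prior over which single variant is
    causal; sums to 1.  A simplification of multi-signal fine mapping.
    """
    l = np.asarray(labf, dtype=float)
    if l.size == 0:
        raise ValueError("empty log-ABF vector")
    return np.exp(l - logsumexp(l))


def locus_window(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    lead_rsid: str,
    half_width_bp: int = DEFAULT_HALF_WIDTH_BP,
) -> pd.DataFrame:
    """Intersect and harmonize two summary-stats tables around a lead SNP.

    Keeps variants within ``half_width_bp`` of the lead's position present in
    both tables, flipping trait-2 betas where its EA/OA are swapped; raises
    on irreconcilable alleles.  Columns of the result: rsID, CHR, BP, EA,
    OA, BETA1, SE1, P1, BETA2, SE2, P2.
    """
    if lead_rsid not in set(stats1["rsID"]):
        raise KeyError(f"lead variant {lead_rsid!r} absent from trait-1 stats")
    lead = stats1.loc[stats1["rsID"] == lead_rsid].iloc[0]
    s1 = stats1.loc[
        (stats1["CHR"] == lead["CHR"])
        & ((stats1["BP"] - lead["BP"]).abs() <= half_width_bp)
    ]
    merged = s1.merge(stats2, on="rsID", suffixes=("_1", "_2"))
    rows = []
    for _, row in merged.iterrows():
        b2 = row["BETA_2"]
        if (row["EA_1"], row["OA_1"]) == (row["EA_2"], row["OA_2"]):
            pass
        elif (row["EA_1"], row["OA_1"]) == (row["OA_2"], row["EA_2"]):
            b2 = -b2
        else:
            raise ValueError(f"{row['rsID']}: alleles cannot be harmonized")
        rows.append(
            {
                "rsID": row["rsID"],
                "CHR": row["CHR_1"],
                "BP": row["BP_1"],
                "EA": row["EA_1"],
                "OA": row["OA_1"],
                "BETA1": row["BETA_1"],
                "SE1": row["SE_1"],
                "P1": row["P_1"],
                "BETA2": b2,
                "SE2": row["SE_2"],
                "P2": row["P_2"],
            }
        )
    return pd.DataFrame(rows)
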