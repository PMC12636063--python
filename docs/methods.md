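# Methods

This note documents the models implemented in `adipocomp`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish about real data.

## Signal model and spectral parameterization

The forward model for one voxel's magnitude signal at echo time `TE` (ms) is

    S(TE) = | W + F · m(TE) | · exp(−R2* · TE / 1000)

with water amplitude `W ≥ 0`, fat amplitude `F ≥ 0` (arbitrary units) and a
single effective relaxation rate `R2*` (1/s) shared by water and fat — ten
magnitude echoes cannot support separate water/fat decays robustly. `m(TE)`
is the proton-weighted mean phasor of the nine-peak triglyceride spectrum
with shifts 5.3, 5.2, 4.2, 2.75, 2.2, 2.0, 1.6, 1.3, 0.9 ppm and proton
counts

    2·NDB, 1, 4, 2·NMIDB, 6, 4·(NDB−NMIDB), 6, 6·(CL−4)−8·NDB+2·NMIDB, 9

per triglyceride (total `6·CL − 2·NDB + 2`). Off-resonance frequencies are
`(shift − 4.7 ppm) × 42.577 MHz/T × B0` with `B0 = 1.5 T` by default. The
default protocol carries the ten echo times 2.38–23.82 ms (ΔTE 2.38 ms), TR
27 ms, flip angle 20°; TR and flip angle are informational (no T1 term in a
magnitude model without steady-state correction, a known bias source listed
under limitations).

NMIDB is not free: the empirical constraint `NMIDB = 0.093 · NDB²` ties
polyunsaturation to total unsaturation, and CL is fixed at 17.4 carbons —
estimating chain length from ten echoes is not identifiable in practice, and
fixing it is the established convention for this spectral model.

Noise is Rician: independent Gaussian noise on the real and imaginary
channels before the magnitude. The phantom renderer applies the same model
voxel-wise; outside depot masks voxels are water-only.

## Voxel fit

Per voxel we minimize the sum of squared residuals over `(W, F, NDB, R2*)`
with a trust-region reflective bounded least-squares solver (analytic
Jacobian, tolerances 1e-10, ≤ 500 evaluations), NDB box-constrained to
`[1, 6]` and `R2* ∈ [0, 500]`. The magnitude objective is multi-modal in
NDB, so the fit restarts from NDB ∈ {1.5, 3, 5} with amplitudes initialized
by a two-point Dixon-style split of the first two echoes (near out-/in-phase
at 1.5 T). That split cannot decide which component is water and which is
fat, so a fourth start swaps the assignment; without it, water-dominant
voxels are systematically mis-fit as fat. The lowest residual wins; ties
break toward lower NDB. Voxels where no start converges keep missing values
and the volume-level convergence rate is logged.

Fractions follow from NDB:

    fUFA = (NDB − NMIDB)/3    fSFA = 1 − fUFA
    fPUFA = NMIDB/3           fMUFA = fUFA − fPUFA

The fMUFA/fPUFA split adopts the convention of one methylene-interrupted
pattern per (predominantly di-unsaturated) polyunsaturated chain with three
chains per triglyceride. The three fractions sum to 1 identically. Note
that `fMUFA = (NDB − 2·NMIDB)/3` turns negative above NDB ≈ 5.38, where the
quadratic NMIDB constraint overtakes NDB/2; fractions are reported
unclipped so the sum identity is exact, and adipose NDB in the 1.5–3 range
is far from that regime. Fat fraction is the signal-weighted `F/(W+F)`
without proton-density or T1 correction, applied uniformly.

Accuracy: with noiseless data the fit recovers NDB to well under 0.05 over
NDB ∈ [1.2, 4.5], fat fraction ∈ [0.5, 0.95], R2* ∈ [20, 60]. At noise SD
2 on a total amplitude of 100 (SNR ≈ 50), the Cramér–Rao bound for this
grid already implies a median absolute NDB error ≈ 0.37; the constrained
estimator achieves ≈ 0.32 because the box clips large excursions. Accuracy
claims below ~0.3 NDB at that noise level are therefore not attainable by
any estimator under this model.

## Phantom and post-processing

The phantom is deliberately crude: an annular SAT-like ring and elliptical
VAT-like blobs per slice (disjoint by construction), with spatially smooth
Gaussian truth fields (default SAT NDB 2.1 ± 0.2, VAT 1.9 ± 0.2 — the
values implied by depot fSFA around 0.44 and 0.47 — fat fraction 0.90/0.85,
R2* 40/45 s⁻¹, smoothing σ = 2 voxels). A 1-voxel rim of each mask carries
partial-volume contamination (fat fraction 0.15, NDB biased +0.8) so the
hygiene steps have something real to remove. Note the smoothing correlates
neighbouring voxels: the effective number of independent truth patches is
in the tens, so depot means wander by ~0.05 NDB between seeds.

Post-processing is (1) in-slice binary erosion of each depot mask (3×3
square element, 1 iteration; no through-slice erosion because the multiecho
acquisition is effectively single-slice and thin depots would empty), and
(2) exclusion of voxels with fitted fat fraction strictly below 0.20 (the
cutoff is inclusive at 0.20). Participant-level traits are arithmetic means
over retained voxels (configurable; the median is deliberately not the
default). On the default phantom the contaminated rim biases the naive SAT
fSFA mean by > 0.01; after erosion + filtering the residual bias is below
0.005.

## Synthetic cohort

Genotypes: hard calls are Binomial(2, MAF) (Hardy–Weinberg); imputed
dosages are the posterior mean of the genotype given a noisy read
(`hard + N(0, σ)`) under the HWE prior. Like real imputation posterior
means these live in [0, 2], are unbiased for 2·MAF, and shrink toward the
prior as σ grows, so the INFO score `var(dosage)/(2·p̂·(1−p̂))` falls from 1
toward 0 — variants generated with large σ exercise the INFO > 0.9 filter.
Strand-ambiguous (A/T, C/G) variants are refused by the generator so no
strand flipping is ever needed downstream.

Traits: planted effects act on a latent depot NDB (baseline + Σ β·dosage +
small age/sex effects + N(0, 0.2)), expressed in latent-noise SDs per
allele, then map through the fraction formulas. Because the fractions are
monotone in NDB and the traits are inverse-normal transformed before
association, a planted +β on latent NDB is recovered as ≈ −β on transformed
fSFA (and ≈ +β on fPUFA); the transform absorbs the nonlinearity entirely.
Depot-specific genetics arise from β_SAT ≠ β_VAT. Covariates (age ~ N(64.5,
7.7²) clipped to 45–82, sex, 10 standard-normal PCs, 2-level array, 3-level
centre) mirror the structure of an imaging-cohort GWAS; the PCs carry no
real population structure, which is precisely why plain OLS is the correct
engine here.

Diet and disease: intakes are Gaussian with cohort-typical means (SFA
27.54 ± 11.78 g, MUFA 26.96 ± 10.73 g, PUFA 19.90 ± 7.51 g); each disease
follows a logistic model with genotype, standardized-intake, genotype ×
intake, age and sex terms. Intercepts in the demo configuration target
prevalences of roughly 36% (hypertension), 5% (type 2 diabetes) and 9%
(cardiovascular disease).

Determinism: every generator draws from named, seed-derived RNG streams; a
single integer seed reproduces the whole cohort bit-for-bit.

## Statistics layer

- **INT**: rank-based inverse normal transform with the Blom offset
  `(r − 3/8)/(n + 1/4)`, average ranks for ties; constant traits are an
  error, not silently zeroed.
- **Association**: per-variant OLS of the transformed trait on dosage plus
  covariates; p-values from the normal approximation of the t statistic
  (the GWAS convention; immaterial at n ≥ 5000). A vectorized
  Frisch–Waugh implementation handles many variants and is tested to agree
  with per-variant OLS to 1e-10. Whole-genome ridge/mixed models are
  deliberately out of scope: without relatedness or structure in the
  simulator, per-variant OLS is their correct reduction.
- **QC**: retain MAF > 0.01 AND INFO > 0.9, both strict.
- **Heterogeneity**: Cochran's Q between depot estimates (allele-harmonized
  first; mismatched alleles are an error), df = 1, `I² = max(0,
  (Q−df)/Q)·100`; depot-specific iff HetPval < 0.05 and I² > 75.
- **Meta-analysis**: fixed-effect inverse variance; a single study passes
  through with a warning rather than an error.
- **Interaction**: logistic regression by in-module IRLS (Newton scoring on
  the expected information), Wald tests, with diverging coefficients
  reported as separation and a suggestion to penalize; genotype-stratified
  diet effects (rounded dosage 0/1/2) with 95% CIs reproduce the standard
  forest-plot layout. Verified against an independent likelihood maximizer
  to 1e-6.
- **Thresholds**: α/m with its 1-significant-figure quotation (17 tests at
  α = 0.05 → 0.00294, quoted 0.003) plus Benjamini–Hochberg adjusted
  p-values. The division-based threshold is the default because the quoted
  0.003 is numerically α/m, even when labelled FDR. Genome-wide flagging
  uses p ≤ 5e-8.

## Colocalization

Per-variant evidence is the Wakefield log-ABF `0.5·(log(1−r) + r·z²)` with
`r = w²/(w² + se²)`; prior effect scales default to `w = 0.15` for
quantitative and `0.2` for binary traits, per-configuration priors to
p1 = p2 = 1e-4, p12 = 1e-5 (the conventional defaults). Windows are 200 kb
around the lead SNP (lowest p, ties by |β| then position); variant sets are
intersected and allele-harmonized, then greedily pruned at r² > 0.5 in
ascending-p order before the five-hypothesis enumeration, which runs
entirely in log space (log-sum-exp; no underflow up to z = 40; the
off-diagonal H3 sum uses a stable log1p(−exp) of the diagonal correction).
The per-variant PIP is a softmax over log-ABFs under a one-causal-variant
assumption — an explicit simplification of multi-signal fine mapping, and
labelled as such in every output that contains it. The shared-signal call
is PP.H4 ≥ 0.95, with 0.70 as the sensitivity re-analysis; the relaxed rule
can only flag more loci.

## Pipeline

`run_pipeline` chains phantom → fit → postprocess → cohort → stats → coloc,
writing volumes as NIfTI-1, tables as TSV (GWAS tables use the
rsID/CHR/BP/EA/OA/BETA/SE/P/EAF/N column set, 1-based positions) and a
manifest of SHA-256 checksums keyed by stage; a stage failure marks the
manifest invalid and names the stage. Volumes default to uncompressed
`.nii` so checksums do not depend on gzip metadata. The configuration is a
strictly-validated YAML schema — unknown keys are rejected by name before
any stage runs — and its hash (excluding the output location) is recorded
in the manifest. The demo configuration uses a 48×48×3 phantom and a
2000-participant, ~200-variant cohort with one LD-block locus shared
between depots, one SAT-only and one VAT-only variant, and one diet
interaction variant; these sizes keep a full run around 15 s while leaving
every planted signal comfortably detectable. The sumstats reader tolerates
typeset journal tables (typographic minus signs, digit-grouping commas,
truncated scientific notation such as `4.E-293`).

## What the synthetic data do not show

The phantom has no anatomy, no B0 inhomogeneity, no T1 bias from the 20°
flip angle, no multi-compartment R2*, and its segmentations are generated,
not estimated — so passing tests validate the estimator and the pipeline
logic, not robustness to real artefacts. The cohort has no linkage
disequilibrium outside the designated block, no relatedness, no ancestry
structure and no genotyping batch effects; calibration results therefore
certify the statistics under their own assumptions, not under confounding.
Published effect sizes from restricted cohorts are used only to set
realistic generator scales, never as expected outputs.
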