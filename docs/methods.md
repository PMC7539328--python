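# Methods

`driftgarden` tests whether quantitative-trait divergence among populations
raised in a common garden exceeds the divergence genetic drift alone would
produce, and whether that excess tracks candidate environmental drivers.
This note documents the models, their assumptions, the defaults, and the
numerical choices.

## The drift null

Under pure drift from a common ancestral population, the vector of
population additive trait means α is distributed

    α ~ MVN(μ·1, 2·σ²_A·Θ)

where μ and σ²_A are the ancestral additive mean and variance and Θ is the
populations' coancestry matrix: θ_jk is the probability of identity by
descent of genes drawn from populations j and k, the same quantity that
governs neutral allele-frequency divergence. Everything in the package
hangs off this null.

## Coancestry from SNPs: the admixture F-model (`afm`)

Per locus l an ancestral allele frequency π_l drifts within each source
population s to

    p_sl ~ Beta(π_l·(1−a_s)/a_s, (1−π_l)·(1−a_s)/a_s)

(mean π_l, variance a_s·π_l(1−π_l), so a_s is the source's drift
intensity). Present-day populations mix sources with weights W (rows on the
simplex), giving allele frequencies q = W·p, genotypes Binomial(2, q_jl),
and coancestry θ_jk = Σ_s w_js·w_ks·a_s.

Priors: π ~ U(0,1), a ~ U(0.001, 0.999), W rows ~ Dirichlet(1). Sources
default to one per population, with an optional extra source shared by all
populations to represent regional admixture. Inference is multi-chain
random-walk Metropolis: logit-scale proposals for π, p, a (vectorised
across loci, which are conditionally independent), and Dirichlet proposals
centred on the current row for W (Metropolis–Hastings-corrected). Proposal
scales adapt toward ~30% acceptance during burn-in only, so the post-burn-in
chain is Markovian. Initialisation: π at pooled empirical frequencies
clipped to [0.02, 0.98], a at 0.05, W near identity rows, with small
seeded per-chain jitter to disperse the chains for the Gelman–Rubin
diagnostic. Monomorphic loci are dropped with a warning: they carry no
drift information and destabilise logit moves. Default run lengths (10
chains, 5,000 burn-in, 2,500 estimation iterations, thinning 5) are the
package's desk-scale defaults; convergence is always reported as the
per-entry PSRF over chains.

## Animal model (`quantgen`)

The univariate model is y = Xb + Z_p p + Z_m m + Z_a a + e: block fixed
effects, a random population-of-origin effect, seed weight either as a
fixed covariate (default, a proxy for maternal effects) or as a random
maternal term with variance V_M, breeding values with Var(a) = A·V_A, and
iid residuals. h² = V_A/V_T with V_T the sum of the configured components,
and CV_A = √V_A / trait mean (the trait mean is taken from the data).

Estimation is Gibbs sampling with conjugate updates; variance components
carry scaled-inverse-χ² priors with ν₀ = 1 and scales set to modest
fractions of the phenotypic variance (0.25·V_P for V_A and V_E, 0.1·V_P
for V_pop and V_M) — weak enough to be overwhelmed by a few hundred
families. Point estimates are posterior means.

Rather than sampling breeding values of unphenotyped mothers, the sampler
uses the exact marginal decomposition of A for phenotyped offspring under
unknown, unrelated sires: a family component with variance ρ_sib·V_A
(the sib–sib covariance) plus an individual component with variance
(1−ρ_sib)·V_A. ρ_sib defaults to 0.25 (half-sibs) and can be raised to 0.5
(full sibs) or toward 1 (selfing) for mating-system sensitivity analyses.
`build_A` still constructs the full tabular-method A for inspection and
testing. The bivariate model places an inverse-Wishart prior (df 4, scale
0.25·V_P per trait) on the 2×2 additive covariance G, so every draw is
positive definite and every genetic-correlation draw lies in [−1, 1];
residuals are modelled independent between traits, so traits need only
share families, not residual structure.

## Divergence model and selection tests (`divergence`)

The divergence model is the animal model with the population effect
replaced by the drift-null prior above. Coancestry uncertainty is
propagated by cycling one Θ posterior draw per sampler iteration (a
`fixed_theta` option collapses to the posterior mean). Near-singular Θ
draws get a 1e−8 ridge. Block effects are sampled as contrasts to the
first block so the trait level is carried by μ and α alone.

* **S-test.** Per retained draw, the Mahalanobis dispersion
  D = (α−μ1)ᵀ(2σ²_A Θ)⁻¹(α−μ1) is compared with the dispersion of a fresh
  drift-null draw (exactly χ²_P); S is the fraction of draws where the
  observed dispersion wins, with ties counting 0. S ≈ 0.5 is neutral,
  S → 1 diversifying, S → 0 homogenizing.
* **Population-wise S-test.** The drift envelope of population j is the
  central 95% interval of the null predictive μ + √(2σ²_A θ_jj)·z pooling
  posterior draws of (μ, σ²_A, θ_jj) — a predictive envelope, chosen over a
  plug-in envelope so posterior uncertainty honestly widens it. A
  population is "unusual" when ≥95% of its α_j posterior mass falls outside
  its envelope; the direction relative to μ is reported. This rule is
  deliberately stringent: a 5-null-SD planted shift is reliably detected at
  the emulated study's design size (16 populations × ~30 families), while
  smaller designs (8 × 15) trade power for the same false-flag control.
* **H and H\*.** Standardized divergences z_j = (α_j−μ)/√(2σ²_A θ_jj) are
  compared with a candidate driver. H uses the absolute covariance between
  z and the (standardized) driver against the same quantity for a
  drift-null draw: it is scale-sensitive, so strong divergence inflates H
  even when the driver is irrelevant — the documented false-positive mode.
  H* uses the absolute Pearson correlation against a freshly permuted
  driver per draw: scale-free, H* ≈ 0.5 whenever the driver explains no
  more than a random relabelling. Absolute values make both invariant to
  the driver's sign convention; the signed mean correlation is reported
  separately for interpretation.
* **Divergence PCA.** Posterior-mean z vectors across traits are centred
  (not rescaled — they are already on the drift-standardized scale) and
  decomposed by SVD to name multi-trait divergence axes.

## Trait scores (`traits`)

Bud Break Score is the sum of two 1–5 phenology scores (2–10, higher =
earlier). Growth Increment is fall minus spring height in mm, preserved
when ≤ 0 and flagged as dieback. The weighted Water Stress Score combines
0–3 drought scores at 1–6 strictly increasing early-summer Julian dates
with inverse-log-date weights normalised to sum to one: raw ln(JD) weights
would up-weight *later* observations, while the score's purpose is to
up-weight the earliest (most drought-sensitive) responses, so weights
w_i ∝ 1/ln(JD_i) are used. The score is bounded in [0, 3], reaches the
bounds exactly at all-0 / all-3 scores, and is strictly monotone in every
single score.

## Environment (`env`)

The 19 bioclim variables follow the standard definitions with quarters as
three consecutive calendar months including the Dec–Jan wraparound;
temperature seasonality is SD×100 (sample SD), precipitation seasonality is
the CV in percent computed on monthly precipitation + 1 mm so fully dry
months are tolerated. Monthly *mean* temperature series carry no diurnal
range, so bio2 and bio3 are returned as defined-missing (NaN) unless
monthly tmin/tmax are supplied — nothing is invented. Delta-method
downscaling is additive for temperature and multiplicative (clipped at 0)
for precipitation. The environmental PCA standardises variables
(divisor n−1) and fixes signs so each component's largest-magnitude
loading is positive.

## Synthetic data (`simulate`)

The generator emulates the study design the package targets: 16
populations, 20 genotyped adults/population at ~357 SNPs, ~30
open-pollinated maternal families of ~17 seedlings per population, 4
greenhouse blocks in 2 greenhouses. Default variance components σ²_A =
0.4, σ²_E = 0.6 (h² ≈ 0.4, mid-range for juvenile conifer traits), σ²_M =
0, ancestral mean 10. Coancestry presets: "star" (independent drift per
population, diagonal Θ) and "admixed" (each population mixes its own
source with one shared source — regional clusters; setting one
population's admixture weight to 0 isolates it, the island analogue). The
study preset spreads drift over 0.02–0.12 with one 0.30 island.

Phenotypes: α_pop = ancestral mean + MVN(0, 2σ²_A Θ) + planted shifts
(`driver_slope · driver` for selection scenarios); mothers deviate
N(0, σ²_A) around α_pop; offspring inherit half the maternal deviation
plus an N(0, 0.75σ²_A) Mendelian/paternal term — sires are open-pollinated
trees of the same population, so the full population mean is transmitted
and sibs covary at 0.25σ²_A. Seed weight is a noisy linear monotone proxy
of the latent maternal effect (thousand-seed-weight scale, ~50 g),
matching its use as a covariate rather than a variance component of
interest.

What the generator does *not* emulate: linkage between SNPs, spatial
isolation-by-distance (Θ is specified, not emergent), genotype–environment
interaction, non-normal trait distributions, inbred founders, and
measurement error structure beyond iid noise. Passing recovery tests
therefore show the estimators are correct under the stated model, not that
the model captures every feature of real common-garden data.

## Numerical choices and limitations

* Missing genotypes: sentinel −1 in memory, "NA" in CSV, "./." in VCF; no
  imputation, no phasing. SNP filters keep boundary loci (MAF exactly 5%,
  missingness exactly 10%); MAF is pooled across populations — per-population
  filtering is a documented alternative the package does not implement.
* PSRF is the classical (non-rank-normalised, non-split) Gelman–Rubin form;
  all-constant chains return 1.0 with a warning.
* Gibbs variance draws use scaled-inverse-χ² conditionals; the Mahalanobis
  comparison in the S-test counts ties as 0 (they have measure zero).
* Desk-scale default run lengths (reported with every result) are chosen so
  a full pipeline runs in minutes on one core; the per-entry / per-scalar
  PSRF output is the guard against under-running, and results failing the
  1.1 / 1.15 thresholds should be re-run longer.
* Multivariate (trait-pair) divergence models are out of scope — the
  PCA-of-divergences summary stands in. Bivariate animal models are
  supported; three- and four-trait models are not.
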