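# Methods

This note documents the models, estimators and default choices behind
`poolscape`, in the order the pipeline runs them, together with what the
synthetic landscape does and does not emulate.

## The synthetic landscape

The generator produces the study layout the analysis modules expect: 15
localities placed along a one-dimensional west–east axis embedded in
latitude/longitude (≈ 13–21°E, 63.4–64.6°N), each with one old-growth stand
and two planted stands jittered within ~2 km. Seven climate variables
(AIT, CMT, CONT, DegD0, DegD5, MTC, PCQ) are linear functions of the shared
axis plus independent Gaussian noise (default 5% of each variable's range),
which makes them strongly mutually collinear — as real temperature/aridity
summaries of a single regional gradient are. Variable ranges are loosely
modelled on ENVIREM values for northern Sweden (e.g. continentality falling
from 27 to 21 °C toward the coast).

**Allele frequencies.** Neutral SNPs follow the Balding–Nichols model: an
ancestral frequency π ~ Uniform(0.05, 0.95) and independent per-stand
frequencies Beta-distributed with mean π and variance π(1−π)·F, with
F = `fst_background` = 0.05 by default (differentiation of the order seen
among conifer stands). Adaptive SNPs (default 100 per climate variable,
drivers cycling over the seven variables, on top of 20,000 neutral SNPs)
put the *old-stand* mean on a logistic cline,
logistic(logit(π) + s·z), where z is the standardized driver at the stand
and s = `slope_logit` = 1.0 — a strong cline, moving the expected frequency
by roughly ±0.25 per driver standard deviation near π = 0.5. Planted-stand
means are mixed toward the ancestral frequency,
(1−d)·cline + d·π with d = `source_decoupling` = 0.8, before the same Beta
drift noise is applied. This is the minimal mechanism for "replanted from
non-local sources": planted stands keep species-wide variation but lose
most of the locally adaptive signal. The decoupling parameter is a modelling
stand-in, not an estimate of any real seed-transfer process.

**Pooled reads.** Per SNP and stand, k alt haplotypes ~ Binomial(60, freq)
(pools of 30 diploid trees), depth ~ negative binomial with mean 1850 (the
coverage scale of deep pooled GBS) and dispersion 5 (coefficient of
variation ≈ 0.45, so the coverage-quantile filters have something to do),
and alt reads ~ Binomial(depth, q) with q = (k/60)(1−e) + (1−k/60)e,
e = 10⁻³ per-read error. Reads resample haplotypes *with replacement*,
which is what makes pool-seq estimators differ from individual sequencing.

**Future scenario.** The future climate adds a per-variable shift of about
one across-stand standard deviation (warmer and slightly drier), modulated
±15% along the axis. The modulation matters: a spatially uniform shift is
removed entirely by the standardization inside climate distances
(translation invariance), which would make future-scenario Mantel results
identical to current ones by construction.

**What the generator does not emulate.** SNPs are exchangeable and
independent: no linkage, no coalescent/migration history, no GBS
restriction-site structure, no reference bias. In particular there is *no
neutral spatial structure* — neutral drift is iid across stands. Two
consequences for interpreting results on synthetic data: (i) all geographic
signal in all-SNP F<sub>ST</sub> flows through the adaptive clines, so
"isolation by distance" on the default landscape is climate-driven and
strong, unlike the weak neutral IBD typical of real wind-pollinated
conifers; and (ii) the principal components of the frequency matrix are
dominated by the adaptive cline axis itself, so the latent-factor detector
conditions away most of the true clinal signal and behaves very
conservatively (its hits are few and largely borderline loci). Passing
tests therefore demonstrate correct estimator behaviour and the intended
old-vs-planted contrasts, not realistic absolute power for structured real
data.

## Filters and frequency estimation

Three retention rules, applied in order: (a) every pool ≥ 60 reads (1× per
haplotype); (b) every pool's depth within its own 0.1–99.9% depth quantiles,
computed per pool across the SNPs surviving (a) — per-pool rather than
global quantiles is the pool-seq convention, and the bounds are order
statistics (inclusive, observed depths) so re-filtering filtered data is
stable; (c) depth-weighted minor-allele frequency across all pools ≥ 0.008
(≈ a single-haplotype frequency in one pool, i.e. a dataset-wide singleton
filter; a per-pool mode exists). Frequencies are raw read proportions with
no haploid-size shrinkage — at 1850× coverage the read-sampling error is
negligible next to the haplotype-sampling error, and the proportion is the
standard pool-seq estimator.

## Pool-seq F<sub>ST</sub>

Let pool i have depth c_i, haploid size n_i, alt reads y_i, p̂_i = y_i/c_i.
Write a = 1−Q₁ (within-deme heterozygosity) and b = 1−Q₂ (between-deme).
Two distinct reads from pool i come from distinct haplotypes with
probability 1−1/n_i, so E[(read pair differs)] = (1−1/n_i)·a. From the
read-level ANOVA decomposition,

    E[SSI] = (a/2)·S_a,                      SSI = Σ c_i p̂_i(1−p̂_i)
    E[SSP] = (a/2)(T_a−S_a) + (b/2)·U,       SSP = Σ c_i (p̂_i−p̄)²

with S_a = Σ(c_i−1)(1−1/n_i), T_a = Σc_i(c_i−1)(1−1/n_i)/C₁,
U = C₁−C₂/C₁, C₁ = Σc_i, C₂ = Σc_i². Solving gives per-locus unbiased
components â = 2·SSI/S_a and b̂ = (2·SSP + â(S_a−T_a))/U, and the
multilocus estimate is the ratio of sums F̂ = Σ(b̂−â)/Σb̂ (single-locus and
multilocus estimates coincide for one locus). As n_i → ∞ this reduces
algebraically to the classical Weir–Cockerham ANOVA with read depth in the
sample-size role. Loci need depth ≥ 2 in both pools; negative estimates are
reported as-is (clamping would bias downstream Mantel statistics). The
estimator is validated by its closed-form limits (0 under identical
frequencies, 1 under opposite fixation) and by Balding–Nichols parameter
recovery (simulated F = 0.05 recovered within ±0.01 over replicates).

## Outgroup f₃

f₃(O; A, B) = mean over loci of (p̂_O−p̂_A)(p̂_O−p̂_B) − v̂_O, where v̂_O
estimates the sampling variance of the outgroup's frequency,
v̂ = ĥ·(1/n + 1/c − 1/(nc)) with ĥ = p̂(1−p̂)·c/((c−1)(1−1/n)) the
unbiased p(1−p) estimate. The correction removes the upward bias from
p̂_O entering the product twice; cross-pool terms are unbiased because
pools are independent. Standard errors use a delete-one block jackknife
over contiguous blocks of 500 SNPs (the panel has no linkage map; blocks
guard against local dependence in real data). In the locality scan, the
outgroup role cycles through the three stands: old as outgroup means the
two sources are planted ("P vs. P"), otherwise "O vs. P"; under source
decoupling the two planted stands share their deviation from the local
cline, which raises f₃(P vs. P) above f₃(O vs. P) — the expected signature
of a shared non-local origin.

## Gene–environment association

**Correlation null.** The threshold is the 99.9% quantile of Pearson r
between a random frequency vector of length n and a randomly selected
climate variable, from 10⁶ draws. Draws are iid standard Gaussian by
default: for spherical draws the null of r against *any* fixed vector is
exactly Student-t, giving r* = t₀.₉₉₉/√(t²+n−2) = 0.7301 at n = 15 — and
this threshold also calibrates Beta-drift neutral SNPs to the 10⁻³ design
false-positive rate (measured 1.04×10⁻³ on 2×10⁵ neutral SNPs). A
Uniform(0,1) mode is provided; against near-collinear, evenly spaced
gradient vectors its 99.9% quantile sits visibly higher (~0.74 at n = 15)
because the t-transform is only exact for spherical draws. The threshold is
computed once from the old-stand count (n = 15) and applied to both stand
sets; exceedance is one-sided (r > r*, matching an upper-quantile null),
with an |r| mode behind a flag. Ties at the threshold do not pass.

**Latent-factor regression.** Per climate variable and SNP, OLS of
frequency on [1, variable, PC₁…PC₄] where the PCs come from the
column-centered frequency matrix of the same stand set (K = 4 from the
scree plot of the real-scale panel). The variable's t-scores are
recalibrated by the genomic inflation factor λ = median(t²)/χ²₁(0.5) and
converted to p-values via χ²₁ on t²/λ — the standard LFMM calibration
recipe. This recipe treats t-scores as Gaussian; with only 15 stands
(9 residual df) the Student tails are heavier than Gaussian, so the null
tail beyond the Bonferroni point is somewhat inflated at small n (and more
so for 15 old stands than 30 planted ones). We keep the recipe as published
rather than substituting an exact-t transform, and note that the
recalibration leaves p-value ranks unchanged (tested). Significance is
Bonferroni: p < α/M with α = 0.05.

## Mantel suite

Distance matrices are vectorized over the strictly lower triangle.
Climate distance standardizes each variable (mean 0, SD 1, ddof = 1) and
takes Euclidean distances — one named variable for the per-variable tables
(equivalently |Δz|), all seven for the global analysis. Mantel r is the
Pearson correlation of two such vectors; the partial statistic is the
first-order partial correlation controlling the third matrix. Significance
permutes the first matrix's labels, recomputing the (partial) statistic,
one-sided in the upper tail (the vegan convention), with
p = (#{r_perm ≥ r_obs}+1)/(n_perm+1); the default n_perm = 9999 makes
p < 10⁻³ attainable. Per-variable IBE rows use that variable's outlier
SNPs for the outlier F<sub>ST</sub> matrix and all SNPs outside the
report's full outlier set for background F<sub>ST</sub>; variables with
fewer than two outliers yield NaN (reported, counted as non-significant).
Type-I error of both tests is verified at nominal 0.05 over independent
null replicates.

## RONA

Per SNP, OLS of stand frequency on the *raw* climate variable (slopes keep
per-unit meaning; no standardization here). The single-set operation
follows the "theoretical shift" closed form |b̂|·|Δe|, R²-weighted:

    RONA_s = Σ_l R²_l · |b̂_l|·|e_fut,s − e_cur,s| / Σ_l R²_l

(zero shift ⇒ exactly 0; a single SNP gives exactly |b̂·Δe|). The
study-level protocol differs in two deliberate ways. First, the associated
SNP set per method × variable is the union across stand sets — the planted
set alone often has no associations for a variable, yet its risk is still
defined. Second, by default the regressions are fitted on the old-growth
stands and the *observed-current* shift |fitted(e_future) − observed(e_now)|
is used: the old-growth cline is the empirical model of locally adapted
allele frequencies, and a stand's risk includes any standing mismatch
between its current frequencies and that cline. This is what makes
recently planted, source-decoupled stands score higher — fitting each set
on itself with the theoretical shift would let the planted stands' own
flattened cline absorb their maladaptation and mechanically give them
*lower* RONA. Both alternatives (`reference="own"`, `shift="theoretical"`)
remain available. RONA is a proxy for adaptive mismatch in allele-frequency
units; it says nothing about fitness.

## Orchestration, sizes and determinism

The pipeline derives all stage seeds from one master seed
(`numpy.random.SeedSequence`), so a config reproduces every output file
byte for byte. Diversity summaries are computed on coverage-filtered but
not MAF-filtered counts, so invariant sites remain countable. Default
problem sizes — 20,000 neutral + 700 adaptive SNPs, 45 pools, 10⁶ null
draws, 9,999 permutations — run the full pipeline in well under a minute
on one core; the test suite uses smaller landscapes (hundreds to a few
thousand SNPs, 4–15 localities) chosen so each check's statistical signal
is still decisive, and states its replicate counts inline.

## Known limitations

* No neutral spatial structure in the generator (see above): weak-IBD
  patterns of real conifer data are not reproduced, and the latent-factor
  detector's absolute power here understates its value on structured data.
* The Monte-Carlo correlation null assumes iid frequencies across stands;
  spatially autocorrelated neutral structure would inflate its false-positive
  rate (that is precisely the case the latent-factor method exists for).
* The F<sub>ST</sub> estimator ignores sequencing error (negligible at
  e = 10⁻³ relative to drift and sampling noise) and assumes known pool
  sizes.
* RONA's linear response model is a first-order local approximation; the
  logistic generating clines are only locally linear in the driver.
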