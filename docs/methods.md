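# Methods

## Count model and normalization

Counts in both assays (total RNA and ribosome-protected fragments, RPFs) are
modeled as negative binomial with a mean/dispersion parameterization,
Var = μ + φμ²; φ = 0 is treated as the Poisson limit throughout. Between-
sample normalization is TMM: for each sample against a reference (the sample
whose 75th percentile of count/library-size is closest to the mean such
percentile), gene-wise M = log₂ ratios and A = average log abundances are
computed on genes nonzero in both samples (no pseudocount), the M values are
trimmed 30% on each side by rank and the A values 5% on each side, and the
factor is 2 raised to the inverse-variance-weighted mean of the surviving M
values, with weights from the delta-method binomial variance
(N−y)/(Ny) summed over the pair. Factors are rescaled to geometric mean 1 so
effective library sizes remain on the raw scale. When fewer genes survive
trimming than expected, or all M values are below 1e-6, the factor falls back
to 1. The implementation agrees with an independently coded brute-force
version to 1e-8 and with edgeR's `calcNormFactors(method="TMM")` to 1e-6 on
random NB matrices (both checked in the test suite).

TMM corrects library composition only up to its trimming behavior: when
planted changes all point one way, the trimmed mean retains a small residual
offset. The simulator therefore plants transcriptional effects with balanced
random signs (see below), which is also the realistic regime.

## Differential expression

Libraries are first equalized: counts are scaled to the geometric-mean
effective library size and rounded half-to-even back to integers. This
deterministic scaling replaces quantile-adjusted pseudo-data; the
simplification is validated by the type-I calibration test (fraction of
p < 0.05 on an all-null NB simulation is 0.05 ± 0.01).

A single common dispersion is estimated by maximizing the summed per-gene NB
conditional log-likelihood, conditioning on each gene's within-condition
total (which removes the per-gene mean as a nuisance parameter):
P(y|z) = ∏ᵢ C(yᵢ+r−1, yᵢ) / C(z+nr−1, z) with r = 1/φ. The optimum over
φ ∈ [1e-6, 10] is bracketed on a 25-point log grid and refined by
golden-section search. Tagwise shrinkage is deliberately not implemented;
with a common planted φ the common estimator is the right tool, and the
recovery tests show it is accurate to a few percent at 2000 genes.

Each gene is then tested with an exact conditional test: given the total
t = ΣA + ΣB, the group sums are NB-sum distributed (the sum of n iid
NB(r, p) is NB(nr, p); Poisson at φ = 0) with common mean t/(n_A+n_B) per
sample, and p is the sum of probabilities of all splits whose point
probability is at most that of the observed split (a float tolerance of
1e-10 in log space absorbs ties). This two-sided rule is well defined for
the asymmetric NB-sum distribution, unlike doubling the smaller tail.
t = 0 returns p = 1 by convention. Fold changes are
log₂((mean_B + c)/(mean_A + c)) with prior count c = 0.5 to keep zero-count
genes finite. Multiple testing uses Benjamini–Hochberg (via statsmodels);
significance is FDR < 0.01 and |log₂FC| > 1, both exposed as configuration.

## Differential translation efficiency

ΔTE = log₂FC(RPF) − log₂FC(RNA) for the same contrast. The variance of each
assay's fold change is approximated by the delta method as
Var(log₂FC) ≈ (1/ln²2) Σ_{g∈{A,B}} (1/(μ̂_g+c) + φ)/n_g, with μ̂ the group
mean of equalized counts and c the same prior count, and the two assays'
variances add (independent libraries). The Wald z gives a two-sided normal
p, BH-adjusted. On fully coupled simulations the p distribution is uniform
to KS distance < 0.05 at 5000 genes, and a planted ΔTE of ±2 is recovered
with bias < 0.1 — both are acceptance checks. An interaction GLM would be
the heavier alternative; the Wald construction needs only quantities the DE
stage already produces and is fully testable, which is why it is the
package's definition.

## Decoupling classification

Genes are classified from the two DE tables, in order: (a) neither assay
significant → UNCHANGED; (b) ΔTE > band and RPF significant → TE_UP;
(c) ΔTE < −band and either assay significant → TE_DOWN; (d) both significant
and |ΔTE| ≤ band → TRANSCRIPTIONAL; (e) otherwise UNCHANGED. The band
defaults to 1 log₂ unit. The significance guards in (b)/(c) are this
package's default ("guarded" mode) to suppress noise-driven calls among
weakly expressed genes; a "literal" mode classifies purely by the band among
genes significant in either assay. The decoupled fraction is
|TE_UP ∪ TE_DOWN| / |TE_UP ∪ TE_DOWN ∪ TRANSCRIPTIONAL| and is reported as
NaN when no gene is classified.

The per-condition global TE slope is OLS of log₂(RPF RPKM + 0.01) on
log₂(RNA RPKM + 0.01), replicates averaged, on genes passing the expression
filter; the 95% CI is slope ± t₀.₉₇₅,n−₂·SE, with Monte-Carlo coverage
93–97% at 5000 genes checked in acceptance. Which genes enter the fit is
configurable; the filtered set is the default. Scatter groups among
highly transcribed genes (RNA RPKM above the 0.90 quantile) are defined by
regression residuals: below the residual_q quantile RED (low translation),
above 1−residual_q BLUE (very high translation), the rest GREEN; quantiles
are computed within the high-transcription set with strict comparisons, so
residual_q → 0 empties the extreme groups.

## Expression filters

A gene is expressed in a condition when its CPM reaches 1 in all of that
condition's replicates; by default a gene is retained when expressed in at
least one condition ("any_condition"), since a gene active only in the
perturbed line must survive the filter. The stricter "all_conditions" scope
is available behind a switch. Presence flags use RPKM > 1 in all replicates
of a condition. Thresholds are parameters, not constants.

## Gene-set enrichment

Preranked GSEA sorts genes by a real metric (descending); members increment
the running sum by |metric|^p normalized to total 1 (p = 1 default),
non-members decrement by 1/(N−k); ES is the signed maximum deviation. The
null permutes set membership (uniform random sets of equal size,
n_perm = 1000 default, seed required), p = (1 + #{|ES*| ≥ |ES|})/(n_perm+1),
NES = ES / mean |ES*| of the same sign. Gene-set permutation is the
appropriate null for preranked input; phenotype permutation is not
applicable. The direction field reports whether the extreme lands in the
left (top) or right half of the list, matching barcode-plot skew language.
A set covering the whole ranking is an error. Over-representation is the
upper-tail hypergeometric (scipy) with BH across sets; fold enrichment is
(overlap/|query|)/(|set ∩ universe|/|universe|).

## Polysome qPCR

Each gradient fraction carries a fixed-mass spike-in RNA; per-fraction
technical offsets are removed by Cq_corr = Cq − (spike_Cq − mean spike_Cq
within the sample run). The reference choice (mean spike Cq) only shifts all
corrected values by a constant, which the relative-quantity transform
q = 2^(Cq_min − Cq) cancels — the tests include this invariance. The
polysome/monosome TE ratio is Σ_poly q / Σ_mono q per replicate, aggregated
by mean ± SD; the monosome/polysome boundary is a required parameter with
default mono = {7, 8}, poly = {9…14} within the 7–14 gradient window.
A reciprocal-Cq display transform exists in the literature but is not
proportional to abundance and is not used for quantification here. Profile
shifts are differences of quantity-weighted mean fraction indices
(Σ f·π_f), with a one-sided bootstrap over replicates (resampling with
replacement; p = fraction of bootstrap shifts ≤ 0, floored at 1/n_boot);
with a single replicate the statistic is returned without a p.

## Synthetic data

The generator emulates the targeted experimental design: 3 cell lines × 3
biological replicates × 2 assays, NB counts. Defaults: 2000 genes; class mix
60% null, 20% transcriptional, 10% TE-up, 10% TE-down; |log₂FC| = 2 for
transcriptional effects (with balanced random signs) and ΔTE = ±2 for the
decoupled classes — the 4-fold regime the classification thresholds target;
φ = 0.05, typical of cell-line biological replicates; baseline abundances
log-normal (log-mean 5.7, log-sd 0.4, i.e. median ≈ 300 counts); latent
per-gene log₂ TE offsets N(0, 0.5); library sizes uniform in
[0.8M, 1.2M]. The second condition carries the planted effects, applied
symmetrically (±lfc/2) so the planted contrast is exact; remaining
conditions are unperturbed controls, mirroring a design with two control
lines. Gene lengths are uniform in [300, 5000] nt purely to exercise RPKM
code paths. Class counts follow the proportions by largest remainder;
everything is reproducible bit-for-bit from the seed.

The Cq generator plants a two-block mass profile per gene (monosome share
1/(1+ρ), polysome share ρ/(1+ρ) for true ratio ρ, or an explicit profile),
converts to Cq = base − log₂ q, and adds fraction-specific technical offsets
shared between gene and spike Cq plus N(0, noise_sd) cycles of noise.
Offsets are drawn mean-zero across fractions so spike correction restores
the noise-free truth exactly; a non-zero mean would only add a constant that
the quantity transform cancels. The gene-set generator emits one set drawn
from the planted TE-up genes plus uniform decoys, in GMT.

What the simulations do not emulate: positional read structure (UTR/CDS
coverage, P-site offsets), gene-length–dependent counting biases, tagwise
dispersion heterogeneity, correlated replicates, batch effects, or partial
mass overlap between monosome and polysome blocks. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated NB
model, not robustness to those real-data complications.

## Numerical choices

Exact-test tie tolerance 1e-10 in log probability; dispersion search bounds
[1e-6, 10]; BH via statsmodels with explicit NaN rejection; rounding in
library equalization is half-to-even; GSEA permutation masks are drawn
vectorized from a seeded generator, so results are identical across runs and
platforms; all simulation sizes in tests (200–5000 genes, 100–1000
replicates/permutations) were chosen as the smallest scales at which the
statistical assertions are stable, and are stated in each test.

## Known limitations

Common dispersion only (a tagwise method would be needed for real data with
dispersion trends); two-group exact test only (no GLM designs, no batch
terms); the TE slope is a descriptive OLS summary, not an errors-in-
variables fit, and inherits the usual attenuation when RNA RPKM is noisy;
GSEA p-values are permutation-based and bounded below by 1/(n_perm+1).
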