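# Methods

This note documents the models, the numerical choices, and what the test
suite does and does not demonstrate.

## The estimation model

**Data.** For one species: a folded synonymous SFS and a folded
non-synonymous SFS (counts `c_i` at minor-allele count `i = 1..⌊n/2⌋` in a
sample of `n` chromosomes, with mutational-opportunity sizes `L_s`, `L_n`),
plus divergence counts `dN`, `dS` with their own site totals. Counts may be
fractional because spectra are built by hypergeometric projection of each
SNP down to a common sample size (chosen per species to maximize the
retained SNP mass, since coverage is uneven across individuals).

**Sojourn kernel.** A mutation with scaled effect `S = 4 N_e s` (additive,
i.e. heterozygote effect `s`, homozygote `2s`) contributes to frequency
class `j` of an `n`-sample in proportion to
`B(j; n, S) = C(n,j) ∫ H(x;S) x^j (1−x)^{n−j} dx`, with
`H(x;S) = (1 − e^{−S(1−x)}) / (x(1−x)(1 − e^{−S}))`. We evaluate `B`
exactly as `n/(j(n−j)) · (M(j,n,S) − e^S)/(1 − e^S)` with `M` Kummer's
confluent hypergeometric function (and the Kummer transform
`M(j,n,S) e^{−S} = M(n−j,n,−S)` for `S > 0` to avoid overflow). This closed
form is stable over `|S| ≤ 1e5` and is verified in the tests against
adaptive quadrature (with a boundary-layer substitution for strongly
negative `S`, where naive quadrature fails) and against the asymptotic
`B ≈ n/(j(n−j)) · Γ(n)/Γ(n−j) · |S|^{−j}`.

**DFE families.** GammaZero: reflected gamma on `S < 0` (mean, shape).
GammaExpo: adds a proportion `p_pos` of beneficial effects, exponential
with mean `S̄_b`. ScaledBeta: Beta(a,b) mapped onto `S ∈ [−25, 25]`. The
continuous families are discretized for the likelihood on fixed grids —
256 log-spaced nodes over `|S| ∈ [1e−6, 1e5]` for the deleterious part,
128 over `[1e−6, 1e4]` for the exponential tail, 400 linear cells for the
Beta support — with node masses computed as CDF differences, so the node
positions (and hence the cached per-`n` sojourn matrix) never depend on the
parameters. Sub-grid tail mass is folded into the end nodes (the low end is
effectively neutral, the high end effectively invisible).

**Likelihood.** Independent Poisson counts per folded class for both
spectra, sharing a per-site `θ` and per-class nuisance multipliers `r_i`
(`r_1 ≡ 1`). Fractional observations enter as `c log λ − λ`. Given `θ` and
the DFE parameters, the MLE of each free `r_i` is
`(c_i^{syn} + c_i^{non}) / (λ_i^{syn} + λ_i^{non})` in closed form, so the
`r_i` are profiled out exactly and only 3–5 parameters are optimized
numerically (log/logit transforms, L-BFGS-B, 10 seeded multistarts by
default, convergence tolerance 1e−8 on the log-likelihood). AIC counts all
free parameters including `θ` and the profiled `r_i`; no small-sample
correction is applied.

**From DFE to ω_a.** `ω_na` is the integral of the relative fixation rate
`S/(1 − e^{−S})` over the non-adaptive DFE component (`S ≤ 0`); fixations
driven by a fitted weakly-beneficial component are counted as adaptive by
default, with `include_positive=True` switching to the alternative
accounting. This integral is computed to ~1e−8 relative accuracy by
composite Gauss–Legendre panels on a substituted variable with analytic
endpoint heads (the fitting grid is not reused here, so the reported
`ω_na` is free of discretization error). Then `α = 1 − ω_na/ω_obs`,
`ω_a = α ω_obs`; `α` may be negative, and `ω_a + ω_na = ω_obs` holds by
construction for every single-model and Akaike-averaged estimate.

**Group estimators.** ω_a[P]: species spectra are projected to the
minimum shared even `n`, pooled with equal species weights (each species'
spectrum normalized by its total SNP count, summed, rescaled to the summed
total), and the pooled spectrum is fitted against the whole-tree dN/dS.
ω_a[A]: the group dN/dS minus the arithmetic mean of the species `ω_na`.

**Bootstrap.** Replicates resample SNPs — one multinomial draw over the
concatenated syn+nonsyn frequency cells with the grand total fixed, which
preserves the binomial variance of the syn/nonsyn split that drives
`ω_na` — and resample `dN`, `dS` as Poisson. Each replicate reruns the
fit → Akaike-average pipeline warm-started from the point-estimate optimum
(a single start; the point estimate itself uses the full multistart).
Percentile 2.5/97.5 bounds; deterministic given the seed; replicates with
zero resampled `dS` or failed fits are dropped, with a warning above 20%.
A per-spectrum resampling scheme (each total fixed separately) is
available via `resample_scheme="per_spectrum"`; it conditions away the
split variance and measurably undercovers, so it is not the default.

## Site counting and GC-conservative subsets

Each codon position contributes, for each of its three possible changes,
1/3 of a site to the synonymous or non-synonymous total; stop-gaining
changes count toward neither, and codons containing ambiguous bases are
excluded with a warning. Every position has exactly one GC-conservative
change (A↔T or C↔G); it contributes one full GC-conservative site to the
class of that change (or none if stop-gaining). This per-site convention is
one defensible normalization of "GC-conservative sites"; analyses using
the GC-conservative subset are internally consistent as long as SNPs and
site counts use the same convention, which the toolkit enforces by
filtering both through the same classifier.

## Comparative layer

Simple OLS with two-sided t-tests on the slope; traits are log10
transformed, diversity is analyzed both raw and log10. Spearman tests use
tie-corrected ranks with the t approximation, switching to exact
permutation enumeration for n ≤ 9. The ANCOVA fits the additive model
`response ~ covariate + group` and reports the common slope with its
t-test, an F-test of the group factor against the covariate-only model
(distinct intercepts), and an F-test of the interaction term added to the
additive model (slope heterogeneity). The slope meta-analysis computes
per-group OLS slopes (groups with < 3 complete species are flagged and
excluded) and Spearman-correlates them with group mean diversity. Missing
values are dropped listwise per test and no multiple-testing correction is
applied, so p-values are comparable to single-test reporting.

## Wright–Fisher control simulator

Individual-based, diploid, panmictic; genomes are explicit coding
sequences (default 200 genes × 999 bp, random sense codons) so that
synonymous/non-synonymous classification is identical to the SFS toolkit's.
New mutations arise at rate `μ` per bp per generation; synonymous changes
are neutral, stop-gaining changes get `s = −0.9`, and non-synonymous
changes draw from gamma (deleterious) plus, with probability `p_pos`, an
exponential beneficial tail. Fitness is multiplicative with semidominance
(`1 + s` heterozygous, `1 + 2s` homozygous, clipped above −1); selection
coefficients are additive effects so that `S = 4Ns` matches the diffusion
scaling of the estimation model (validated by the neutral `π = 4Nμ` and
strongly-deleterious `dN/dS` checks in the tests). Recombination is
per-bp crossover; crossover gametes are rebuilt by breakpoint parity.
Fixed mutations are written back into the reference (interactions between
simultaneously segregating sites of one codon are classified against the
current reference — a standard approximation at these densities), logged
as substitutions after burn-in (10 × max N generations), and divergence is
measured against the post-burn-in consensus.

A desk-scale caveat worth stating plainly: with a 200-gene genome the
realized coalescent fluctuates strongly between sample times (sd(π_s)/mean
≈ 10%), and deleterious non-synonymous polymorphism — being age-limited —
does not scale up with deep trees the way neutral polymorphism does, so
π_n/π_s anticorrelates with π_s across time points. The fitted DFE then
looks more deleterious exactly when π_s is high, pulling ω̂_a upward with
π̂_s. Pooling many constant-N replicates makes this coupling clearly
detectable even though the mean ω̂_a stays unbiased near zero and most
individual replicates are non-significant at five time points. The
amplitude of both fluctuations shrinks with genome size (600 genes cut
sd(π_s)/mean to ≈ 6.6%, and a 1500-gene genome as in full-scale
experiments fluctuates further still), though the two remain correlated at
any scale. This effect is distinct from the ancient-demography artifact
the control is designed to probe, and it is why conclusions from the
control are drawn per replicate at the chosen scale rather than from
pooled scatter.

The nominal parameterization is `μ = 2.2e−9`, `rec = 1e−7` per bp at a
reference `N = 100 000`, i.e. θ ≈ 9e−4, matching the primate-like DFE
(gamma mean −740, shape 0.14; exponential beneficial mean 1e−4 as a raw
selection coefficient; `p_pos = 0.02` as a realistic beneficial fraction —
the proportion is a free choice, and control runs set it to 0).
`rescale_parameters(cfg, N)` maps this to a desk-scale population holding
`4Nμ`, `4Nrec`, `4Ns` and durations in units of `N` constant; tests run at
`N = 100–200`, where one replicate takes tens of seconds. Sample times are
spaced `2N` generations so that π_s decorrelates between samples; the
ω_a–π_s regression across time points otherwise inherits the
autocorrelation of both series and its test is anti-conservative.

## Synthetic data: what it shows and what it does not

The SFS generator draws class counts Poisson around the model's own
expected spectra (default nuisance distortion: a monotone ramp from 1.0 to
1.2 across frequency classes, exercising the `r_i` correction), and
divergence as Poisson with `dN = L_n d_s (ω_na(model) + ω_a^{true})`,
`d_s = 0.1` synonymous substitutions per site by default (within the
within-group divergence range the estimators are meant for). Recovery and
coverage results on these data validate the inference machinery —
likelihood, optimization, averaging, bootstrap — under a correctly
specified sampling model with free recombination. They do not probe
linkage, selection on synonymous sites, polarization error, or
misspecified DFE shapes beyond the cross-family fits; the forward
simulator restores linkage and finite-population realism at reduced scale,
but desk-scale runs have far fewer SNPs and substitutions than real
species data, so its per-time-point estimates are noisier than published
per-species estimates.

Typical behavior worth knowing: with a weak beneficial tail in the
generating DFE, the Akaike average leans on the more parsimonious
GammaZero fit, which absorbs some beneficial polymorphism into the
deleterious DFE and biases ω̂_a slightly downward (about −0.01 at the
default recovery settings); the median recovery criterion passes with this
bias included, and it is the known cost of model averaging with nested
families.

## Problem sizes in the default test run

Recovery uses 20 datasets (n = 20, L = 1e6); coverage uses 100 datasets at
B = 200 with a GammaZero-only family set (n = 10); the simulation control
uses 10 constant-N replicates at N = 200 with 5 time points each. These
sizes are the package's chosen desk-scale study conditions; the full suite
runs in roughly seven minutes on one CPU.

## Known limitations

- The folded-SFS likelihood cannot separate very weak selection from
  nuisance distortion at small `n`; the (mean, shape) gamma ridge is wide,
  which is why `ω_na` (a functional of the DFE) is reported rather than
  the raw parameters.
- ScaledBeta has no strongly-deleterious mass outside `[−25, 25]`; on data
  with such mass it fits poorly and receives ~zero Akaike weight, which is
  the intended behavior of the average.
- The simulator's infinite-sites collision handling skips re-mutation at
  segregating positions and ignores within-codon epistasis of
  co-segregating variants.
- `F_is` uses the small-sample-corrected expected heterozygosity averaged
  over polymorphic sites; sites monomorphic among called individuals are
  uninformative and skipped.
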