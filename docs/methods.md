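# Methods

## Data model

The unit of input is a study × SNP × population summary record: sample
sizes, risk-allele frequencies (RAFs, fractions in [0, 1] — percentages
are rejected to avoid silent unit bugs), and/or an odds ratio with its 95%
CI. Records must carry either the case *and* control RAF pair or the full
OR + CI triple; anything else cannot yield an effect estimate and is
rejected at parse time with the offending row number. SNPs that are
monomorphic in one population (RAF exactly 0 or 1) are representable and
are excluded from cross-population stages with a logged event rather than
an error.

Risk alleles are harmonized against a per-SNP reference allele before any
cross-population operation. A record reported on the opposite allele is
flipped: OR → 1/OR, CI → (1/hi, 1/lo), every RAF → 1 − RAF, alleles
swapped; flipping twice restores the original. A/T and C/G SNPs that would
need flipping are flagged as strand-ambiguous and never flipped silently,
because a true allele flip cannot be distinguished from a reverse-strand
report.

## Effect estimates

Two routes produce a log-OR with standard error:

* **Counts-derived.** Allele counts are reconstructed as
  round(RAF · 2n), ties to even (published frequencies rarely imply whole
  counts; the tie rule is arbitrary but fixed). The allelic OR is
  (a·d)/(b·c) on the 2×2 table; when any cell is zero the Haldane–Anscombe
  correction adds 0.5 to every cell for the OR and its SE
  √(1/a + 1/b + 1/c + 1/d), so single extreme studies remain poolable.
  Significance is the two-sided Fisher exact probability — the sum of
  hypergeometric outcomes no more probable than the observed table
  (the "minimum-likelihood" convention; the doubling convention exists but
  is not used) — always computed on the raw, uncorrected counts.
* **CI-derived.** SE = [ln(hi) − ln(lo)]/(2z) with z = 1.959964 for 95%
  intervals. The quantile is held at six decimals so CI → (log-OR, SE) → CI
  round-trips are stable to 4 decimal places. This is the only faithful
  route for consortium results published without variances.

Summary RAFs across reports are averages weighted by total sample size.

## Meta-analysis

Fixed-effect weights are 1/SE². Cochran's Q is the weighted sum of squared
deviations from the fixed-effect mean; I² = max{0, (Q − df)/Q};
the DerSimonian–Laird moment estimator
τ̂² = max{0, (Q − df)/(Σw − Σw²/Σw)} uses fixed-effect weights, as is
standard even when the random-effects pool is reported. Random-effects
weights are 1/(SE² + τ̂²). Whenever Q ≤ df the estimator truncates to zero
and the random-effects result equals the fixed-effect result exactly. A
single study passes through unchanged with Q = 0, df = 0 (its Q p-value is
undefined and reported as absent). DerSimonian–Laird is used because it
was the de-facto default random-effects estimator of the source
literature's era; the test suite cross-checks it against an independent
implementation (statsmodels `combine_effects`). I² bands are labelled
negligible / minimal / moderate / high at configurable thresholds
(default 0.25 / 0.50 / 0.75).

Rows sharing an `ld_group` key (SNPs in linkage disequilibrium, r² > 0.8,
measured in independent cohorts) are pooled as a single signal; the
package performs no LD estimation of its own.

## Cross-population comparison

Effects for the same harmonized SNP are contrasted with
z = (θ_a − θ_b)/√(SE_a² + SE_b²), two-sided normal p. No multiple-testing
adjustment is applied by default (a Bonferroni column is available as a
clearly optional extension), matching the nominal two-sided α = 0.05
convention of the summary tables the pipeline reproduces.

**Reporting precision.** The pipeline's comparison stage rounds
multi-study pooled ORs and CIs to a configurable number of decimals
(default 2) and re-derives the SE from the rounded CI before the Z test,
while single-study inputs pass through at their published precision. This
matches how such comparisons are actually made from printed consortium
tables, and it is the convention under which the packaged tables'
heterogeneity p-values reproduce. Setting `comparison_precision: null`
uses full-precision pooled values instead; the two conventions can differ
by a few hundredths in p when an SE is small.

## Genotype (population-burden) score

score = Σ ln(ORᵢ)·RAFᵢ, variance = Σ RAFᵢ²·var[ln(ORᵢ)], over the SNPs
present and polymorphic in both populations. Both populations are weighted
by one population's ORs (default: population B, intended for the larger,
more precisely estimated consortium), so the score difference is by
construction a pure function of RAF differences. Scores are compared with
z = (S_a − S_b)/√(V_a + V_b). Var[ln(OR)] comes from the CI-derived SE of
the weights population. The score treats the weights as known constants;
the variance formula ignores their estimation error in the *other*
population, which is the convention of the published statistic.

## Power and sample size

The disease model is log-additive: Hardy–Weinberg genotype frequencies
f(g) at population RAF p, per-genotype risk r_g = r₀·ORᵍ, with r₀ set so
that Σ f(g)·r_g equals the disease prevalence (default 0.10). The
constraint is linear in r₀, so r₀ is closed-form; the model is infeasible
(and errors) when any implied genotype risk leaves (0, 1). Case genotypes
are distributed ∝ f(g)·r_g and controls ∝ f(g)·(1 − r_g); their allele
frequencies (p_case, p_control) feed the two-sided allelic Wald
approximation

    var(ln ÔR) = [1/(p_c q_c) + 1/(ratio · p₀ q₀)] / (2 n_cases)
    power = Φ(|ln OR|/SE − z_{1−α/2}) + Φ(−|ln OR|/SE − z_{1−α/2})

with defaults α = 0.05 two-sided and a 1:1 control ratio ("case-control
pairs"). Sample sizes invert this expression and are then adjusted by ±1
against the power function itself to the minimal integer meeting the
target (default 0.80).

**Nominal versus realized allelic OR.** Under this model the
case-vs-control allelic odds ratio slightly exceeds the nominal per-allele
OR whenever prevalence is non-negligible, because controls are depleted of
risk alleles (e.g. nominal 1.20 → realized ≈ 1.23 at prevalence 0.10,
RAF 0.30). `power()` follows the published-table convention and uses the
nominal ln OR as the noncentrality — the choice that reproduces standard
power tables — while `wald_power()` computes the exact
normal-approximation power at given sampling frequencies (defaulting to
the realized allelic effect, `implied_allelic_log_or`), which is the
quantity Monte-Carlo rejection rates converge to. Simulation-based
checks therefore target the realized allelic scale; between-study
variances stated on the nominal log-OR scale map onto it with the delta
method (slope ≈ 1.12 at the parameters above).

## Synthetic data

Each simulated study draws its own log OR from Normal(ln OR, τ²), converts
it to expected case/control allele frequencies through the disease model
above, and samples allele counts binomially over 2n chromosomes — matching
the allelic granularity of the analysis (no genotype-level multinomial, no
LD structure, no covariates). The seed is mandatory and the generator has
no global state: identical configs give identical tables. What passing
tests on these data show: the estimation chain (count reconstruction →
allelic OR → pooling → comparison) is unbiased for the generating truth
and has correct type-I error under binomial sampling. What they cannot
show: robustness to genotyping error, covariate confounding, selection or
publication bias in real summary data.

Default validation conditions: recovery runs use 8 studies of 2,000 cases
(1:1 controls) at OR 1.2, τ² = 0.01, RAF 0.30, prevalence 0.10 — sizes
typical of the mid-size cohort literature the package addresses and small
enough that the full suite runs in well under a minute of simulation; the
RAF and prevalence were fixed once at these field-typical values.
τ̂² recovery is assessed as a mean over 500 replicates within 30% of the
(delta-method-mapped) truth: DerSimonian–Laird is noisy and
truncation-biased at k = 8, so per-replicate agreement is not expected.

## Numerical choices

* Normal quantiles rounded to six decimals (1.959964 at 97.5%).
* Fractional allele counts: nearest integer, ties to even.
* τ̂² and I² truncated at zero; p-values capped at 1.
* Pooling is permutation-invariant and deterministic; pipeline outputs are
  byte-reproducible for a fixed config (floats written at %.6g).
* Degenerate inputs raise typed errors: empty 2×2 rows/columns,
  zero-width CIs, empty estimate lists, infeasible prevalence/OR
  combinations, OR = 1 sample-size requests.

## Known limitations

* The published pooled CIs of two packaged signals (HNF4A rs4812829 and
  VPS26A rs1802295) are not reproducible from their printed per-study rows
  by either fixed-effect or DerSimonian–Laird pooling; the pipeline
  reports its own pooled values for them, and their cross-population
  p-values consequently differ from the source table's.
* ORs are unadjusted allelic ORs; covariate-adjusted comparisons are out
  of scope.
* Power is the Wald approximation, not an exact or likelihood-ratio
  computation; published sample-size tables built with other engines agree
  with it to within a few percent but not exactly.
* Fisher p-values use scipy's exact two-sided routine; for margins in the
  tens of thousands this is exact but slow — disable with
  `allelic_or(..., fisher=False)` in simulation loops.
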