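# Methods

This note records the statistical procedures implemented in `pvsignal`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices a maintainer would otherwise have to reverse-engineer.

## Report store and deduplication

FAERS-style quarterly extracts arrive as five `$`-delimited ASCII tables
(DEMO, DRUG, REAC, THER, OUTC) joined on PRIMARYID. Spontaneous reporting
produces multiple versions of the same case, so the store keeps, per CASEID,
the version with the most recent FDA_DT, breaking ties by the largest
PRIMARYID — numerically when all competing ids are all-digit strings,
lexicographically otherwise (real FAERS ids are numeric; synthetic fixtures
need not be). The operation is idempotent and its output is sorted by
CASEID, so reruns are byte-stable.

Dates are parsed from `YYYYMMDD` with partial forms (`YYYYMM`, `YYYY`)
retained at year resolution for annual tallies but treated as missing
wherever day arithmetic is needed. Drug names are case-folded with
whitespace collapsed; no synonym expansion is attempted — query lists are
configuration. One dialect extension: REAC accepts an optional third column
`event_dt` carrying the event date, which the time-to-onset stage needs
(production FAERS keeps EVENT_DT in DEMO; this dialect's DEMO is fixed, and
REAC is the least invasive carrier since the event date belongs to the
reaction).

Outcome codes are tabulated once per report by the most severe code present,
in the order DE > LT > HO > DS > CA > OT, with no codes mapping to
"Unknown". CA sits between DS and OT so congenital anomalies — an important
medical event — are not folded into "Other". Age units (years, months,
weeks, days, decades) and weights in pounds are converted on ingest;
unparseable values leave the field missing and increment a warning counter
rather than dropping the row.

## Disproportionality analysis

The analysis unit is the (report, term) pair: a report with k distinct PTs
contributes k pairs and duplicate PTs within one report count once. This
keeps N constant across terms at a fixed level, and makes a SOC-level table
exactly the sum of its member-PT tables. The comparator for a drug is every
other report in the deduplicated store.

The four algorithms follow the standard closed forms (see README for the
formulas). Numerical conventions:

- **Zero cells.** No Haldane-style continuity correction is applied. Any
  quantity needing the log or reciprocal of an empty cell is marked NaN and
  its flag fails; the a ≥ 3 thresholds exclude such pairs from signals
  anyway.
- **BCPNN.** The information component uses the closed-form Bayesian
  approximation with hyper-priors α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1:
  E(IC) = log₂[(a+1)(N+2)²/((N+γ)(a+b+1)(a+c+1))] with
  γ = (N+2)²/((a+b+1)(a+c+1)), and the variance sum over the three
  shrunken margins; IC025 = E(IC) − 2√V(IC). This is the formulation in
  routine pharmacovigilance use; it satisfies IC → 0 under exact
  independence as N grows, which the tests check at N = 10⁶.
- **MGPS.** EBGM is the shrunken relative reporting ratio aN/((a+c)(a+b)),
  and EBGM05 a normal-approximation lower bound
  exp(ln EBGM − 1.64·√(1/a+1/b+1/c+1/d)) — *not* the full gamma-Poisson
  mixture posterior. Output tables carry a metadata note to that effect.
- χ² is Pearson's without continuity correction, matching the PRR
  threshold convention (χ² ≥ 4).

Signals require all four flags simultaneously (logical AND). No
multiple-testing correction is applied anywhere in the screening or the
gender contrasts: the concordance rule is the specificity control, and the
outputs are hypothesis-generating. Gender contrasts are oriented
female-vs-male (ROR > 1 = female-prone) and use the same uncorrected χ²;
a missing gender margin yields an undefined-marked row, never an exception.

## Time to onset

TTO = (event date − therapy start date) + 1 day, so same-day onset is
representable as 1; only day-resolution dates on both sides qualify, and
event-before-start rows are excluded and counted. Quartiles use linear
interpolation between order statistics (numpy's default, type 7).

The two-parameter Weibull is fitted by maximum likelihood on the continuous
density, treating integer days as continuous. The MLE is seeded by
`scipy.stats.weibull_min.fit(floc=0)` and polished with Nelder-Mead on
(log α, log β); 95% CIs are Wald intervals on the log-parameter scale from
the observed information (central-difference Hessian, step 10⁻⁵),
back-transformed. Fits require n ≥ 10 and a non-degenerate sample. Failure
classification is a pure function of the shape CI: early iff the upper
bound < 1, wear-out iff the lower bound > 1, random otherwise.

**Known limitation — day-level rounding.** Because files carry dates, onset
times are integers, and for shape < 1 the mass below one day is snapped to
1. The continuous-likelihood shape MLE is then biased upward by roughly
5–10% in the α ≈ 0.6–0.8, scale ≈ 30–70 regime, and the nominal CI
under-covers the continuous-law shape. The fitter's coverage guarantees
(≥ 90% across seeded replicates) therefore hold for continuous samples of
the onset law; on day-rounded data the *classification* (early failure) is
robust — the bias never pushes a clearly sub-exponential shape across 1 —
and both facts are asserted in the test suite. No right-censoring is
modelled: reports without an event never enter the sample.

## IME logistic models

IME = outcomes ∩ {DE, LT, HO, DS, CA} ≠ ∅, a monotone function of the code
set. Five focal variables are modelled: gender (male vs female reference),
age and weight continuous, and their bands (<18 / 18–64 / >64 years;
<80 / 80–100 / >100 kg, reference the lowest band). Univariate models fit
each focal variable alone; multivariate models adjust the focal variable for
the other two entered as continuous covariates (banded focal variables are
likewise adjusted for the other two continuous terms plus gender). Fits are
maximum-likelihood logistic (statsmodels Newton), complete-case per model,
with Wald CIs and p-values. A contrast is reported NA when the optimizer
fails, any |coefficient| exceeds 15 on the logit scale, the Wald SE exceeds
100 (collinearity or quasi-separation), or a covariate class has zero
variance — mirroring how sparse strata surface in practice. No Firth
correction, interactions, or model selection.

## Drug-target MR

Instrument selection: SNPs within ±500 kb of the gene body, F = (β/se)² ≥ 10,
then greedy clumping ordered by ascending p-value (SNP id as deterministic
tie-break) keeping a variant iff r² < 0.001 with every already-kept variant
within 500 kb. The distance window is honored literally: correlated variants
farther than 500 kb apart are both kept. Every selection decision is logged
in a per-SNP provenance trail. Harmonization joins on SNP id, drops
palindromic (A/T, G/C) variants unconditionally — no allele-frequency
rescue — negates the outcome beta when alleles are swapped, reconciles
strand flips by complementing, and drops irreconcilable allele sets with
counts. An empty join and an everything-dropped outcome raise distinct
errors.

Estimators, on Wald ratios r_j = β_Y,j/β_X,j with first-order
se_j = se_Y,j/|β_X,j| (second-order terms need a cross-covariance two-sample
data lack):

- **IVW**: 1/se_Y²-weighted regression through the origin; multiplicative
  overdispersion scale max(1, √(Q/(k−1))); normal inference.
- **MR-Egger**: weighted regression with intercept, residual scale floored
  at 1, t-inference on k−2 df for both slope and intercept.
- **Weighted median**: 50% point of the weight-ordered ratios with linear
  interpolation between bracketing order statistics; weights (β_X/se_Y)².
- **Simple/weighted mode**: argmax of a Gaussian-kernel density over the
  ratios, bandwidth h = s·(4/(3k))^{1/5} with s the normal-scaled MAD;
  identical ratios (h = 0) return the common value.

Bootstrap standard errors (median and modes) use a seeded parametric
bootstrap of 1000 draws perturbing both betas by their SEs. Minimum
instrument counts: IVW 1 (degenerating to the Wald ratio), the rest 3.
An exposure beta within 10⁻¹² of zero is an error, not a huge ratio.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the suite assumes. FAERS side: 50,000 reports; four
planted drugs at 8% market share each, one planted PT per drug with a
reporting-odds multiplier of 10 (each report draws a single PT from a
background multinomial whose odds for planted pairs are multiplied, making
the target ROR equal the multiplier exactly in expectation); remaining share
split over 20 background drugs; per-drug Weibull onset laws in the
early-failure regime (shapes 0.56–0.76, scales 28–70 days, mirroring
reported onset profiles for these agents); IME outcomes from a logistic law
on gender/age/weight (default male log-odds ln 1.5, age 0.01/year) applied
to *true* covariate values before missingness is masked at random, so
complete-case fits remain consistent; duplicate case versions at a
configurable rate (default 0.10) with strictly ordered receipt dates and the
*larger* PRIMARYID on the stale version, so deduplication must decide by
date; a truth ledger records every planted quantity — survivor ids, drug,
PT, IME label, onset days (continuous and rounded), year — sufficient to
recompute any downstream result without re-reading the files.

GWAS side: latent instrument effects γ_j ~ N(0, 0.1²) with optional
block-correlation via a Gaussian copula (r = √r²); observed exposure betas
add N(0, se_X²) noise; outcome betas are true_beta·γ_j + pleiotropy_j +
N(0, se_Y²) — built from the *latent* effect, not the noisy observed beta,
so the ledger's truth is exact; configurable palindromic fraction and
outcome-side allele swaps/strand flips exercise harmonization; the r²
matrix is emitted with SNP labels. Defaults (50 SNPs, true β 0.25,
se_X 0.01, se_Y 0.05) give IVW power ≈ 3 SEs from zero — a deliberately
honest, not overwhelming, regime.

What the generator does **not** emulate: multi-reaction reports (one PT per
report, so pair counting equals report counting in generated data — the
multi-PT counting rule is covered by constructed unit fixtures), realistic
MedDRA breadth (30 PTs, 9 SOCs), indication channeling, reporting-rate
drift, genotype-level LD, or population stratification. Passing tests
therefore demonstrate algorithmic correctness under known structure, not
robustness to every bias of real spontaneous-report data.

## Reference demographic counts

`pvsignal.reference` carries the published deduplicated report tallies for
the four HDACi (N = 1360 / 1065 / 225 / 1234) as a fixed fixture.
`reports_from_counts` expands them into synthetic reports whose per-category
marginals match the counts exactly; only the per-section percentages are
meaningful on the expanded store (categories are assigned independently, so
joint distributions and means are not).

## Problem sizes and determinism

The test suite and acceptance script use the sizes the methods are specified
at: the 50,000-report store for signal concordance, 20,000 reports for the
IME odds-ratio recovery, 150 seeded Weibull replicates of n = 500, a 50-SNP
instrument set, and an exhaustive sweep of all 2×2 tables with cells ≤ 6
against an independently coded formula oracle at 10⁻¹². Every stochastic
stage takes an explicit seed; pipelines, generators and CSV writers are
byte-deterministic given (config, seed).
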