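# Methods

This note documents the statistical models behind `repbayes`, the numerical
schemes used to compute them, the defaults and why they were chosen, and
what the tests do and do not establish.

## Summary-statistic likelihoods

All t-test machinery works from the sufficient triple (t, ν, N_eff):

* one-sample design: ν = n₁ − 1, N_eff = n₁;
* two-sample design: ν = n₁ + n₂ − 2, N_eff = n₁n₂/(n₁ + n₂).

Under the usual normal model with standardized effect size δ and the
noninformative nuisance prior p(μ, σ) ∝ σ⁻², the observed t-statistic is
noncentral-t distributed with ν degrees of freedom and noncentrality
δ√N_eff, and it carries all the information the raw data hold about δ.
Working on summaries is therefore not an approximation for these designs;
it is the exact reduction.  Raw-data ingestion, Welch/unequal-variance
designs and paired designs beyond their one-sample reduction are
deliberately out of scope.

The noncentral-t log-density (`repbayes.noncentral_t_logpdf`) evaluates
through scipy where scipy is finite and falls back to a peak-centred
Gauss–Hermite quadrature of the defining normal/scaled-chi mixture where
scipy underflows or overflows (extreme noncentralities, very large ν).  The
log-integrand is concave in the mixing variable with a closed-form peak, so
the 100-node rule is accurate to ~1e−10 and finite for all finite inputs
(exercised up to |ncp| = 50 and ν ≈ 10⁴ in the tests).

## Default Bayes factors for t-tests

H0 fixes δ = 0.  H1 assigns δ a zero-centred Cauchy prior with width r,
default r = 2^−1/2 ≈ 0.707 (the modern "user prior" default; r = 1 is
Jeffreys's historical wide prior).  BF10 is computed by adaptive quadrature
(scipy `quad`, relative tolerance 1e−10 per segment) of the likelihood
times the prior over δ, on segments split at 0 and at the likelihood centre
± 8 standard errors so the integrator cannot miss a sharp likelihood peak;
the same pass yields the posterior mass on δ > 0.  The width r = 0 is the
degenerate point-null limit and returns BF = 1 exactly, bypassing
quadrature.

One-sided (folded) Bayes factors use the mass-ratio identity

    BF+0 = BF10 · P(δ > 0 | data, H1) / P(δ > 0 | H1),

with prior sign probability ½ under any zero-centred prior.  This is
algebraically identical to integrating a truncated, renormalized prior but
cheaper and better conditioned.  It enforces BF+0 + BF−0 = 2·BF10 to
rounding error, which the test suite checks across randomized inputs.

The independent cross-check in the tests integrates over the
inverse-gamma mixture representation instead (δ | g ~ N(0, g r²),
g ~ InvGamma(½, ½)), for which the marginal of t given g is closed-form;
that route never evaluates a noncentral-t density, and agrees with the
implementation to ~1e−13 relative.

## Effect-size posteriors

`delta_posterior` evaluates likelihood × prior on a grid of 4001 equally
spaced points spanning the posterior mode ± 6 posterior standard deviations
(mode and curvature from a numerical pilot), normalizes by the trapezoid
rule, and reads the median and the central (equal-tail) interval off the
interpolated CDF — which also serves as the tie-break for the median.
One-sided priors truncate and renormalize the grid to the requested sign.
Draws, when needed, come from inverse-CDF sampling on the grid.

`rho2_from_delta` maps δ draws to the proportion of variance explained.
For two-sample designs ρ² = p₁p₂δ²/(1 + p₁p₂δ²) with group proportions
p₁, p₂.  The package defines the one-sample analogue as δ²/(1 + δ²) and
flags it in the summary metadata (`convention: one_sample_analogue`),
since no printed convention exists for that case.

Correlations use the exact (Fisher) sampling density of the observed
Pearson r given ρ and n, evaluated via its hypergeometric form with
argument (1 + ρr)/2, which stays inside the unit interval and is stable to
n in the thousands (validated against simulation and by normalization in
the tests).  The prior is a stretched beta on (−1, 1) with width κ;
κ = 1 — the default — is uniform.  BF10 integrates this likelihood against
the prior by adaptive quadrature; the test suite cross-checks it through
the Savage–Dickey density ratio at ρ = 0.

Cramér's φ² for an R×C table uses a symmetric Dirichlet(α) prior, default
α = 1, over the flattened cell probabilities of a joint multinomial —
posterior Dirichlet(counts + α) — and summarizes φ² over 50 000 seeded
draws.  Monte Carlo is used because φ² of a Dirichlet vector has no
convenient closed form.  The sampling scheme (joint multinomial rather
than Poisson or row-multinomial) is a fixed design choice, so numerical
agreement with analyses that used other schemes is not claimed.
Contingency-table *Bayes factors* are out of scope throughout.

## Prior-width robustness curves

`robustness_curve` evaluates the chosen Bayes factor on a grid of widths.
The likelihood is tabulated once on a fine δ grid and reused for every
width, making a 200-point curve cost about as much as two single Bayes
factors.  Widths narrower than the grid can resolve (r < 20 grid steps)
fall back to the adaptive-quadrature path, and r = 0 returns exactly 1, so
the curve is accurate from the point-null limit up.

## Hierarchical random-effects meta-analysis

The model for S t-test studies:

    t_s | δ_s  ~ noncentral-t(ν_s, δ_s √N_eff,s)
    δ_s | θ, τ ~ Normal(θ, τ²)
    θ          ~ Cauchy(0, ½)
    τ          ~ half-Cauchy(0, ½)            [default]
                 or p(τ) ∝ τ⁻² on [10⁻³, 10]  [`as_printed`]

The τ⁻² prior is offered because it matches the published specification of
this analysis, but it is not normalizable at 0; truncated to [10⁻³, 10] it
places ~88% of its mass below τ = 0.01 and visibly distorts weak-data
posteriors, so the half-Cauchy is the default.  Both choices are recorded
in the fit's diagnostics metadata.

### Sampling by composition, not MCMC

The joint posterior factorizes:

    p(θ, τ, δ | data) = p(θ, τ | data) · ∏_s p(δ_s | θ, τ, t_s).

`fit_meta` exploits this directly:

1. each study's log-likelihood in δ is tabulated on a 4001-point grid
   spanning its centre ± 12 standard errors (and at least [−8, 8]);
2. δ_s is marginalized by convolving the tabulated likelihood with the
   Normal(0, τ²) kernel (FFT convolution; a locally-flat shortcut for τ
   below the grid step; dense evaluation when the kernel is wider than the
   tabulated support), giving log p(θ, log τ | data) on a grid that is
   adaptively refined twice around the posterior mass, ending at 241 × 121
   points;
3. (θ, τ) pairs are drawn i.i.d. from that grid (multinomial over cells,
   uniform within-cell jitter);
4. each δ_s is drawn from its one-dimensional conditional
   lik_s(δ)·N(δ; θ, τ²), tabulated per draw on 49 nodes across the
   precision-weighted product of likelihood and kernel and sampled by
   inverse CDF.

An earlier development version used an ensemble MCMC sampler on the
non-centred parametrization; it passed R-hat gates while still producing a
τ² marginal biased upward by a factor ~2 against exact quadrature, because
all chains shared the same slow mixing in τ.  The composition sampler has
no such failure mode: draws are independent by construction, and the grid
marginalization agrees with direct adaptive quadrature to ~1e−9.  It is
also bit-reproducible given (seed, chains, draws), and study-order
invariant — per-study likelihood planes are sorted before summation and
each study's conditional stream is keyed by its id, so permuting the
studies permutes the per-study draws and leaves the θ/τ² draws
bit-identical.

Convergence diagnostics (split-R-hat ≤ 1.01, ESS ≥ 400 across independent
seeded chains) are still computed and gated, because the interface promises
them; with i.i.d. draws they are trivially satisfied and serve as a sanity
check on the stream handling.  `HierarchicalConfig.warmup` is accepted for
interface compatibility and unused.

`shrinkage_table` pairs each study's hierarchical summary with its
individual (single-study) posterior and reports the shrinkage fraction
1 − |hier − θ̂| / |indiv − θ̂| (θ̂ the posterior median of θ; defined as 0
when the individual median already sits on θ̂).

## Synthetic data

`simulate_studies` draws, per study: a true effect δ_s ~ Normal(θ, τ²), a
design (two-sample with probability `design_mix`, default 0.8 — most
replication t-tests compare independent groups), group sizes uniform on
`n_range` (default 20–120), and an observed t from the noncentral-t
sampling distribution.  Defaults (38 studies, θ = 0.05, τ = 0.14, i.e.
τ² ≈ 0.02) mirror the setting the package targets: a corpus of modestly
powered social-psychology replications with a near-zero group mean and
small heterogeneity.  Hidden truths are returned in a separate table (and
written to a separate file by the CLI) so a pipeline cannot consume them by
accident.  `fixture_special_issue_like` is a deterministic 38-study set
whose first entry is the worked-example anchor (t = 4.178, n₁ = 18,
n₂ = 69).

What the generator emulates: the exact generative structure the hierarchy
assumes, so parameter-recovery and calibration tests are well-posed.  What
it does not emulate: duplicate studies from the same experiment (the real
corpus has a few; the model ignores the dependence, as the published
analysis did), publication or selection effects, non-normal raw data,
unequal variances, and correlation/contingency designs (the hierarchy is
restricted to t-tests).  Passing recovery tests therefore show the
machinery is correct and calibrated under its own assumptions — not that
those assumptions hold for any particular real corpus.

## Evidence categories and the pipeline

Bayes factors are binned into the Jeffreys bands with fixed symmetric
boundaries {1, 3, 10, 30, 100} (1–3 anecdotal, 3–10 moderate, 10–30
strong, 30–100 very strong, >100 extreme; reciprocals for H0).  Boundary
values fall to the weaker band (BF = 3 is still anecdotal); BF = 1 is
exact indifference.

The batch pipeline analyses each CSV row by its test type, recodes signs so
the predicted direction is positive (the forest-plot convention), and
reports per-row: the one-sided Bayes factor in the predicted direction
(t-tests and correlations; contingency rows carry φ² only), the directed
effect-size posterior, the ρ²-scale posterior, and three flags — "CI
excludes zero in the predicted direction" (ci_low > 0 after recoding) and
"ρ² interval reaches 0.05 / 0.10" (ci_high above the threshold, the two
variance-explained benchmarks the report tallies).  Row failures are
isolated: a malformed study lands in the `error` column and is excluded
from tallies, which are re-verified against the row indicators after every
run.  Reports embed a metadata block (seed, priors, package version) and
are byte-identical for identical inputs and seed.  No multiple-testing
adjustment is applied: per-study intervals and Bayes factors are reported
raw, as is conventional for this kind of overview.

## Numerical choices and problem sizes

* Quadrature tolerances: 1e−10 relative per segment for adaptive
  integrals; posterior grids 4001 points (δ), 8001 points (ρ); robustness
  curves reuse a 16001-point likelihood table.
* Monte-Carlo sizes: 50 000 draws for φ², 100 000 for ρ² transforms,
  4 chains × 10 000 draws for the hierarchical fit (5 000 per chain in the
  replicated recovery study).
* The parameter-recovery study runs 20 replicates of 38 studies; interval
  calibration under the null uses 800 simulated studies; credible-interval
  calibration draws true effects from the analysis prior (truncated to
  |δ| ≤ 3 to stay in the noncentrality range the kernel guarantees), where
  95% coverage is exact by construction.
* Degenerate inputs: width r = 0 short-circuits to BF = 1; empty draw
  sets, nonpositive ν, |r_obs| ≥ 1, all-zero tables and sub-minimal study
  sets raise `ValueError` with the offending field named.

## Known limitations

* Multi-factor ANOVA Bayes factors, semi-partial effect sizes, ordered
  ("r/0") hypotheses, Gunel–Dickey contingency Bayes factors, informed
  (non-zero-centred) priors and replication-specific Bayes factors are not
  implemented.
* The φ² posterior depends on the Dirichlet scheme and concentration;
  other software's choices will differ numerically.
* The hierarchical model treats studies as exchangeable; duplicates from a
  single experiment violate that mildly.
* The correlation prior width κ and the τ prior are configurable precisely
  because the published sources do not pin them down; results for
  weakly-informative data are sensitive to these choices, and the fit
  metadata records what was used.
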