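# Methods

This note documents the models and procedures implemented in `eq5dsim`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Health states and value sets

An EQ-5D health state is a 5-tuple of response levels on mobility (MO),
self-care (SC), usual activities (UA), pain/discomfort (PD) and
anxiety/depression (AD) — 3 levels per dimension for the 3L instrument (243
states) or 5 for the 5L (3125 states). State strings use the fixed dimension
order MO SC UA PD AD; no alternative orders are accepted.

A value set (tariff) is data, not code. Every tariff is a list of additive
terms over four indicator families:

| indicator | fires as | expresses |
|---|---|---|
| `level_dummy(dim, level)` | 0/1 | per-level main-effect decrements |
| `any_level_ge(k)` | 0/1 | any-dysfunction constants and N3-style terms |
| `count_levels_ge(k, offset)` | max(0, count−offset) | count-based interactions |
| `square_of_count(k, offset)` | the square of the above | curvature of count models |

Utility is `full_health_value − Σ coef·indicator(state)`. This covers the
structural forms of the Dutch (constant + N3), US (count-interaction) and
Japanese (constant + main effects) models without per-country code.
Utilities are floats compared at 1e-9; coefficients round-trip through the
YAML files as their printed decimal strings. A tariff validates on load:
full health must score exactly `full_health_value`, every enumerable state
must fall inside the declared range, and duplicate or out-of-version terms
are schema errors.

**The shipped NL/US/JP tables are synthetic reconstructions.** Their
structure follows the published models and the six widely-cited anchor
decrements are exact (3L MO3: NL 0.161, US 0.490, JP 0.418; 5L AD5: NL
0.421, US 0.340, JP 0.197), but the remaining coefficients are plausible
inventions — each file's `notes` field says so. "Decrement" here means the
main-effect coefficient for a response level, not the total utility drop
from full health (which can include constants and N3 terms).

## Crosswalks

A crosswalk model carries five row-stochastic matrices
P_d(target level | source level) and computes, under cross-dimension
independence,

    E[u(q)] = Σ_t Π_d P_d(t_d | q_d) · u_target(t).

The joint source×target mapping is the Kronecker product of the five
matrices (3125×243 at most), and expected utilities are a single
matrix-vector product against the target tariff's utility table; brute
force over all target states is the test oracle. Because the output is a
convex combination of target utilities it is automatically bounded by the
target tariff's range.

Published crosswalks are distributed as full state-to-index tables, and it
is not knowable from the outside whether those tables are an independence
product or a joint mapping. The model therefore also accepts a
`state,country,utility` lookup covering every source state; when a lookup
covers the target country it takes precedence over the matrices, and
`consistency_check` reports per-state differences between the two routes.
The shipped matrices are synthetic stand-ins with the qualitative shape of
the published crosswalks (deterministic endpoints, adjacent-level mass) so
the suite runs with no downloads.

## Synthetic trial generator

The generator defines the study conditions; its defaults are not tuning
knobs.

**Baseline profiles.** Response levels are drawn independently per
dimension from per-arm probability vectors. The builtin
condition × severity recipes are deterministic: each condition has
per-dimension salience weights (depression loads anxiety/depression, low
back pain loads pain/discomfort and mobility, osteoarthritis mobility and
pain, cancer usual activities and pain), severity sets an overall
dysfunction location (mild 0.22, moderate 0.45, severe 0.70 on a 0–1
scale), and the level distribution is a binomial discretisation with
success probability `clip(location·(0.35 + 0.65·weight), 0.02, 0.95)`.
Both arms share the same baseline table — no treatment effect at baseline,
which is why only 12 condition × severity populations exist for baseline
comparisons. These recipes are *synthetic*: the empirical response
probabilities that motivated the design came from eight trial datasets that
are not redistributable, so passing tests demonstrate correctness of the
machinery under a realistic structure, not agreement with any empirical
population.

**Follow-up and effect sizes.** Follow-up levels are drawn per dimension
from a transition matrix row indexed by the baseline level. The control
kernel is stay-biased, `weight exp(−2·|to − from|)` renormalised, identical
across dimensions. The intervention arm applies exponential tilting toward
improvement: the probability of moving from level s to t is reweighted by
`exp(shift · max(0, s − t))` and renormalised, so shift = 0 is the identity
and larger shifts monotonically favour larger improvements. The shift is
found by bisection so that Cohen's d of follow-up utilities between arms —
computed *exactly* by enumerating the product-form follow-up state
distribution, pooled-SD convention, scored under the Dutch tariff of the
generated version — hits the band midpoint (small 0.2, medium 0.6, large
0.9) within ±0.05. Exact enumeration replaces Monte-Carlo evaluation
because it makes the calibration deterministic and noise-free; any monotone
reweighting reaching the band would be admissible, and this one is simple
and testable (a two-level system has a closed-form d against which the
bisection is checked). If the requested band is unreachable (the tilt
saturates), a calibration error reports the achievable maximum. The choice
of a single global shift across dimensions (rather than per-dimension
tweaks) is one admissible reading of "tweaking transition probabilities";
it keeps the effect one-dimensional and the calibration well-posed.

**Covariates.** Ages are uniform integers on [25, 75]; male indicators are
Bernoulli(0.19). Neither enters the default analysis; they are carried as
realistic trial furniture and for optional covariate adjustment.

**Costs.** Follow-up costs are gamma with dispersion ν (Var = ν·μ², default
ν = 1 so SD = mean): control mean €2000, intervention mean €2250 — a true
difference of €250 chosen to be statistically non-significant at n = 150
per arm (the 95% CI covers it ~95% of the time). A literal variance of one
squared currency unit would be a degenerate spike, so ν is the natural
reading of "variance 1" in the mean-dispersion convention. Dependence with
QALYs comes from a Gaussian copula: QALYs are converted to normal scores
*within arm* (so no part of the treatment effect leaks into the cost
margin and the arm cost means stay unbiased), the latent correlation ρ is
solved from `target = ρ · load_cost · load_qaly` where the gamma loading is
computed by Gauss–Hermite quadrature and the QALY loading from its
empirical normal scores, and costs are the gamma inverse-CDF of the latent
normal's CDF. This hits the *Pearson* correlation target (−0.10 by
default) while preserving the gamma marginals exactly.

**Seeding.** All randomness flows from one master seed through named
substreams (`baseline`, `followup`, `covariates`, `costs`, `bootstrap`),
keyed additionally by condition, severity and — only where the effect
enters — the effect-size band. Hence the three bands of a population share
bit-identical baselines and covariates, and changing the bootstrap size
cannot perturb the simulated data.

## Cost–utility analysis

QALYs use the area-under-the-curve (trapezoid) rule over the two
measurement points with a default horizon of one year:
`QALY = horizon·(u0 + u1)/2`. The horizon is configurable; no discounting
is applied at a one-year horizon.

Incremental costs and QALYs come from a two-equation SUR system estimated
by one-step feasible GLS: OLS per equation, residual covariance with
divisor n, then GLS on the stacked system. By default the cost equation is
intercept + treatment and the QALY equation intercept + treatment +
baseline utility (standard practice for baseline-imbalanced utilities);
both are configurable. With identical regressors the FGLS estimator
reduces algebraically to OLS, which the tests exploit as an oracle.

Uncertainty: subjects are resampled with replacement within arm
(preserving n per arm), the SUR refitted per replicate (B = 2000 by
default), and BCa intervals computed with the bias constant
z0 = Φ⁻¹(#{θ* < θ̂}/B) (clipped to (0, 1) open interval for degenerate
fractions) and jackknife acceleration a = Σ(θ̄−θᵢ)³ / 6[Σ(θ̄−θᵢ)²]^{3/2}.
Replicate quantiles use linear interpolation. A constant replicate
distribution collapses to a point interval with a warning, as does B < 100.
Both model-based (normal-theory SUR) and BCa intervals are reported,
labelled, since either convention is defensible for the incremental
estimates; ICER uncertainty is always bootstrap-based (BCa over replicate
ratios, undefined replicates dropped).

The ICER is ΔC/ΔE with an explicit undefined flag when |ΔE| < 1e-6
(undefined is a value, not an exception). CE-plane quadrants put ties on
the positive side (ΔC ≥ 0 is North, ΔE ≥ 0 is East). The CEAC is
pCE(λ) = fraction of replicates with λ·ΔE − ΔC strictly positive, at
λ ∈ {0; 20,000; 30,000; 50,000} per QALY by default, and the decision rule
is inclusive: cost-effective when pCE(λ) ≥ 0.80.

## Method comparison

For each country, the 3L value set is compared against the 3L→5L crosswalk
and the 5L value set against the 5L→3L crosswalk — both methods score the
same source-version states, so comparisons are paired at subject level.
Baseline utilities are compared on pooled arms (12 populations per country
per pairing); QALYs per scenario (36); and full CUAs per scenario with the
differences in incremental QALYs, ICERs, pCE at each λ and decisions. All
differences are value set minus crosswalk. Paired t tests are descriptive
(no multiplicity correction); the clinical-relevance threshold is an MCID
of 0.074 utility points, inclusive. The bootstrap substream is keyed by
scenario, country and pairing — not by method — so the two methods of a
pair are evaluated on identical resamples; a crosswalk rigged to reproduce
the value set therefore yields exactly zero differences everywhere, which
the test suite asserts as a null-method property. Distribution summaries
use 24-bin histograms and a Gaussian KDE with the Silverman
normal-reference bandwidth on a fixed 512-point grid, so they are
deterministic.

## Problem sizes

Defaults follow the study design: n = 150 per arm, B = 2000, 36 scenarios,
3 countries, 2 pairings. The test suite and the acceptance script exercise
the same code paths at reduced sizes chosen for quick iteration — 500
trials for CI coverage, n = 100,000 for the large-sample frequency,
correlation and marginal checks, B = 100–200 for factorial smoke runs —
with all seeds fixed.

## Known limitations

- Cross-dimension independence at baseline, in transitions and in the
  crosswalk product form; real EQ-5D data show dimension correlations.
  Published lookup tables can restore exact crosswalk behaviour as data.
- Two measurement points and a single follow-up cost; no missing data
  (complete-case by construction), no discounting, no copula/regression
  mapping models, no EQ-VAS.
- The shipped tariffs, crosswalk matrices and condition recipes are
  synthetic; conclusions about any specific country's value set require
  loading the actual published tables.
- The effect-size tilt acts on the whole profile through a single shift;
  condition-specific response shapes enter only through the baseline
  probabilities.
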