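# Methods

## The task and its design

The intervene-or-watch task presents a third party, endowed with `x3 = 50`
tokens, with the outcome of a dictator game: a transgressor kept `x1` of
100 tokens and left `x2 = 100 − x1` to a victim. The third party may accept
a costly intervention offer — pay `cost` tokens so that the transgressor
loses `ratio × cost` tokens (punishment scenario) or the victim gains
`ratio × cost` tokens (helping scenario) — or keep the endowment.

Four variables are crossed factorially: scenario (2), nominal
transgressor share (50, 60, 70, 80, 90), cost (10–50 in steps of 10) and
impact ratio (1.5, 3.0), giving 100 conditions. A session presents each
condition three times (300 trials) in six scenario-homogeneous blocks of
50; the displayed split is jittered by an integer drawn uniformly from
{−2, …, +2} while keeping `x1 + x2 = 100`. Design choices the task
description leaves open, decided here: the jitter is an integer uniform on
the full ±2 range (the simplest rule consistent with displayed examples
like 88:12); 50:50 trials are jittered too, so the victim can end up the
(slightly) richer party — the `max(·, 0)` terms in the utilities handle
either sign; blocks alternate scenario, with the starting scenario decided
by the session seed; each scenario's 50 conditions appear exactly once per
block, which balances conditions over time.

## The model family

Choices are modeled as a softmax over the utilities of not intervening
(`U_no`) and intervening (`U_yes`):

    P(yes) = 1 / (1 + exp(λ (U_no − U_yes))),    λ ∈ [0, 10].

The full seven-motive utility ("motive cocktail") is

    U_no  = x3 − γ max(x1 − x2, 0) δ_no − α Σ_j max(x_j − x3, 0)
            − β Σ_j max(x3 − x_j, 0) + ω (x1 + x2) + κ max(x2 − x1, 0)
    U_yes = same expression on the post-intervention payoffs
            (x1′, x2′, x3′ = x3 − cost), with δ_yes in place of δ_no

with inequality-discount factors

    δ = 2 / (1 + exp(η · cost / 50)),    η_no, η_yes ∈ [0, 20],

which equal 1 at zero cost or zero rate and attenuate the victim-centered
inequality term as the intervention cost rises. Sub-models zero out the
absent weights: self-interest only (SI), + self-centered inequality (α
disadvantageous, β advantageous), + victim-centered inequality (γ),
+ efficiency concern (ω on the other parties' total), + reversal
preference (κ, signed, on the victim ending richer). A baseline model is
a constant Bernoulli rate `q`. Two further variants handle inattentive
responding: a lapse version bounding P(yes) between `P_min` and
`1 − P_max` (both in [0, 0.5]), and a simple-response model that maps a
linear combination of the manipulated variables directly to choice
probability (scenario dummy-coded punishment = 1, the other predictors
z-scored over the session — a convention chosen here; the exact coding
used in prior fits of such rules is not standardized).

Both reversal-preference and victim-centered terms are kept literally in
the utility even though at most one of `max(x1 − x2, 0)`,
`max(x2 − x1, 0)` is nonzero in any state. Post-intervention payoffs may
go negative (maximum impact 150 exceeds any x1); no flooring is applied,
keeping the utilities piecewise-linear.

Free-parameter counts (used by AICc): baseline 1, SI 1, +SCI 3, +VCI 4,
+EC 5, +RP 6, cocktail 8, cocktail+lapse 10, simple-response 7.

## Fitting and model comparison

Each model is fit per participant by maximum likelihood (Bernoulli
likelihood of the 0/1 choices, probabilities clipped to
[1e−12, 1 − 1e−12]) with multistart bounded L-BFGS-B. The reference
multistart count is 500; desk-scale analyses and the test suite use
8–50. Starting points are uniform within bounds except for slope
parameters (inverse temperature), which are drawn log-uniformly
(10^U(−2, 1)): a uniform draw of λ on [0, 10] almost always lands where
choice probabilities are saturated and the gradient vanishes, which
starves small multistart budgets. The first start is a deterministic
anchor near the small-parameter corner, where the surface is curved. The
baseline model's rate is estimated by its closed-form MLE (the mean
choice). Estimates on a bound are flagged. Softmax exponents are clamped
to ±700 before exponentiation.

Models are compared per participant by AICc,
`2·NLL + 2k + 2k(k+1)/(n−k−1)` (ties toward fewer parameters), and at
the group level by random-effects Bayesian model selection: model
identity per participant is a random effect with population frequencies
`r ~ Dirichlet(1)`, updated variationally (tolerance 1e−8 on the
concentration, max 10,000 iterations) from per-participant log-evidence
proxies `−AICc/2`. Exceedance probabilities come from Monte-Carlo
Dirichlet draws (default 1e6, seeded), or the analytic Beta tail when
only two models are compared. The Bayesian omnibus risk compares the
variational free energy against the fixed equal-frequency null, and the
protected exceedance probability is `EP·(1 − BOR) + BOR/K`. The choice
of `−AICc/2` as the evidence proxy follows the use of AICc as the
fit metric; exact marginal likelihoods are not available for these
models.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
not any particular observed cohort. Parameters are drawn per participant
from a three-component mixture (weights 0.35 / 0.18 / 0.47) whose
components produce the three behavioral regimes the pipeline is designed
to resolve, with gamma laws for the nonnegative weights, a normal law for
the signed reversal preference and beta laws for lapse rates, all
truncated to the parameter bounds by rejection:

* **justice warriors** — strong victim-centered aversion (γ ≈ 1.2) with
  low inaction discounting (η_no ≈ 0.5), high action discounting
  (η_yes ≈ 8) and relatively deterministic choices (λ ≈ 0.8): high
  intervention wherever inequality exists, modulated by cost;
* **pragmatic helpers** — efficiency concern (ω ≈ 0.45) and strong
  reversal preference (κ ≈ 1.2) with weak determinism (λ ≈ 0.15):
  moderately high, flat, helping-tilted intervention;
* **rational moralists** — the warriors' γ but strong discounting in
  both directions (η_no ≈ η_yes ≈ 5): little intervention unless the
  cost is minimal.

The components differ chiefly in η_yes, κ and η_no — the same contrasts
that distinguish the empirically described phenotypes. The
regime-defining weights are kept tight within a component (gamma shape 9,
CV 1/3) so that the regimes stay geometrically resolvable; the minor
weights (α, β, ω where not regime-defining) get wide heterogeneity
(gamma shape 2, CV ≈ 0.7) with archetype-linked means, matching the
order-of-magnitude spread of inequality-aversion weights across people —
without real between-participant variance in a weight, recovery
correlations for it would be undefined. These hyperparameters are
synthetic defaults: passing tests show that the pipeline recovers
structure of this kind, not that any real population has these values.

Choices are Bernoulli draws from the model's per-trial P(yes).
Decision times, generated only to exercise exclusion rules, are lognormal
with a mean that peaks where P(yes) ≈ 0.5 (hard decisions are slow — an
inverted-U difficulty pattern); they enter no inference. Attention checks
are Binomial(12, accuracy). Exclusions: attention accuracy strictly below
75%, or mean decision time above the cohort mean + 2.5 s.d.

## Validation machinery

**Model recovery** simulates cohorts from each generating model's default
population, fits all candidate models, and tabulates AICc winners into a
confusion matrix. Desk scale is 10 datasets per generator with 30
multistarts (the reference procedure uses 100 datasets and 500 starts;
both are configurable). **Parameter recovery** correlates generating and
re-estimated parameters per participant (Pearson); parameters with zero
truth variance are reported as undefined rather than raising. A
repetition multiplier tiles the 300-trial session (e.g. ×10 = 3,000
trials) to probe consistency under more data. **Redundancy checks**
permute each fitted-parameter column independently across participants
(destroying cross-parameter correlations), simulate and refit, and
compare correlation matrices before and after: structure that survives
only in the original fits is behavioral, not a parameter-space artifact.

**Power curve.** The reference power analysis refits a generalized linear
mixed model per replicate; that is out of scope here. The stand-in fits a
lightly ridge-penalized logistic regression per participant (z-scored
inequality, cost, ratio, scenario dummy, all two-way products and the
three-way product) and t-tests the inequality × cost × ratio coefficient
across participants, counting replicates significant at α = 0.05. It
preserves the two properties the suite checks — type-I calibration at the
null and monotone power in the sample size — but its absolute power
values are not comparable to mixed-model results.

## Phenotyping

Participants are summarized by their mean intervention rate in each of
the 100 conditions (nominal-split bins, mean over the 3 repetitions) and
clustered with Euclidean k-means; the cluster count is chosen by mean
silhouette over k = 2…10 with 100 restarts (ties toward smaller k).
Profiles are not standardized — all columns already live on [0, 1].
Sensitivities dichotomize exactly as printed: high inequality =
{90:10, 80:20, 70:30}; low cost = cost ≤ 20; high ratio = 3.0; scenario =
helping vs punishment; each sensitivity is the (high − low) probability
difference divided by the participant's overall P(yes) (undefined, and
flagged, when the participant never intervenes). Archetype *names* are
reporting plumbing layered on top of the clustering: deterministic
thresholds on a centroid's overall level and its scenario / inequality /
cost sensitivities map it to one of six labels (justice warrior,
pragmatic helper, rational moralist, scenario-response, cost-response,
random-response).

## Extrapolation to expenditure protocols

Utility-gain grids evaluate `ΔU = U_yes − U_no` over inequality × cost,
one panel per scenario × ratio; for display, positive and negative values
are scaled separately within each column (positives by the column
maximum, negatives by the magnitude of the column minimum).

Continuous-expenditure protocols (candidate costs 0–100 in steps of 10,
cost 0 = no intervention) are simulated by evaluating the utility of each
candidate cost and reporting the utility-maximizing cost, ties toward the
smaller cost. The choice of argmax is a design decision — it makes the
prediction a pure function of the parameters; a softmax-weighted expected
expenditure (using λ) is available as an option. Second-party
intervention (the victim punishing on their own behalf) substitutes the
victim's payoff x2 for the intervener's endowment slot in the utilities
and sets ω = 0 (a second party is assumed not to value the other parties'
total welfare).

## Problem sizes and numerical defaults

Desk-scale defaults used by the test suite and the acceptance script:
30 multistarts per fit, 10 recovery datasets per generator, 50
participants for parameter recovery, 120 participants for phenotyping,
50,000–100,000 Monte-Carlo draws for exceedance probabilities. Optimizer
tolerance 1e−8 (ftol), maximum 500 iterations per start. All randomness
derives from a single seed via named substreams (CRC-32 of the stage
name folded into a `SeedSequence`), so any stage reproduces in isolation.

## Known limitations

* The generator's population hyperparameters are constructed, not
  estimated; absolute recovery correlations and cluster silhouettes
  depend on them.
* The power stand-in is not a mixed model; only its calibration and
  monotonicity are meaningful.
* The simple-response model's predictor coding is a convention; fits to
  data generated under a different coding will shift its weights.
* Expenditure extrapolation assumes the argmax choice rule; graded
  stochastic spending would require the softmax mode and a noise model
  for the reported amounts.
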