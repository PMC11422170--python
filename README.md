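# motivecocktail

Computational modeling of **third-party punishment and helping**: why do
unaffected bystanders pay to sanction a transgressor or compensate a
victim, and which mixture of socioeconomic motives drives each person's
decisions?

The package implements, end to end, the analysis pipeline for the
*intervene-or-watch* task: a third party endowed with 50 tokens watches a
dictator split 100 tokens with a passive victim and decides whether to
accept a costly intervention offer (pay `cost` to change the
transgressor's or victim's payoff by `ratio × cost`). Scenario
(punishment/helping), inequality (50:50 … 90:10), cost (10–50) and impact
ratio (1.5, 3.0) are crossed into 100 conditions × 3 repetitions per
participant.

## The model family

Binary choices follow a softmax of the utility difference,
`P(yes) = 1/(1 + e^{λ(U_no − U_yes)})`, where the full seven-motive
utility ("motive cocktail") is

```
U = x_self − γ·max(x1 − x2, 0)·δ − α·Σ_j max(x_j − x_self, 0)
    − β·Σ_j max(x_self − x_j, 0) + ω·(x1 + x2) + κ·max(x2 − x1, 0)
δ = 2 / (1 + e^{η·cost/50})
```

with self-centered disadvantageous/advantageous inequality aversion
(α, β), victim-centered inequality aversion (γ), efficiency concern (ω),
reversal preference (κ) and cost-dependent inequality discounting
(η_no for inaction, η_yes for action). Nested sub-models (self-interest
only up to the full cocktail), a Bernoulli baseline, a lapse-rate
variant and a simple linear response rule complete the nine-model family.

The pipeline covers: session generation, synthetic cohorts with
three behavioral archetypes (justice warriors, pragmatic helpers,
rational moralists), multistart maximum-likelihood fitting, AICc and
random-effects Bayesian model selection with protected exceedance
probabilities, model/parameter recovery and redundancy validation,
silhouette-selected k-means phenotyping, and out-of-sample simulation of
second-party vs third-party expenditure protocols. See
`docs/methods.md` for the science and the numerical choices.

## Worked example

```python
import motivecocktail as mc

# 12 synthetic participants from the documented archetype population
cohort = mc.simulate_cohort(mc.default_population(), 12, seed=7)

# fit four models per participant (30 multistarts each), compare by AICc
tab = mc.fit_cohort(["baseline", "SI", "SI_SCI_VCI", "cocktail"],
                    cohort, mc.FitOptions(n_starts=30, seed=7))
print(mc.best_model_counts(mc.delta_aicc(tab)))

# group-level random-effects model selection
bms = mc.rfx_bms(mc.evidence_matrix(tab), mc_samples=100_000, seed=7)
for model, pep in zip(bms.models, bms.pep):
    print(f"{model}: PEP = {pep:.4f}")
```

prints

```
baseline       0
SI             0
SI_SCI_VCI     0
cocktail      12
SI: PEP = 0.0001
SI_SCI_VCI: PEP = 0.0001
baseline: PEP = 0.0001
cocktail: PEP = 0.9996
```

All 12 participants were generated from the full model and all 12 are
best fit by it (lowest AICc); the protected exceedance probability —
the posterior probability that the cocktail is the most frequent
data-generating model in the population, protected against the
equal-frequency null — is ≈ 1.

The same pipeline is available from the shell:

```sh
motivecocktail simulate --n 20 --seed 7 --out cohort.csv
motivecocktail fit --data cohort.csv --models all --starts 30 --seed 7
motivecocktail compare --fits fits.csv --seed 7
motivecocktail cluster --data cohort.csv --seed 7
motivecocktail report --fits fits.csv --bms bms.json --clusters clusters.json
```

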