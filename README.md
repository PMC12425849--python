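# nondirtest

Statistical tests for **non-directional within-participant effects** in
trial-level behavioural data.

In a typical within-participant experiment (e.g. congruent vs. incongruent
primes), the standard analysis averages each participant's condition
difference and t-tests the group mean. That test is *directional*: it can
only see effects whose sign is shared across people. If every participant
has a real effect but signs vary — some faster on congruent trials, some
slower — the group mean sits near zero and the t-test reports nothing,
even though the manipulation affects everyone. `nondirtest` provides tests
of the **global null** (no participant has any effect) that are robust to
such sign heterogeneity, together with the generative simulator used to
validate their calibration and power.

## The tests

Let participant *i* contribute trials in two conditions *c* ∈ {0, 1}, and
let *s(i)* be a signed per-participant statistic (mean RT difference,
Cohen's *d*, Δ*d′*, φ, or a type-2 AUROC contrast).

* **Sign Consistency (SC)** — for each participant, split their trials into
  two random halves (stratified by condition, 500 splits) and score the
  proportion of splits in which both halves give the same sign of *s*.
  Under no effect E[SC] = ½; a real effect of either sign pushes SC toward 1.
  The group mean SC is referred to a permutation null: condition labels are
  shuffled within participants (100 permutations each) and 10,000
  group-level null samples are drawn by averaging one shuffled score per
  participant (Stelzer-style aggregation).
* **Absolute Effect Size (|ES|)** — the group mean of |*s(i)*| in
  standardised units, against the same two-stage permutation null.
* **Prevalence global-null test (GNT)** — test each participant at
  α_individual (two-sided t or within-participant permutation), then test the
  significant count *k* of *n* against Bin(*n*, α_individual) with a
  one-sided binomial test; the one-sided Clopper–Pearson lower bound on
  prevalence is reported (the upper bound is 100% by construction).
* **Omnibus ANOVA (OANOVA)** — trial-level fixed-effects *F* test comparing
  the participant × condition cell-mean model to participant intercepts:
  F(P(C−1), N−PC).
* A two-sided **directional sign-flipping test** on the population mean is
  always available as the companion directional analysis.

## Worked example

Simulate the *non-directional differences* scenario — every participant has
a true effect e_i ~ N(0, 15 ms), trial noise σ_w = 30 ms, 15 participants,
100 trials per condition — and analyse it:

```python
from nondirtest import (ScenarioParams, simulate_scenario, apply_exclusions,
                        SignConsistency, AbsoluteEffectSize,
                        mean_difference, directional_sign_flip_test)

sim = simulate_scenario(ScenarioParams.non_directional(), seed=7)
table, report = apply_exclusions(sim.table)   # >=5 trials/cell, variance > 0

effects = [mean_difference(p) for p in table.iter_participants()]
print(directional_sign_flip_test(effects, seed=7))   # 0.327 — nothing there

print(SignConsistency(table).fit(seed=7).summary())
```

```
            Sign Consistency Test
=============================================
Statistic:                 mean_diff
Participants:              15
Group mean:                0.6959
Null mean:                 0.5014
Null 95th percentile:      0.6255
p-value (greater):         0.0036
Permutations/participant:  100
Null samples:              10000
n_splits:                  500
seed:                      7
=============================================
```

The directional test misses the effect (p = .33) because positive and
negative effects cancel; sign consistency finds it (group SC = 0.70 against
a null centred at 0.50, p = .0036). The absolute effect size test agrees,
and more strongly (group |d| = 0.27 vs. null mean 0.12, p < .001):

```python
print(AbsoluteEffectSize(table).fit(seed=7).summary())
```

Every model is also constructible from your own data frame:

```python
model = SignConsistency.from_dataframe(
    df, participant="subj", condition="cond", outcome="rt",
    levels=("congruent", "incongruent"),   # second level is the positive sign
)
```

The same analyses are available from the shell:

```bash
nondirtest simulate --sigma-b 15 --sigma-w 30 --seed 7 -o data.csv
nondirtest test data.csv --method sign-consistency --seed 7 --out result.json
nondirtest power --test abs-es --sigma-b 0 --sigma-w 100 --sims 500 --seed 1
```

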