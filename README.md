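# lexgaze

Individualized lexico-semantic structure and real-time word recognition in
toddlers.

`lexgaze` implements an analysis pipeline for studies that ask how the
*structure* of an 18-month-old's productive vocabulary — not just its size —
shapes spoken-word recognition in a looking-while-listening (LWL)
eye-tracking task. It measures semantic structure at three granularities in
each child's CDI-style checklist vocabulary, reduces 500 Hz gaze streams to a
trial-level accuracy statistic, and relates the two with item-random-effect
mixed models. A synthetic-cohort generator with known effect structure makes
every stage testable end to end without access to any participant data.

## The measures and the model

For each child, with their reported productive vocabulary as input:

- **Category density** (category level): the proportion of each of six
  early-acquired semantic categories (ANIMALS, CLOTHING, VEHICLES,
  BODY-PARTS, FRUIT, DRINKS) that the child produces is rank-ordered; the
  top three categories are that child's *High*-density categories, the
  bottom three *Low*, and a tie straddling the 3/4 boundary promotes both
  categories to High.
- **Degree** (word level): in the child's semantic network — nodes are
  produced nouns, with an edge whenever two nouns share at least two
  perceptual and/or functional features in a feature-norm database — the
  degree of a target word is its number of neighbors.
- **Global clustering coefficient, GCC** (lexicon level): the transitivity
  of that network, `3 × triangles / connected triples ∈ [0, 1]`, where a
  connected triple is a two-path counted at its center vertex.

Per trial, word recognition is summarized over the 300–2000 ms
post-label-onset window as the log-gaze proportion ratio

    LogGaze = ln(P_target / P_distractor)

(positive = target preference; counts are smoothed additively with c = 0.5
so the ratio is always defined). Trials are excluded when the parent rated
the target word below 2 on the 1–4 comprehension scale, and then, among the
survivors, when the child viewed the screen for under 20% of the window.

Semantically related and unrelated trials are modeled separately with

    LogGaze ~ (GCC + Degree + CategoryDensity) * VocabGroup + (1 | Item)

by REML, with sum coding (High = −0.5, Low = +0.5), continuous predictors
standardized within the modeled subset, and z-based p-values. `VocabGroup`
is a median split of productive vocabulary size. Follow-up models fit each
vocabulary group separately with the three structure terms only.

## Worked example

```python
import lexgaze as lg
from lexgaze import gaze as G, model as M

cohort = lg.simulate_cohort(lg.SimConfig(seed=2))          # 79 children
accs = [G.trial_log_gaze(t) for t in cohort.trials]
retained, ledger = G.filter_trials(cohort.trials, accs)
print(ledger.attrs["stages"])
design = M.build_design(retained, cohort.metrics, cohort.density,
                        cohort.groups, lg.EXPERIMENTAL_ITEMS)
print(M.fit_group_model(design, "related", "High").summary())
```

prints the exclusion bookkeeping

```
{'input': 1896, 'removed_comprehension': 108, 'after_comprehension': 1788,
 'removed_track_loss': 78, 'retained': 1710,
 'pct_comprehension': 5.696..., 'pct_track_loss': 4.362...}
```

(1896 trials from 79 children × 24 trials; ~5% lost to each filter under
the default generative settings) and a model panel such as

```
related trials, High vocabulary group
=====================================
n_trials=436  n_items=12  random effects: (1 | item)  converged=True
item intercept variance=0.1255  residual=1.1659
term                                      Estimate   Std.Err   t-value   p-value
(Intercept)                                  0.864     0.115      7.54  4.81e-14 *
Semantic Category Density                   -0.432     0.109     -3.96  7.42e-05 *
Word Degree                                  0.053     0.057      0.92     0.355
Global Cluster Coefficient                  -0.159     0.052     -3.06    0.0022 *
```

The negative GCC estimate is the generated interference effect: children
with more interconnected lexicons recognize words *more slowly* when the
distractor is semantically related, and the default generator concentrates
that effect in the high-vocabulary group (just as the default density
facilitation in unrelated trials is concentrated in the low-vocabulary
group).

The same analysis runs from the shell:

```bash
lexgaze all --seed 2 --outdir out/       # manifest, tables, report, figures
lexgaze simulate --seed 2 --outdir cohort/ --write-samples
```

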