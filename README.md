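# novarecall

A toolkit for **self-completed 24-h dietary recall aligned with the Nova
food-processing classification**, and for evaluating how well two such
instruments agree.

Researchers studying ultra-processed food consumption need the previous
day's intake expressed as the *relative energy contribution of the four
Nova groups* — 1 unprocessed/minimally processed foods, 2 processed
culinary ingredients, 3 processed foods, 4 ultra-processed foods — per
participant. `novarecall` provides the full machinery:

* a **branching questionnaire engine**: yes/no key questions gate
  type-and-amount questions, which gate added-item, preparation and detail
  questions, with dedup warnings and deterministic traversal;
* a **food database** schema (items, grouped items with a representative
  food code, culinary recipes, composition table, portions, Nova
  assignments) with validation, CSV/JSON bundles and two code-generated
  fixtures — a hand-written miniature and a seeded full-shape database with
  526 items behind 395 food questions;
* a **recall processor** that converts portions to grams, imputes skipped
  type/source/preparation answers by fractional allocation over population
  answer distributions, disaggregates dishes into recipe ingredients
  (cooked rice → rice, oil, onion, garlic, salt), attaches energy and Nova
  labels, and computes per-participant Nova energy shares;
* the **three-stage consensus workflow** for assigning Nova groups —
  independent reviewers, shortlisting on any pairwise disagreement, expert
  panel resolution with an audit trail;
* **agreement statistics** between two tools: paired means with 95 % CIs
  and a paired t-test, the intraclass correlation from a two-way model
  (default ICC(3,1), consistency) with F-based CIs and the
  poor/moderate/good/excellent bands at 0.50/0.75/0.90, quintile
  cross-classification with PABAK = (5·Po − 1)/4 and Landis–Koch-style
  bands, stratified ICCs, and the Walter–Eliasziw–Donner reliability
  sample size n = 1 + 2k(z₁₋α+z₁₋β)²/((k−1)(ln C0)²) with one-sided α;
* a **synthetic cohort** generator (demographics, sessions with controlled
  missingness, paired shares from an additive-log-ratio normal model with
  a closed-form implied ICC) so everything is testable offline.

See `docs/methods.md` for the models and design decisions.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/run_recall.py` walks one participant through the
miniature database — 180 g of cooked rice, one 120 g fish fillet with the
preparation question left blank, two sweetened coffees — and prints:

```
code             grams     kcal  nova  imputed
C_RICE_RAW       158.4    570.2     1  False
C_OIL              9.0     79.6     2  False
C_ONION            7.2      2.9     1  False
C_GARLIC           3.6      4.7     1  False
C_SALT             1.8      0.0     2  False
C_FISH_GRILLED    84.0    100.8     1  True
C_FISH_FRESH      28.8     28.8     1  True
C_OIL              4.3     38.2     2  True
C_WHEAT_FLOUR      2.9     10.4     1  True
C_COFFEE         100.0      2.0     1  False
C_SUGAR           10.0     38.7     2  False

total energy: 876.2 kcal
Nova shares (% of energy): {1: 82.1, 2: 17.9, 3: 0.0, 4: 0.0}
```

The rice dish was disaggregated into its five recipe ingredients (mass
conserved: 158.4+9+7.2+3.6+1.8 = 180 g). The missing fish preparation was
imputed 70 % grilled / 30 % fried from a population distribution — the
fried portion then disaggregated further — and every record touched by
imputation is flagged. The share vector says 82.1 % of this day's energy
came from unprocessed/minimally processed foods and 17.9 % from culinary
ingredients.

`python examples/sample_size.py` prints reliability sample sizes, e.g.
detecting even a weak ICC of 0.2 (two ratings per subject, one-sided
α = 0.05, 80 % power) needs **152** subjects.
`python examples/agreement_study.py` simulates a 186-participant two-tool
study and prints the full agreement report;
`python examples/classification_workflow.py` demonstrates consensus,
shortlisting and panel resolution.

## Command line

The same operations are exposed as a thin CLI:

```bash
novarecall fixture --scale paper-shape --seed 1 --out db/
novarecall validate-db db/                      # counts: 526 items, 395 food questions
novarecall simulate --db db/ --n 186 --seed 7 --out-sessions s.json --out-dists d.csv
novarecall process --db db/ --sessions s.json --dists d.csv \
    --out-records records.csv --out-shares shares.csv
novarecall agree --pairs pairs.csv --tool-a self_report --tool-b reference --out report.json
novarecall samplesize --rho0 0 --rho1 0.2 --k 2 --alpha 0.05 --power 0.8   # -> 152
```

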