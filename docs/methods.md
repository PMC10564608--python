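# Methods

`novarecall` models a self-completed, branching 24-h dietary recall whose
output is classified by the Nova food-processing taxonomy, together with the
statistical machinery used to evaluate how well two such instruments agree.
This note records the models, the defaults and the design decisions behind
each part, and what the synthetic cohort does and does not show.

## The recall instrument

The questionnaire is a directed acyclic graph of close-ended questions.
Yes/no **key** questions ("Did you eat fish yesterday?") gate
**type-and-amount** questions; specific type selections can trigger
**added-item** questions (e.g. sugar in coffee), **preparation** questions
(raw/grilled/fried...) and **detail** questions (homemade vs. purchased).
A dietary-restriction question opens the recall; two usual-intake questions
and a supplement question close it. The engine is deterministic and
monotone: identical answer sequences produce identical question sequences,
and answering a question never retracts an already-answered one. Earlier
answers may be revised; downstream answers whose triggers are no longer
satisfied are invalidated, so the session invariant — answers exist only
for triggered questions — holds at all times. Duplicate-reporting warnings
(e.g. "DO NOT include milk added to porridge") are presentation text on the
node; the engine does not auto-correct answers, mirroring how such
instruments rely on respondent action.

Skipping rules: restriction, key, usual-intake and supplement questions are
mandatory; any other question may be explicitly skipped and is recorded as
missing. This matches the scope of downstream imputation, which covers
type/source/preparation fields only.

## Food database

Each selectable item is `individual`, `grouped` or a culinary
`preparation`. Grouped items ("squash, zucchini or eggplant") carry the
composition food code of an explicitly designated representative member;
the representative is declared in the bundle rather than derived, because
deriving it would require consumption-survey data the package does not
ship. Preparations carry no code or Nova group of their own: both come from
the recipe ingredients. Recipes are stored as mass fractions of the
prepared dish (per 100 g of dish), chosen because respondents report grams
of dish consumed; fractions are normalized to sum to 1 at load (with a
logged warning if they did not). Energy is kcal throughout; a bundle
providing `energy_kj_per_100g` is converted at 4.184 kJ/kcal with a logged
note. A composition entry whose Atwater energy (4/4/9 kcal per g of
protein/carbohydrate/fat) deviates more than 30 % from its stated energy
triggers a load-time warning, not an error, so deliberately degenerate test
fixtures still load.

Two fixtures ship as code. The `mini` fixture (~25 items, 5 recipes,
hand-written) covers every item kind, every question type and all four Nova
groups, including a cooked-rice recipe that disaggregates into rice, oil,
onion, garlic and salt; since no public source states ingredient
proportions for these dishes, the fixture's fractions are arbitrary but
fixed. The `paper-shape` fixture is generated from a seed and reproduces
the structural counts of the full-size instrument (526 items = 347
individual/grouped + 179 preparations; 395 food questions =
57 key + 190 type-amount + 47 added-item + 19 preparation + 82 detail);
its labels and compositions are synthetic, and its refiner questions refine
presentation only (they do not re-map items — the mini fixture exercises
re-mapping).

## Processing and imputation

Each reported food passes through portion conversion → imputation (if a
refiner answer is missing) → recipe disaggregation (if a preparation) →
composition and Nova attachment. Imputation is *fractional allocation*:
the reported mass is split across all options of the skipped question in
proportion to a population answer distribution — one report becomes several
weighted records, each flagged `imputed` — rather than hot-deck assignment
to a single category. Distributions are keyed by a conceptual food
identifier (the refiner node's `subject`) and field (`type`, `source` or
`preparation`), because the refined variants are themselves distinct items
so no single base item exists to key on. Distributions are assumed to
reflect report frequencies in the reference population. When no
distribution exists the default is to fail loudly; a uniform split is
available by flag.

Mass is conserved through imputation and disaggregation by construction
(the final allocation takes the remainder), so totals agree to the last
floating-point bit for small option sets and to well below 1e-9 generally.
Supplements are modelled as a flag with zero energy and contribute no
records. A participant whose recall carries zero energy yields an undefined
share vector, flagged and excluded from downstream aggregation.

The per-participant summary is the Nova share vector: the percentage of
total energy intake contributed by each of the four Nova groups, summing to
100 whenever total energy is positive.

## Nova classification workflow

Assignments by ≥2 independent reviewers reach consensus only if all agree
on both group and subgroup (a group-only mode is available by flag); any
pairwise disagreement shortlists the item for an expert panel whose
decision is final. The stage structure (two assigners, two reviewers, then
a panel) is represented generically as labelled assignments, and any
disagreement — including a later reviewer against an earlier consensus —
shortlists the item. Adjudication is order-independent and keeps the full
audit trail.

## Agreement statistics

**ICC.** The default is ICC(3,1): two-way mixed effects, single
measurement, consistency, computed from the ANOVA mean squares
(MS_R − MS_E)/(MS_R + (k−1)·MS_E); absolute agreement (ICC(2,1)) is
available by flag and the report names the form used. Confidence intervals
use the F-distribution method (Satterthwaite degrees of freedom for the
absolute-agreement form). A table with zero between-subject *and* zero
residual variance is rejected as degenerate; a perfect-agreement table
(zero residual only) returns ICC = 1 with a degenerate CI at 1.
Interpretation bands: poor < 0.50 ≤ moderate < 0.75 ≤ good ≤ 0.90 <
excellent, with the boundaries resolved inclusive-lower so that 0.50 is
moderate and 0.75 is good.

**Paired means.** Normal-theory t confidence intervals per tool and a
paired t-test on the differences (Wilcoxon by flag). Zero variance of the
differences makes the statistic undefined; the comparison is flagged
degenerate instead of guessed.

**Quintile cross-classification.** Participants are split into fifths of
each tool's own empirical distribution, so each tool's fifths reflect its
own measurement scale. The default split is rank-based with
ties broken by stable participant order, so the five groups are as balanced
as n allows; a sample-quantile-threshold mode exists and falls back to the
rank split with a warning when heavy ties empty a quintile. Agreement is
summarized by exact and exact-or-adjacent proportions and by
PABAK = (5·Po − 1)/4, the prevalence- and bias-adjusted kappa for five
categories, banded on the modified Landis–Koch scale (≤0 none, ≤0.20
none-to-slight, ≤0.40 fair, ≤0.60 moderate, ≤0.80 substantial, else almost
perfect).

**Sample size.** The Walter–Eliasziw–Donner approximation with
θ = ρ/(1−ρ), C0 = (1+kθ0)/(1+kθ1) and
n = 1 + 2k(z₁₋α+z₁₋β)²/((k−1)(ln C0)²), **one-sided α**, rounded up.
One-sided α is what yields the familiar 152 subjects at
(ρ0=0, ρ1=0.2, k=2, α=0.05, power=0.80) and is stated in the CLI help. The
approximation is accurate but not conservative: at ρ1=0.5 the exact F-test
power at the returned n is ≈0.795 rather than 0.80, which the tests verify
by Monte Carlo.

## Synthetic cohort

The generator emulates the conditions of a two-tool agreement study:
186 participants with the Brazilian adult demographic mix (55 % women,
61 % from the most populous regions, ~95 % with secondary schooling or
more, 30 %/24 % overweight/obese), a 23/186 ≈ 12 % fraction of
participants leaving imputable fields blank, and population mean shares of
52.6/11.9/14.7/20.9 % of energy for Nova groups 1–4.

Paired shares follow an additive-log-ratio (ALR) normal model: each
participant's latent diet is a 3-vector of log-ratios against group 1,
drawn around the population mean with between-subject SD σ_b; each tool
observes it with independent within-tool noise σ_w (plus an optional ALR
bias). Because both layers are Gaussian on the ALR scale, the implied
per-coordinate ICC is exactly σ_b²/(σ_b²+σ_w²); defaults (σ_b=0.8,
σ_w=0.5) imply ICC ≈ 0.72, inside the moderate-to-good range such tool
pairs exhibit. Share-scale ICCs are slightly attenuated by the nonlinear
ALR inverse, which the pipeline tests account for by checking recovery on
the ALR scale and monotonicity on the share scale.

What passing tests do **not** show about real data: the session simulator
answers questions at random (yes-probability 0.35 per key question), so it
exercises traversal, conservation and imputation mechanics, not realistic
diet composition; the ALR model has no energy misreporting, no
day-of-week effects and no item-level disagreement between tools. Results
on real cohorts depend on those features.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeded explicitly;
fixture generation and report writing are byte-deterministic given a seed.
Recipe-fraction and population-share unit sums are enforced at 1e-9; Nova
shares sum to 100 within 1e-6. Validation-suite problem sizes were chosen
to make sampling error negligible relative to the tolerance under test:
ICC recovery uses 1000 replicates of n=500 pairs per true value, null
calibration of the paired test 2000 replicates at n=186, PABAK-under-
independence n=5000, and conservation checks 1000 simulated sessions.

## Known limitations

* The recall resolution model allows at most one item-refining follow-up
  per reported option; deeper refiner chains would need nesting.
* Only energy and the three macronutrients are carried; no micronutrients.
* Multi-day usual-intake modelling, Bland–Altman analysis and automated
  (text-based) Nova classification are out of scope.
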