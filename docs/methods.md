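# Methods

`gaprunner` is a headless re-implementation of an infinite-runner
inattention assessment: a raccoon-style avatar runs at fixed speed along a
1-D track and must jump 180 gaps; the distance from each jump point to the
gap's leading edge, and the omissions (gaps reached without jumping,
triggering an automatic edge jump recorded with distance 0), are the
behavioral measures. The package covers the stimulus program, a seedable
session simulator, a synthetic-participant model tied to the SWAN
inattention subscale, and the complete downstream statistical battery.

## Stimulus program

The default program is 18 blocks × 10 gaps. Each block fixes trunk length
(track units), gap width, and speed (units/s); the inter-stimulus (IS)
time is `trunk / speed`. Blocks fall into three nominal IS classes — SHORT
(< 2 s, ≈1.5 s), MEDIUM ([2, 3) s, ≈2.5 s) and LONG (≥ 3 s, ≈3.5 s) — six
blocks per class. The class boundaries are half-open at 2 s and 3 s, which
places every default block in its advertised class. For blocks B16–B18
the advertised IS labels (1.2/2.2/3.2 s) exceed `trunk/speed` by ≈0.057 s;
the geometry is treated as ground truth and the labels as rounded
annotations. The per-block gap count (10 = 180/18) is a configurable
assumption; the total session lasts 540 s of nominal running time. No
lead-in/lead-out track is modeled before B1 or after B18.

Jump mechanics: a jump spans `speed × airtime` horizontal units
(default airtime 1.0 s), so it clears the gap iff it starts at most
`span − gap` units before the edge. With the default airtime every block
is clearable and the clearance margin shrinks as gaps widen, preserving
the intended difficulty ordering. A FELL outcome is logged but the avatar
respawns at the far edge; outcomes never feed into the metrics.
Intended distances at or beyond the trunk length are clamped to
`trunk − 1e-9` and counted in the log's `n_clamped` metadata.

## Synthetic-participant model

Each participant has a latent inattention `λ ∈ [0, 1]` driving two
channels per gap:

* **Omissions** — an attention lapse over the IS interval is modeled as a
  Poisson hazard: the gap is missed with probability
  `1 − exp(−lapse_rate · λ · t_IS)` (`lapse_rate` default 0.6 /s).
  Omission probability therefore rises with both inattention and IS time,
  which produces the IS-class omission gradient.
* **Jump distance** — voluntary jumps follow a scalar-timing (Weber-law)
  model: `d = d0 · exp(−shift + σ_log · Z)` with `Z ~ N(0,1)`,
  `σ_log = sigma_d / d0`, and
  `shift = attention_gain · λ · max(t_IS − is_threshold, 0) / is_ref`.
  Multiplicative noise makes a participant's spread proportional to their
  typical distance, so inattentive participants' distances both shrink
  and compress toward the gap edge — median *and* IQR fall with
  inattention. The `max(·)` gate (threshold 1.0 s, reference 2.5 s)
  encodes the interpretation that a rapid stimulus train keeps even
  inattentive players engaged: at short IS the distance signal nearly
  vanishes, which is what makes SHORT blocks weak predictors while
  MEDIUM/LONG blocks remain strong.

An earlier additive formulation (lapse recovery consuming distance
`speed · δ` from `d0` with additive Gaussian noise) was rejected at the
design stage: recovered late jumps spread the voluntary-distance
distribution out, so the per-participant IQR *rises* with inattention,
the opposite of the empirically observed positive IQR–SWAN correlation.
The scalar-timing form is the simplest mechanism we found that jointly
reproduces all three predictor signs and the IS-class gradient; it is a
modeling choice, not an estimate fitted to any dataset.

Defaults: `d0 = 3.0` units, `sigma_d = 1.5` units (50 % coefficient of
variation — deliberately large, child-level motor/timing variability;
chosen in a pre-registration-style sweep so within-participant spread
dominates the between-IS-class median spread, keeping the pooled-IQR sign
stable across seeds), `lapse_rate = 0.6`, `attention_gain = 1.0`,
`is_threshold = 1.0` s, `is_ref = 2.5` s, `swan_sigma = 1.0`.
Cohort λ are Uniform(0, 1) by default (configurable, e.g. Beta).

**SWAN.** The 9-item inattention subscale is generated from the same
latent: each item is `round(3·(1 − 2λ) + N(0, swan_sigma²))` clamped to
[−3, 3]; totals lie in [−27, 27] and *higher totals mean better
attention*, the direction implied by the positive median–SWAN and
negative omissions–SWAN correlations this instrument is built around.
The generator is not calibrated to any particular clinical cohort's SWAN
marginal (a Beta λ-distribution can shift it if desired).

**Seeding.** Participant `i` draws everything from sub-streams of
`SeedSequence([master_seed, i])`, so cohorts are reproducible and the
first *k* participants do not change when the cohort grows. The hold-out
validation uses its own derived stream.

## Metrics

Per participant and per scope (ALL, SHORT, MEDIUM, LONG): median and IQR
(Q3 − Q1) of voluntary jump distances, plus the omission count.
Quantiles interpolate linearly between order statistics. Omission events
(distance 0 by construction) are excluded from the distance statistics by
default — distances and omissions are treated as separate, collinear
predictors — with `include_omission_distances=True` preserving the
alternative. A scope with zero voluntary jumps yields NaN distance
statistics and is dropped pairwise downstream, with a logged count.

One modeled subtlety: the *pooled* voluntary median is not perfectly
monotone in λ at extreme inattention, because omissions censor most
heavily in LONG blocks where distances are shortest; within an IS class
the median is monotone. Tests assert the within-class property.

## Statistics

* Pearson r with two-sided t-based p (`t = r√((n−2)/(1−r²))`, n−2 df);
  the 3 predictors × 4 scopes grid carries no multiplicity correction.
* OLS (with intercept) over the 7 nonempty predictor subsets of
  {median, IQR, omissions}, reported as per-term t and p — the standard
  collinearity demonstration (each significant alone, none jointly).
* Per-block correlations: block-wise median distance vs SWAN, B1…B18,
  tagged by IS class; participants without a voluntary jump in a block
  are dropped pairwise for that block.
* One-way fixed-effects ANOVA on those 18 correlations with IS class as
  factor (block-level correlations treated as independent observations),
  then Bonferroni pairwise two-sample t tests at per-test α = family α/3.
* Repeated hold-out validation: predictors are the three per-IS-class
  median distances (each aggregating 6 blocks); each repetition splits
  the cohort into disjoint train/test sets with
  `train_n = round(0.75·n)` (24/8 at n = 32), fits OLS on train, and
  scores the Pearson r between test predictions and observed SWAN totals;
  the raw r values are averaged over repetitions (default 10 000).
  A Fisher-z average is available (`fisher_z_mean`) but off by default.
  Repetitions with constant test response or predictions are excluded
  and counted rather than scored 0.

**Null behavior of the hold-out mean.** Repeated splits of a *single*
finite cohort converge to that cohort's own (chance) predictor–response
association, not to the population value: under a true null the
per-cohort mean r has an across-cohort SD of ≈0.2 at n = 32. Null
calibration therefore averages over many independent null cohorts
(100 × 20 repetitions in the tests), where the grand mean is ≈0.

## Numerical and interface choices

CSV and JSON-lines writers print floats with `repr`, so write→read
round-trips are bit-exact; reports are serialized with sorted keys and
are byte-identical across runs with the same configuration. Degenerate
inputs (constant vectors, n < 3, rank-deficient designs, empty scopes)
raise typed errors rather than returning NaN. The CLI (`gaprunner`) is a
thin layer over the library; every randomized subcommand takes an
explicit `--seed`.

## Problem sizes

Sign-recovery analyses use seeded cohorts of n = 200 (chosen so the
qualitative sign pattern and IS gradient are stable across seeds);
study-scale runs use n = 32 with 10 000 hold-out repetitions; oracle
suites use 100 random instances of size ≤ 12.

## What passing tests do and do not show

The synthetic cohort is a mechanism built to embody the instrument's
working hypotheses, so sign-pattern recovery demonstrates that the
pipeline correctly extracts a signal of that shape — it is not evidence
about real children, real SWAN ratings, practice/fatigue effects,
hyperactivity items, or the magnitudes of real-world correlations. No
age/sex covariates, no go/no-go commissions (the paradigm has no no-go
stimulus) and no ADHD-vs-control classification are modeled.
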