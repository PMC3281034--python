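# Methods

## The measurement model

A contact diary records, for one subject on one survey day under one
recording tool, the locations visited and the face-to-face interactions
that took place there. Visits are classified into six setting categories —
home, other, retail, social, travel, work (this alphabetical order is the
canonical vector order everywhere in the package) — by the *purpose* of
presence, not the venue: a shop employee is at "work", a friend's house is
a "social" setting.

Three person-contact-hours (PCH) measures are extracted per
subject-day-setting, in increasing order of inclusiveness:

- **PCH-interaction** = Σ encounter durations (hours): cumulative two-way
  conversational or touch contact. Repeated encounters with the same
  contact count every time, and simultaneous conversations accumulate once
  per contact (cumulative person-time). Encounters are attributed to a
  setting through their parent visit, because the diary opens a new page
  per location.
- **PCH-reach** = Σ duration × (people within arm's reach).
- **PCH-setting** = Σ duration × (people in the whole setting).

Headcounts exclude the diarist. For a self-consistent report the measures
nest (interaction ≤ reach ≤ setting); real diarists break this ordering
occasionally, so headcount inconsistencies are *flagged, never rejected*,
and `nesting_check` reports the violation fraction per setting and
overall.

The subject-day is the analysis unit and person-days are treated as
independent. Subject-days whose total PCH is zero are retained in the raw
accounting and excluded only at normalization (with a logged count).

## Contact location profiles and tertiles

A subject-day's *contact location profile* divides its setting-specific
PCH by its total daily PCH for the same measure: a 6-vector of shares
summing to 1. Normalization makes subject-days with very different daily
totals comparable and stops outlying totals from becoming their own
clusters.

Subject-days are partitioned by total daily PCH into empirical tertiles
(percentile ≤ 33.33 → low, ≤ 66.67 → medium, else high). The partition
pools subject-days across survey days, consistent with treating
person-days independently; a per-day partition is obtained by calling
`tertile_partition` on one day's totals. Percentile rank
is minimum-rank / n × 100, so tied totals share the *lower* label and a
degenerate all-equal input is entirely "low"; on distinct data this is
identical to average ranks. Trends of a setting's share across tertiles
use a tie-corrected Kruskal–Wallis rank test (the package's choice of
omnibus test; the chi-square p uses df = groups − 1, and an all-identical
input returns H = 0, p = 1 by convention).

## Clustering into mixing types

Profiles are clustered with agglomerative hierarchical clustering,
default unweighted average linkage (UPGMA-style on an arbitrary distance
table), on Euclidean distances in share space. The metric and the
deterministic tie-break — among equal-distance merges, the
lexicographically smallest (cluster-id pair), with leaves 0..n−1 and merge
i creating id n+i — are this package's conventions, chosen so identical
inputs always yield identical trees. Weighted-average, centroid and
complete linkage are available because profile clusterings are typically
robust to the linkage choice; centroid linkage runs the Lance–Williams
recurrence on squared distances.

The cluster count is chosen by the Caliński–Harabasz pseudo-F,
(B/(k−1))/(W/(n−k)), evaluated on the hierarchical cuts for k in
[2, k_max] (no re-partitioning step). The chosen k is the argmax (smallest
k on ties), truncated to a default interpretability cap of 6 — with six
setting shares there are at most six possible dominant settings, and
finer partitions mostly split home- and work-dominated groups. Pass
`cap=None` for uncapped selection (used by the recovery checks). An
all-singleton cut has W = 0 and reports +inf.

Each cluster is labelled by the setting with the largest mean share
(ties break by canonical setting order): HD/OD/RD/SD/TD/WD for
home/other/retail/social/travel/work-dominated. Duplicate labels are
permitted and flagged. Occupancy tables count subject-days per (day,
label); membership diversity counts distinct labels per subject across
days.

## Tool-comparison statistics

Cross-over designs pair the same subject-day under two tools, so:

- **Bland–Altman**: mean paired difference with a t-based 95% CI of the
  mean difference (not limits of agreement — the package reports the CI
  of the bias itself). Pairs missing on either side are dropped and
  counted.
- **Presence ascertainment**: exact two-sided McNemar test on the
  discordant subject-days (Binomial(b+c, ½) tail mass); zero discordant
  pairs returns p = 1. Concordant cells never enter.
- **Between-setting comparisons**: tie-corrected Kruskal–Wallis omnibus,
  then all pairwise two-sided Wilcoxon rank-sum tests — exact enumeration
  for tie-free pooled samples of ≤ 10, otherwise the normal approximation
  with continuity correction — with raw p multiplied by the number of
  comparisons performed (Bonferroni), capped at 1 and reported next to m.
- **Locations visited**: univariate NB2 negative binomial regression
  (log link, Var = μ + αμ²) by maximum likelihood, Newton iterations with
  a BFGS fallback when the dispersion runs to the Poisson boundary (where
  Newton can return non-finite estimates). Reported as the
  incidence-rate ratio exp(β₁) with Wald 95% CI and p. A constant
  covariate or all-zero counts raise a structured error.

## The synthetic-data generator

Raw contact-diary data are rarely publicly deposited, so a generator
with known ground truth stands in for real records. Its defaults *are*
the study conditions: 65 adults × 3 days (Wed/Fri/Sun) × 3 tools =
195 subject-day observations per tool; universal home presence;
day-dependent presence elsewhere (work collapses, social rises on
Sundays); household sizes with median 3, IQR (2,4); a 7.5% headcount
inconsistency rate (mid-range of the 5–10% typical of self-reported
headcounts); and a total daily
PCH-setting scale with median 124 person-hours.

Each subject-day draws a latent *mixing archetype* — one Dirichlet
component per setting, dominant concentration 12 against 0.8 elsewhere
(mean dominant share 0.75; a calibration choice giving clearly separated
clusters) — from day-dependent type frequencies (weekdays favour
home/work types, Sundays home/social; travel and retail types are rare
throughout). The archetype's Dirichlet draw, restricted to the settings
present and renormalized, is the day's target PCH-setting profile; the
whole-setting headcount is constructed as share × total-PCH / duration
with unbiased stochastic rounding, so the *expected* normalized
PCH-setting profile tracks the archetype. This is why `headcount_params`
carries only the arm's-reach ratio distributions (Beta per setting): the
whole-setting headcount is determined by the profile construction, not
drawn independently.

Encounters are coupled to reach headcounts by an invented but documented
rule: each person within reach is conversed with independently
(probability 0.7), for a Beta(2,2) fraction of the stay, occasionally
split into repeated encounters; this guarantees interaction ≤ reach by
construction, so nesting violations occur only through the planted
reach > setting inconsistencies, at the configured rate. Tool views are
per-visit independent thinnings (paper faithful; PDA under-ascertains
home and travel; questionnaire under-ascertains retail/social/other),
with the guarantee that a diary day never loses its last visit — this
keeps the 195-per-tool accounting exact.

All draws consume one `numpy.random.default_rng` stream in a fixed
order, so a seed fully determines the output bytes.

What the generator does *not* emulate: intra-household network structure,
time-of-day scheduling, recall decay over a day, occupational clustering
of the convenience sample, and any calibration of medians/IQRs beyond the
scale anchors above. Passing tests therefore demonstrate correctness of
the measures, statistics and recovery machinery under a plausible
generative model — not that real diary data would reproduce any specific
published estimate.

## Numerical choices and problem sizes

- Validation tolerance for "encounter fits in its visit": 1e-12 hours;
  nesting comparisons use 1e-9 person-hours.
- Profile shares sum to 1 within 1e-9; zero-denominator ratio rows are
  excluded and counted rather than propagated as NaN.
- Oracle suites in the tests run brute-force average linkage on ~200
  random instances of n ≤ 12, exhaustive rank-sum enumeration at pooled
  n ≤ 10, and 500-replicate CI-coverage simulations at n = 500 — sizes at
  which the independent oracles are exact and fast.
- The acceptance script regenerates the default study, reruns the
  pipeline, and recovers a planted IRR of 0.8 at n = 5000; NB coverage is
  estimated from 500 replicates.

## Known limitations

- The interaction-measure profile is a noisy transform of the archetype
  (encounter sampling sits on top of the headcount construction), so
  uncapped pseudo-F selection on interaction profiles occasionally
  prefers 7–9 clusters, splitting a dominant type — mirroring the
  behaviour that motivates the interpretability cap of 6.
- The Bland–Altman CI is of the mean difference; analyses wanting limits
  of agreement must compute them separately.
- McNemar, Wilcoxon and Kruskal–Wallis p-values are unconditional on the
  cross-over order (order effects are not modelled).
- NB regression is univariate by design; confounding between covariates
  is out of scope.
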