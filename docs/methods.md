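# Methods

## Correlation model and edge filter

Functional connectivity between regions i and j is the Pearson
product-moment correlation of their c-Fos-positive cell counts across
subjects. The implementation uses the population (1/n) form of covariance
and standard deviation; the normalization cancels, so the value is
identical to the sample-convention estimate. `n` is always the number of
rows of the count table — if a design contributes two observations per
animal (e.g. bilateral values), that convention is the caller's, and the
matrix records the `n` actually used.

Each pair is tested against the null r = 0 with
t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom, two-sided. The network
keeps an edge exactly when p < α, uncorrected (α = 0.05 by default,
configurable). Significant *negative* correlations are kept by default —
the filter is on the two-sided p — with a `positive_only` switch for
analyses that only admit co-activation. |r| = 1 (exact linear dependence,
e.g. a duplicated region) is assigned p = 0, the limit of the statistic.

Degenerate inputs: correlations need ≥ 3 subjects; a zero-variance region
has no defined correlation and is excluded from edge testing and the
network with a logged warning rather than imputed.

## Centralities and the hub rule

Degree centrality is the raw edge count. Betweenness centrality is
computed by Brandes' algorithm on the **unweighted** edge set (each
unordered pair of other nodes counted once; disconnected pairs contribute
0), reported unnormalized by default with a normalized option (the
Cytoscape convention) and an optional 1−|r| edge-length variant; the
correlation is kept as an edge attribute only. The definition of
betweenness here is purely combinatorial, so hop-count paths are the
default.

Hubs are regions ranked within the top fraction (default 0.35) on *both*
centralities. The cutoff is k = floor(fraction × R) — for 20 regions,
k = 7 exactly, so floor vs round is indistinguishable there; floor is the
conservative choice elsewhere. Ranks are descending-value competition
ranks with ties sharing the best rank, an inclusive reading of "within the
top 35%" that can transiently admit more than k hubs when values tie
(e.g. many regions with equal low degree in a sparse network).

## Area-resampling bootstrap

Each of the `n_replicates` (default 380) replicates deletes one region
chosen uniformly at random and then duplicates one of the survivors (so
the duplicate's source is never the deleted region), keeping the region
count constant. The duplicated column is appended under a `+dup` suffix
and correlates perfectly with its source; that r = 1 edge is retained
under the p = 0 convention and flagged by the suffix. The correlation
matrix, network, centralities and hub calls are recomputed per replicate;
the summary reports, per original region, its median ranks and hub
frequency over the replicates in which it survives. Both per-replicate
choices are recorded. All draws come from one seeded generator.

## Behavioral schedules and session replay

The progressive-ratio requirement for trial m is
P_m = round(5·e^(0.2·m) − 5), rounded half away from zero with results
clamped to ≥ 1. Rounding the full expression (rather than flooring)
is required to reproduce the canonical sequence 1, 2, 4, 6, 9, 12, 15,
20 — flooring gives 8 instead of 9 at m = 5. Fixed-ratio schedules return
their constant requirement.

A session ends at the first 5-minute (300 s) window with no panel touch,
or at 60 minutes, whichever comes first; the scan starts at t = 0, so an
untouched session ends at 300 s. Sessions ending at the cap are treated as
right-censored in the log-rank comparison of session durations;
quit-terminated sessions are events.

The break point is the requirement of the last collected reward; a session
with no reward gets break point 0 and a `no_reward` flag so group
statistics remain computable. Accuracy is correct touches over all panel
touches (NaN when no touch occurred). First-touch latency is measured per
trial from trial start to the first touch of either panel and averaged over
trials with at least one touch. Early-session touch counts use the
half-open window [0, 1200) s: a touch at exactly 1200 s is excluded.

Stage-advance criteria: FR-1/FR-2 require ≥ 50 reinforcements in the last
session; FR-3 requires ≥ 50 on the last two consecutive days (a single day
is insufficient evidence). PR performance is stable when each of the last
three daily reward counts is within 10% of their 3-day mean.

Group comparisons use the pooled-variance Student t by default (a Welch
option exists); zero pooled variance with equal means is reported as
t = 0, p = 1, and with unequal means is an error rather than an infinite
statistic. The Mann-Whitney tests on correlation vectors use the normal
approximation with tie correction, two-sided; per-region tests are
Bonferroni-corrected by the number of regions; each unordered region pair
enters a correlation vector once (a both-triangles option exists).

## Synthetic data: what it emulates and what it does not

The count generator draws latent vectors z ~ N(0, R) and maps each region
to `round(exp(mu + sigma·z))` with sigma² = log(1 + CV²) and
mu = log(mean) − sigma²/2, so column means are the configured region means
in expectation and the across-subject coefficient of variation is the
`dispersion` parameter (default 0.3, a typical between-animal spread for
immediate-early-gene counts). A log-normal map was chosen over Poisson
because the downstream analysis is correlation-based and unitless; the
latent correlation is the recoverable target. The map attenuates
correlations slightly (closed form: r_count = (e^(r·σ²)−1)/(e^(σ²)−1)),
by less than 0.011 anywhere at CV 0.3 — well inside sampling error at the
study's sample sizes. Default region means are order-of-magnitude
placeholders (90–340 cells) and are config-overridable, never ground
truth.

The two-group preset encodes a sparse-vs-dense contrast: the WT-like
latent matrix has base off-diagonal correlation 0.05 with one 0.65 module
(VO/LO, MO, VP, BLAa, MR), and the KO-like matrix has base 0.45, a 0.65
module (VP, BLAa, MPOA, LHp, DR), and a dominant hub (NAcp-m) correlated
0.65 with every region. These values were chosen to be jointly positive
semi-definite (smallest eigenvalues 0.35 and 0.115) and to give the
KO-like network strictly more significant edges than the WT-like network
in essentially every seed at the default sizes of 20 and 18 rows. Group
sizes of 20/18 rows mirror the two-observations-per-animal convention;
mouse-level presets of 10 and 9 are provided.

The generator emulates the *statistical* structure the pipeline assumes —
correlated, overdispersed counts — not real c-Fos data: there are no
bilateral image replicates, no within-mouse correlation between the two
observations, no region-specific dispersion, and no staining or counting
noise model. Passing tests therefore demonstrate that the pipeline
recovers known structure under its own assumptions, not that those
assumptions hold in tissue.

The operant agent is likewise a construction device, not a behavioral
model: it touches at a fixed cadence (default 5 s), misdirects each touch
with a fixed probability (default 0.1), and quits deterministically when
the next requirement exceeds its threshold, which makes the session's
break point known in advance. The `simulate` command draws per-subject
thresholds from N(base, 0.25·base) (floored at 1) so simulated cohorts
have realistic between-subject break-point variance; cohort bases default
to 15 (WT-like) and 32 (KO-like), bracketing the schedule steps around the
observed direction of a motivation increase.

## Numerical choices

* Correlations are clipped to [−1, 1] after computation to absorb
  floating-point overshoot; affine rescaling of any region changes the
  matrix by < 1e-12.
* JSON reports serialize floats at 6 significant digits, making repeated
  runs byte-identical without destroying small p-values.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; no global RNG state is used anywhere.
* Test and acceptance problem sizes (2000 null tables of 10 × 20 for the
  filter-calibration check; 100 seeds for the two-group direction check;
  200 graphs of ≤ 8 nodes for the betweenness oracle) were chosen so each
  check's Monte-Carlo error is several times smaller than the margin it
  asserts.

## Known limitations

* Pearson r captures linear dependence only; no partial correlations or
  lagged measures are offered.
* The per-region count comparison is a simple two-sample t with Bonferroni
  correction, a deliberate simplification of a genotype × region
  repeated-measures design.
* Bootstrap hub frequencies are conditional on a region surviving the
  replicate's deletion (~95% of replicates for 20 regions).
* The uncorrected α = 0.05 edge filter admits ~9–10 false edges per
  20-region network under the null by construction; that is a property of
  the method, not a defect of the implementation.
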