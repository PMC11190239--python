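# Methods

This note documents the models and procedures `sleepscape` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Window construction and nightly features

The raw unit is one night's hypnogram: contiguous 30-s epochs coded wake
(0), light NREM (1), deep NREM (2), REM (3), bracketed by device-predicted
sleep onset and wake onset.  Only the wake/sleep dichotomy matters
downstream; the three sleep stages are collapsed.

Nights are first filtered: nights that are empty or all-wake are removed,
and nights shorter than 30 min that share a calendar day with a longer
night are treated as artefactual naps and removed.  A night's calendar day
is the date of the midnight nearest its sleep onset (i.e. onsets within
12 h either side of a midnight belong to it); an onset at exactly noon is
equidistant and breaks toward the later date.

Window segmentation applies four rules strictly in order to the binary
sequence:

* (a) wake runs shorter than 10 min become sleep (20 epochs; a run of
  exactly 10 min is preserved),
* (b) sleep runs shorter than 10 min become wake, evaluated on the output
  of (a); runs at the sequence ends are eligible for both,
* (c) sleep segments merge into one window when the contiguous wake gap
  between them is strictly less than 60 min; a gap of exactly 60 min
  splits.  The opposite (≤) reading is available as
  `merge_strictly_below_gap=False`,
* (d) windows shorter than 3 h are *short*, the rest *long*.

Windows are half-open epoch intervals `[start, end)`.  Sleep and wake time
inside a window are measured on the original, pre-smoothing labels, so
rule (a) does not erase genuine brief awakenings from the wake-time
features.

The nine nightly features are sleep percentage (total sleep over all
windows divided by the onset-to-wake-onset span), sleep and wake time per
window kind, window counts, and mean window length per kind.  When a kind
occurs more than once in a night, times are summed and lengths averaged:
summing keeps the sleep-percentage numerator equal to total sleep time,
and the mean keeps "window length" interpretable.  Features of an absent
kind are exactly zero (zero-fill).

## Sleep periods

Candidate periods tile each individual's record in 6-calendar-day blocks
anchored at the first recorded night; gaps do not re-anchor, so period
identity is a pure function of the input.  After removing nights with no
sleep windows, a block is kept if at least 3 nights remain and no
contiguous 3-night section of its 6 day-slots accumulates ≥ 5 h of
non-wear.  The period vector is the mean and standard deviation of each
zero-filled nightly feature over the block's nights — 18 values in a
frozen, header-documented order.  The standard deviation is the population
form (ddof = 0): with as few as 3 nights per period the sample form would
inflate small-n periods, and the choice is configurable where it matters.

## Landscape: embedding, clustering, validation

Period vectors are z-scored per column (constant columns dropped with a
warning), embedded with UMAP (15 neighbours, minimum distance 0.1, 2
components) and clustered with DBSCAN in embedding space.  DBSCAN's
parameters are not dictated by the underlying analysis — the phenotype
islands are widely separated, so the clustering method is deliberately
uncritical — and default to eps 0.5, min_samples 15.  Noise points are
assigned to the nearest cluster centroid so every period gets a phenotype
(configurable off).

One deliberate deviation from UMAP's stock defaults: initialization is
`"random"` rather than spectral.  Well-separated phenotype islands
disconnect the neighbourhood graph, and spectral initialization of a
disconnected graph runs through a threaded eigensolver whose floating-point
reduction order is not reproducible run-to-run; random initialization makes
a seeded fit deterministic on a given machine.  Cross-platform bit-identity
of coordinates is still not promised — tests assert partition agreement,
never coordinates.

Cluster validation uses the silhouette score, (b − a)/max(a, b) per point
(a: mean intra-cluster distance, b: mean nearest-cluster distance),
averaged per cluster, computed on embedding coordinates and cross-checked
in the tests against a brute-force implementation at 1e-12.

Because DBSCAN's integer labels are arbitrary, each cluster is mapped onto
a semantic identity (the high-level Clusters 0-4) through the modal
rule-based composition label of its members: every night short-only → 4;
any short-only night → 1; any long+short night → 2; any multi-long night
→ 3; else 0 (every night exactly one long window).  Several DBSCAN islands
may share one identity — mixed phenotypes take discretely many composition
values and legitimately occupy several islands — so the default policy
merges them (`on_duplicate="merge"`); `"error"` forces manual review.  The
same rule list doubles as a fully deterministic classifier
(`rule_based_cluster`) for pipelines that must avoid embedding
nondeterminism; it underlies the ground-truth recovery tests.

## Thirteen phenotypes

Cluster 1 splits by rules, in precedence order: any night with more than
one long window → 1-c; any night with more than one short window → 1-b;
remainder → 1-a.  Cluster 0 splits geometrically: its centroid is the mean
(x, y) of its periods; periods whose radial distance reaches the
(1 − periphery_fraction) quantile form the periphery, carved into six
half-open 60° sectors counter-clockwise from −180° (0-A..0-F); the rest is
0-center, the recommended 8-h monophasic phenotype.  How the reference
analysis delimited its periphery is unreported — this is the single
largest reproducibility gap — so the radial-quantile rule with default
`periphery_fraction = 0.084` (derived from the published subcluster sizes,
54,628 peripheral of 650,339) is a prominent configuration knob, and
letter assignments are positional rather than guaranteed to match the
published letters.  Insomnia-like status (DSM-5-TR-motivated: > 60 min
wake blocks or < 6.5 h sleep) is carried by {1-a, 1-b, 4} (short,
fractured), {1-c, 2, 3} (long, fractured) and, subjectively, 0-E/0-F; the
set is overridable.

## Transition dynamics

Every pair of successive retained periods of one individual is a
transition (successive among retained periods regardless of calendar gap;
`require_adjacent=True` restricts to adjacent 6-day blocks).  The
conditional transition probability CTP(A, B) is the A→B count divided by
the count of transitions leaving A; rows with outgoing transitions sum to
1 within 1e-9, and rows with none stay all-zero and are flagged rather
than smoothed — uniform smoothing would silently bias the estimates.

## Health-condition comparison

Chronic cohorts compare survey-positive against survey-negative
individuals (no-answer excluded).  Acute cohorts compare, within the same
individuals, units starting within 14 days either side of a symptom report
("during") against units starting strictly more than 50 days before it
("baseline"); the −50..−14-day gap zone belongs to neither group, windows
are day-granular and inclusive, and individuals with another report in the
50 days before are excluded.  Transition pairs are dated by the from-period
start date (to-period available as a config alternative).

The chi-square statistic follows the goodness-of-fit convention:
Χ² = Σ (O − E)²/E with the positive/during group observed, the
negative/baseline group's proportions scaled to the observed total as
expected, and dof = categories − 1.  Categories empty in both groups are
dropped (dof reduced); a zero expected count with nonzero observed raises
unless an explicit pseudocount is enabled — a silent infinity is worse than
a loud failure.  Information gain is IG(P, C) = H[P] − H[P|C] in bits
(base-2; the static/dynamic ratio is base-invariant).  Dynamic categories
are all ordered subcluster pairs present in the data.

## The synthetic-data generator

The generator emulates the study conditions the pipeline was built for:
per-phenotype night architectures calibrated to the published feature
tables, within-individual phenotype dynamics, missing nights and non-wear,
and condition-dependent perturbations of the dynamics.  No generative
model is dictated by the reference analysis; all distributions here are
artifact choices calibrated to its published summary tables.

* **Archetypes.**  Each of the 13 phenotypes has an archetype whose sleep
  percentage, window lengths and night-type composition reproduce the
  published per-subcluster means (and sds).  Night types are one-long,
  short-only, long+short, double-long and double-short; composition
  probabilities imply the published per-night window counts.  Types that
  define an archetype's identity (e.g. a double-long night for the
  long+long phenotype) are guaranteed at least once per 6-night block so
  rule-based classification can recover the latent state; sampled
  composition rates are therefore approximate calibrations.
* **Emission.**  A night is assembled from its planned windows: in-window
  wake is placed as interior bouts each shorter than 10 min (so smoothing
  rule (a) provably restores the planned window), and between-window gaps
  exceed 60 min of wake (so rule (c) provably splits).  For zero-variance
  archetypes the pipeline therefore recovers the planned window count and
  kinds for 100% of nights, and realized features are exact to one epoch.
  On multi-window nights the mandatory gap can exceed the wake budget of
  the night-level sleep-percentage target; windows are then emitted as
  pure sleep and the night's sleep percentage lands below target —
  multi-window nights are intrinsically less efficient, as in the
  published tables.  Non-wake epochs are split among light/deep/REM at
  fixed proportions (0.55/0.25/0.20), a cosmetic choice since downstream
  analysis is binary.
* **Dynamics.**  The latent archetype follows a Markov chain that steps
  once per 6-night block — the granularity at which phenotypes are defined
  — and is constant within a block, so the period-level CTP identifies the
  truth matrix exactly.  Sleep onsets are drawn near 23:00 with
  configurable jitter, one candidate night per calendar day, which makes
  the nearest-midnight day-assignment rule deterministic.
* **Missingness and non-wear.**  Nights are missing independently with a
  configurable probability; non-wear is an explicit per-night hours value
  (zero-inflated exponential), since the exclusion criterion only consumes
  the aggregate.
* **Condition effects.**  A chronic effect replaces the transition matrix
  on every chain step of positive individuals; an acute effect replaces it
  on steps into blocks starting within ±14 days of the individual's report
  date.  Positive sets are disjoint across effects, and explicit acute
  reports closer than 50 days apart are rejected, mirroring the cohort
  clean rule.
* **Determinism.**  All randomness derives from one seed via per-individual
  substreams; identical configuration and seed give byte-identical output.

What the generator does **not** emulate: physiologically realistic
intra-sleep stage sequencing, circadian phase and its drift, weekday
structure, correlated missingness, or device-specific staging error.
Passing tests therefore demonstrate that the pipeline's inference is
correct when its structural assumptions hold, not that those assumptions
hold for any particular device or population.

## Problem sizes and test design

Test and verification problem sizes are chosen as the smallest that make
the statistical assertions sharp: window-rule oracle agreement on 10,000
random epoch strings; transition-matrix recovery from a 1,400-individual,
72-night population (≈ 15,000 transitions, max CTP error < 0.05, which
shrinks as 1/√n); chi-square type-I error over 1,000 null replicates with
a large reference group (500 observed vs 25,000 reference units, so the
estimated-expected inflation ≈ 1 + n_obs/n_ref stays ≈ 2%); planted-effect
information-gain ratios at 12,000 units; and an end-to-end run of 500
individuals × 60 nights.  Dynamics-only planted effects share a stationary
distribution between groups, so the static information gain is pure
sampling noise and the ratio is large; prevalence-only effects use
identity chains, making the dynamic categories a bijection of the static
ones and the ratio exactly 1.

## Known limitations

* Cluster counts, heatmap values, condition p-values and information-gain
  ratios of the reference cohort depend on its inaccessible raw data and
  are reproduced in structure only; what is reproduced numerically is the
  arithmetic from its published primary counts.
* The periphery delimitation and the DBSCAN settings of the reference
  analysis are unreported; defaults here are calibrated or conventional,
  and flagged as non-reproducing of exact cluster counts.
* UMAP embeddings are reproducible per machine and seed, not across
  platforms.
* The transition model is first-order over period labels; higher-order or
  hidden-state dynamics are out of scope.
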