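# Methods

This note documents the models, conventions and numerical choices
behind `alsflow`, in the order the pipeline runs them.

## Event-log model

A trace is one patient's ordered sequence of timestamped activities
plus static attributes. Timestamps are real-valued **days since
disease onset**, so `Onset` sits at day 0. The activity vocabulary is
closed: `Onset`, `TrialStart`, the sixteen MiToS impairment states
`M_abcd` (one binary digit per domain, in the order Walking/Self-care,
Swallowing, Communicating, Breathing), and the terminal events `Dead`
and `Censored`.

*Simultaneous events.* Ties in timestamp are broken by a fixed
priority — `Onset` < `TrialStart` < `M_abcd` < terminal — which makes
directly-follows relations deterministic. Two impairment states at the
same timestamp cannot be ordered meaningfully and are reported as a
validation issue instead.

*Missing attributes* are never imputed: stratified analyses drop the
affected traces and report the dropped count.

## ALSFRS → MiToS mapping

The ALSFRS scores ten abilities 0–4. The MiToS construction used here
flags a domain as impaired when its defining item(s) fall to 1 or
below:

| domain | rule (default) |
|---|---|
| Walking/Self-care | walking ≤ 1 **or** dressing_hygiene ≤ 1 |
| Swallowing | swallowing ≤ 1 |
| Communicating | speech ≤ 1 **and** handwriting ≤ 1 |
| Breathing | breathing ≤ 1 |

Every rule — items, score thresholds, any/all combinator — is
overridable through `MappingConfig` (including from YAML), confining
the risk of divergence from any particular published variant to
configuration rather than code. A visit counts as a functional
assessment only when all items the active mapping references are
scored; partially scored visits are dropped by the cohort filters so
that no domain is ever silently guessed.

## Cohort filters

Subject-level rules run in a fixed order (a subject removed by an
earlier rule is not counted under later ones): unrecorded onset date;
onset after trial start (trial mode); no visit with a functional
assessment; no functional visit within the enrollment window (trial
mode, default 183 days ≈ 6 months after trial start). Visit-level
rules then drop unassessed visits and, in trial mode, pre-trial
visits. The filter report tallies every rule and satisfies
`before − removed = after` by construction.

## Event emission

State events are emitted **on change only**: the first retained visit
always emits its state, later visits emit only when the encoded state
differs from the previously emitted one. This keeps traces short and
matches how staging systems are read clinically (a state persists until
it changes). With `lock_monotone` impairments are carried forward
(domain-wise OR with the previous state), which suppresses recorded
regressions; the default leaves it off, because improbable regressions
are exactly the data errors a deltaGraph review should surface. The
censoring timestamp is the recorded survival time, falling back to the
last visit when absent.

## Directly-Follows Graph

Edge count (A, B) is the number of consecutive pairs A→B over all
traces; the transition probability divides by **all directly-follows
pairs leaving A**. This denominator is well-defined under cycles and
revisits, and coincides with per-patient node cardinality on acyclic
progression logs (where each patient passes a state at most once);
outgoing probabilities from every non-terminal activity sum to one. A
consequence worth noting: an activity occurrence that ends a trace
emits no pair, so it does not enter its activity's denominator.

Pruning (`probability > threshold` is kept, strict) affects display
and export only — node counts and downstream statistics never change.
DeltaGraph edges present in both cohorts are classified
A-favored/B-favored when |Δ| exceeds the threshold, similar otherwise;
edges present in only one cohort are labeled one-sided rather than
silently scored against zero, so that absences driven by small cohorts
stay recognizable.

## CareFlow trees

Each trace containing the root contributes the suffix starting at the
**first** occurrence of the root; node times are event timestamps minus
the root timestamp. Traces without the root are excluded from the tree
but retained in `population_size`, the denominator of the
whole-population edge percentages. Pruning removes nodes below the
support threshold with their subtrees and leaves parent supports
untouched, so children percentages may sum below one — the mass of the
out-filtered infrequent pathways. Siblings are ordered by descending
support, then activity name, and node ids are assigned in DFS order,
which makes the DOT export byte-deterministic.

*Node inference.* For a two-level stratification, each node's 2×2
table compares stratum members containing the root against those among
them whose pathway reaches the node; the reported ratio is the ratio of
these reach proportions. Fisher's exact test is used when any expected
cell count is below 5 (the classical rule; the cutoff is
configurable), otherwise the 1-df χ² without continuity correction.
No multiplicity adjustment is applied across nodes — the p-values are
per-node, as they are usually read in pathway graphs — and the
stratum levels are ordered alphabetically. The two-sided Fisher p is
computed by exact integer enumeration of the hypergeometric support
(with the conventional 1e-7 relative tolerance for near-ties),
cross-checked in the tests against an independent floating-point route
and against scipy.

## Transition times

For a source–target pair, a trace containing the source contributes
the time from the first source occurrence to the first later target
occurrence; under `consecutive_only` the target must be the very next
event. Traces reaching the source but not the target contribute a
right-censored duration up to their terminal event. Death before a
non-death target is treated as right-censoring — the standard
Kaplan–Meier assumption — which overestimates the eventual transition
probability when death competes; competing-risk estimators are out of
scope and this is a documented limitation.

*KDE ("time to fly").* Gaussian kernel on the observed (uncensored)
durations, Silverman bandwidth, 512-point grid from 0 to 1.2× the
largest duration (extended to max + 4 bandwidths when the Silverman
bandwidth is large, so the upper tail stays integrable). Degenerate
samples (single observation, zero spread) fall back to a 10-day
bandwidth. The reported median is the sample median of the raw
observed durations, not a feature of the smoothed curve. Because the
kernel is Gaussian and the grid starts at 0, a little mass leaks below
zero when durations sit within a couple of bandwidths of the origin;
for the transition times this package targets (hundreds of days) the
on-grid integral stays within 2% of one.

*Survival.* Kaplan–Meier fitting and the two-group log-rank test are
delegated to `lifelines`; the tests verify the product-limit against
1 − ECDF (no censoring) and hand-computed censored cases.

*Mann–Whitney.* Exact null enumeration when both samples have ≤ 20
observations and no ties, else the normal approximation with midrank
tie and continuity corrections (scipy). Dataset comparisons follow the
small-sample rule: below 5 transitioning subjects per side no p-value
is produced, only medians for qualitative inspection.

## Synthetic cohort generator

The generator is the package's test bed, not a biological model. Each
domain carries an independent exponential impairment clock started at
onset, rate = baseline × onset-site multiplier; impairments are
permanent. Death is piecewise-exponential: the hazard is multiplied by
a constant factor per currently impaired domain and scaled by
exp(effect × (age − 55)/10). Observation reads the latent state at
visit times — enrollment offset plus normally jittered intervals —
until death or administrative censoring at enrollment + follow-up;
impairments are therefore interval-censored to visit dates while death
times are taken as exactly known (registry-linkage assumption).
Patients who die before enrollment yield an `Onset` + `Dead` trace with
no visits.

Default parameters, with rationale:

* **Population** — onset-site mix 71.9% spinal / 20.8% bulbar / 1.1%
  both / 6.2% other, age 55.26 ± 11.68 years truncated to [18, 95],
  62.6% male: the published baseline characterization of a large
  pooled-trial ALS population.
* **Schedules** — trial-like: enrollment 180 ± 90 days after onset,
  visits every 32 ± 5 days, follow-up 407 ± 175 days (min 60);
  registry-like: visits every 125 ± 25 days, follow-up 931 ± 627 days.
  Interval and follow-up means jointly reproduce the reported ~12.7
  visits per trial patient and ~7.4 per registry patient.
* **Hazards** — walking 8e-4, swallowing 4e-4, communicating 2.5e-4,
  breathing 3.5e-4 per day; spinal ×2 on walking, bulbar ×2.5 on
  swallowing and ×1.8 on communicating (×0.6 on walking); death
  baseline 3.5e-4/day, ×1.8 per impaired domain, age effect 0.3 per
  decade. Chosen once so that, under the trial schedule, roughly a
  quarter to a third of patients die in follow-up, most enter
  observation unimpaired, and each patient records on the order of 1–2
  impairment events — the regime in which the mining and inference
  machinery is meant to operate. They are not fitted quantities.

Reproducibility: every patient draws from RNG substreams keyed by
(seed, patient index, stage), so enlarging a cohort never reshuffles
existing patients and all emitted artifacts (CSV, JSON, DOT) are
byte-identical for a given seed.

What the generator deliberately does **not** emulate: ALSFRS item-level
trajectories (states are emitted directly), disease-duration-dependent
(non-constant) hazards, correlated domain clocks, tracheostomy as a
distinct outcome, treatment effects, or informative censoring. Tests
passing on generated data therefore demonstrate the correctness of the
pipeline's bookkeeping and inference under known ground truth — not
fidelity of any clinical conclusion drawn from real cohorts.

## Problem sizes

The default verification runs use cohorts of 500–2000 synthetic
patients: 2000 with dense (10-day) visits for rate recovery, 500 per
arm for the onset-site contrast, 1000 for the age-at-onset survival
contrast. These sizes put the Monte-Carlo error comfortably inside the
stated recovery tolerances (15% on hazard rates; direction and
significance for the cohort contrasts) while keeping any single run in
the seconds range.

## Known limitations

* Competing risks are folded into right-censoring (above).
* The Fisher/χ² switch uses the expected-count < 5 rule; other
  cardinality rules exist and can be emulated via the cutoff parameter.
* Node-level p-values are unadjusted for multiplicity.
* The DFG probability denominator counts directly-follows pairs, which
  differs from per-occurrence normalization on logs with revisits.
* KDE mass can leak below zero for transitions much faster than the
  bandwidth.
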