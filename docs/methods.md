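# Methods

## Study design

The pipeline estimates temporal disease–disease associations from
longitudinal diagnosis claims. Calendar time is split into an *observation*
window, which defines both the cohort (patients with at least one claim in
it) and disease exposure, and a later, non-overlapping *outcome* window in
which incident diagnoses are read. Diagnosis codes are truncated to their
3-character ICD-10/KCD category. Both window memberships are inclusive of
their endpoint dates and compared at day granularity.

For an ordered pair D₁ → D₂ the at-risk group excludes everyone with an
observation-window record of D₂; within it, exposure to D₁ and acquisition
of D₂ give the 2×2 counts (a, b, c, d) and the relative risk
RR = (a/(a+b)) / (c/(c+d)). Because the at-risk groups of the two
orientations differ, RR_ij and RR_ji are genuinely independent quantities;
self-pairs are excluded, so n codes yield n(n−1) tests.

Assumptions worth keeping in mind: exposure is a binary "diagnosed at least
once" indicator (repeat claims within a window are deliberately collapsed,
which fixes the deduplication rule the claims format leaves open); RR is
unadjusted for confounders, so demographically structured diseases can show
elevated RR without a causal progression; and directionality reflects the
chronological study design, not causality.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| observation window | 2002-01-01 … 2003-12-31 | exposure / history period |
| outcome window | 2004-01-01 … 2013-12-31 | incident-diagnosis period |
| `coverage` | 0.8 (`select_codes`); 1.0 in the demo config | cumulative patient-share of ranked codes kept |
| `min_patients` | 947 (`select_codes`); 100 in the demo config | per-code patient floor against unstable RRs |
| `rr_tail` | 0.1 (demo config) | upper tail defining the integer RR cutoff |
| `p_threshold` | 0.001 | corrected-P threshold for edges |
| `adjust` | `bonferroni` (`bh` optional) | multiplicity correction over tested pairs |
| `test` | `fisher` (`chi2` optional) | independence test per pair |
| walk length `t` | 4 | walktrap random-walk length |

Code ranking for coverage counts distinct patients per code, not raw
records: every downstream statistic is patient-level, so record-count
ranking (available via the `counts` argument) would bias toward
frequently-billed conditions. The 947-patient floor is kept as the
`select_codes` default because it is the scale at which a single
misclassified patient stops mattering for RR in a ~900k cohort; the demo
configuration scales it to 100, which is the same fraction (~0.1%) of its
100k cohort. The demo also sets `coverage: 1.0` and `rr_tail: 0.1`: a
24-disease synthetic universe has no long rare tail to trim, and its 552
ordered pairs with ~4% planted progressions put the "extreme tail" of the
RR distribution at the 90th percentile rather than the 99th appropriate for
a quarter-million-pair universe.

The multiple-testing denominator m is the number of pairs actually tested
(equivalently the length of the P-value vector), logged in the manifest as
`pairs_tested` next to `pair_universe`. Both Bonferroni and
Benjamini–Hochberg are provided because the two are often conflated in
applied reports; Bonferroni is the default and is the stricter of the two.

## Numerical choices

- **RR edge cases.** RR = ∞ when c = 0 with a > 0, 0 when a = 0 with
  c > 0, NaN when a = c = 0; an empty margin (a+b = 0 or c+d = 0) raises.
  Non-finite RRs are excluded from both the percentile computation and the
  edge set (their count is logged): they are exactly the unstable estimates
  the min-patient floor exists to suppress.
- **Integer cutoff.** The cutoff is the nearest integer to the empirical
  (1 − tail) quantile (linear-interpolation quantile), halves rounding up.
  Edge retention uses strict inequalities on both RR and corrected P.
- **Degenerate tests.** Tables with an empty margin get P = 1 with a
  warning rather than an error, so a full pair sweep never aborts.
- **Ties.** Code selection breaks count ties lexicographically; `top_nodes`
  breaks metric ties lexicographically; walktrap breaks equal merge costs
  on the lowest community-index pair. All outputs are deterministic.

## Community detection

Walktrap (Pons–Latapy) is implemented in-package: the directed network is
symmetrised (an undirected edge wherever either direction exists — random
walks need reachability in both directions and the clustering is meant to
reflect connectivity, not effect size), walks are unweighted by default
(`use_weights` switches to RR weights), t-step walk profiles are compared
with the degree-normalised Euclidean distance, and communities are merged
greedily by smallest increase in mean squared profile distance, with merges
allowed only between adjacent communities so disconnected components are
clustered independently. The dendrogram is cut at the partition maximising
Newman–Girvan modularity on the unweighted symmetrised graph (the
all-singleton state is a candidate cut too). The test suite cross-checks
partitions and modularity against python-igraph's independent C
implementation and against exhaustive partition enumeration on small
graphs. Chapter enrichment per cluster uses a one-sided
(over-representation) Fisher exact test — the natural direction for an
enrichment question — with BH adjustment across all (cluster, chapter)
tests.

Cluster demographic profiles pool the *union* of patients diagnosed with
at least one member code (pools overlap across clusters), with ages taken
at the start of the observation window; node demographic summaries use the
start of the outcome window. Age is whole years from birth year, the only
resolution the demographics format carries.

## The synthetic generator

Each patient gets a sex (binary F/M, the granularity the glyph encoding
uses) and an age band (defaults <30 / 30–59 / ≥60 with shares 0.45 / 0.43 /
0.12, roughly an early-2000s Korean age pyramid). Within a window each
disease is drawn independently per patient with probability
`baseline × age_effect[band] × (sex_effect if female)`, clamped to [0, 1].
A planted progression multiplies the target's outcome-window probability by
`planted_rr` for source-exposed patients, making the planted value the true
risk ratio; when several planted sources of one target are exposed, the
largest planted RR applies (this preserves the hard-zero case
`planted_rr = 0`). Specs whose product of effects and RR would exceed
probability 1 are rejected up front, naming the offending pair. Every
diagnosed (patient, code, window) event is emitted as 1 + Poisson(0.5)
dated claim rows (dates uniform in-window) so exposure deduplication is
exercised. Identical seeds give byte-identical cohorts.

What the generator does *not* emulate: visit-frequency and utilisation
patterns, coding drift, income/eligibility structure, and any dependence
between diseases beyond shared demographic gradients and the planted
progressions (within a window, draws are independent per code). Passing
tests therefore show that the pipeline recovers structure that is present
under independence-plus-planted-effects; they do not certify behaviour
under real-world confounding beyond age and sex.

The demo scenario (24 diseases) plants three demographically distinct
clusters — elderly/chronic, reproductive-age women's, young/infectious —
connected by within-cluster progressions with RRs between 3 and 20, plus
demographically flat background codes. Planted-RR magnitudes and
prevalences (0.005–0.25 per window) are chosen so that all planted
probabilities stay below 1 and the common codes are as prevalent as common
primary-care diagnoses are in claims data.

## Benchmark problem sizes

The standard self-checks (in `disnet.benchmarks`, exercised by the test
suite and `scripts/acceptance.py`) use: planted-RR recovery with source
prevalence 0.2 and target prevalence 0.02 at n = 100,000 patients, 20
replicates, no demographic effects (so the planted value is exactly the
estimand); null calibration with 20 independent diseases (prevalence
0.02–0.3) at n = 20,000, 20 replicates; community recovery on 4 planted
blocks of 25 nodes with within/between edge probabilities 0.3/0.01, 10
seeds; and determinism on the full 100,000-patient demo pipeline run
twice. Benchmark cohorts simulate only the study diseases, so the whole
simulated population stands in for "patients with at least one medical
visit"; in the demo pipeline, by contrast, the cohort is genuinely the
patients with at least one observation-window claim.

## Limitations

- RR is a marginal association measure; the package deliberately performs
  no confounder adjustment (the demo's inflated within-cluster RRs show
  what that means in practice).
- The percentile cutoff is computed over all finite RRs; computing it over
  significance-passing pairs only is a defensible alternative the
  configuration does not currently expose.
- Chapter enrichment has little power for small code universes (with 24
  demo codes no test survives BH at .05); it becomes informative at the
  hundreds-of-codes scale the design targets.
- Rendering reimplements the visual encoding, not any particular layout
  engine; any seeded force-directed layout is considered equivalent, since
  layout is presentation rather than inference.
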