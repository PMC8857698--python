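# Methods

This note documents the model behind `carenet`, the choices made where the
design was genuinely open, and what validation against the synthetic
generator does and does not establish.

## Unit of analysis

Collaboration is modeled at the level of **functional roles** (service ×
generic role, e.g. `Neurosurg_R`), not individuals: clinical teams are
staffed by interchangeable role occupants, and role-level networks are the
structures that persist across encounters. The **shift rotation** — day =
[07:00, 19:00), night = [19:00, 07:00), half-open at minute resolution — is
the unit of collaboration opportunity: two roles involved with the same
patient during the same shift *could* have worked together. Shift numbers
count boundary crossings from the arrival shift (number 0), so they are a
pure function of the wall clock; translating an encounter by 24 h changes
nothing.

## Event-log preparation

* `t_norm` = minutes from ED arrival, real-valued. Records timestamped
  before arrival (pre-registration artifacts) are dropped rather than
  clamped, since the downstream contract requires `t_norm ≥ 0`.
* Exclusions (system-initiated, student-initiated, incomplete records)
  always return both partitions with machine-readable reason codes, so
  |kept| + |excluded| = |input| is checkable at every stage.
* Locations of notes and flow sheets are inferred from the ADT timeline
  under the half-open `[start, end)` convention; times past the last
  interval take the last location (documentation routinely trails
  discharge).
* Role resolution:
  * attendings, fellows, physician assistants, and nurse practitioners with
    service evidence: modal service of their notes, falling back to the
    roster; fixed across the dataset.
  * residents and radiology technicians: per encounter, the modal
    cosigner service of their notes in that encounter; mode ties are broken
    by the most recent note (the most recent supervision relationship is the
    best guess for a rotating trainee).
  * nurses, unit NPs, and allied HCPs: the service bound to the modal
    location of all their activities; location-mode ties are broken by the
    earliest-seen location, then lexicographically — deterministic and
    data-driven. Their note/flow-sheet records at other locations are
    excluded (`off_base_unit`) rather than relabeled, because an inferred
    location disagreeing with the base unit is more likely an inference
    error than a true excursion.
  * HCPs with no resolvable service are excluded entirely
    (`unresolved_role`). Manual chart review is out of scope; exclusion is
    the fallback.
* A cosigned note yields two same-time events: the author and a same-service
  attending. The note **creation** time is used as the note's event time —
  sign-off can trail writing by hours and says nothing about when the work
  happened.

## Natural-break segmentation

Within-shift activity is bursty: minutes-apart clusters of documentation
separated by long quiet gaps (EHR registration also lags real activity, so
a break must be at least 30 min). The break interval is chosen by a
two-class natural-breaks optimization constrained to the grid
{30, 35, …, 120} minutes: each candidate *c* splits the pooled gap sample
into {g < c} and {g ≥ c}, and the goodness of variance fit
`GVF(c) = 1 − SSD_within/SSD_total` is maximized. Ties go to the smallest
interval (the finest segmentation consistent with the 30-min minimum); a gap
exactly equal to the interval starts a new segment; if all gaps are equal
the optimization is degenerate and the grid minimum is returned with a
warning. Gaps are pooled **globally** across the master log by default so
that one interval serves all six sublogs and day/night networks stay
comparable; a per-sublog mode (`jenks_scope: per_sublog`) is available when
day and night rhythms differ strongly.

## The working-closely-together metric

For each segment, all pairwise combinations of the distinct roles present
are co-segmented for that (encounter, shift); a pair co-segmented several
times within one shift counts once. The edge weight is
`co_segment_shifts / co_present_shifts`, where co-presence is scoped to the
same sublog and the same (encounter, shift) — collaboration opportunity is
defined per patient-shift, not hospital-wide. Weights therefore lie in
(0, 1], with 1 meaning the pair co-segmented in every shift they shared.
Since the counting unit is the (encounter, shift) pair, "shared shifts" and
"shared encounters" coincide here by construction. Roles that appear in a
sublog but never co-segment with anyone are kept as isolated nodes in
exports but reported separately, since published team diagrams show only
connected roles.

## Threshold selection

Raw co-occurrence networks contain one-off pairings that do not reflect
collaboration. The shared-shift threshold is swept over 2..20 on the raw
`co_segment_shifts` counts (applying t = 2 implicitly removes count-1 edges;
their number is reported for transparency). The per-step removal count is
smoothed with locally weighted **linear** regression (`lowess`, fraction
0.5 over the 19 grid points, no robustness iterations — the robustifying
pass would treat the low-threshold removal spike as an outlier and flatten
exactly the feature the elbow rule needs; values clipped at 0). The elbow is
formalized as the smallest threshold from which the smoothed removal rate
stays ≤ ε (default 0.10) of its peak for all larger thresholds — an explicit
version of "the rate of change becomes insignificant or constant". ε and the
LOWESS fraction are configuration-exposed, and the curve plus chosen elbow
are always written out (`threshold_curve_*.csv/png`) so the selection can be
inspected visually. Each sublog network is thresholded independently.
Degenerate cases: an all-zero removal curve yields the minimum threshold
with a warning; a curve that never becomes insignificant yields the maximum
with a warning.

## Overlapping link communities

Communities are detected on edges, so a role can belong to several teams.
For edges e = (i, k), f = (j, k) sharing node k, the similarity is the
weighted Tanimoto of the non-shared endpoints' inclusive-neighborhood weight
vectors: `S = a_i·a_j / (|a_i|² + |a_j|² − a_i·a_j)` with the self-entry
`a_i(i)` set to the mean weight of i's incident edges; with uniform weights
this reduces to the Jaccard index of inclusive neighborhoods. Non-adjacent
edge pairs have similarity 0 and sit at distance 1, so disconnected parts of
the similarity graph join at height 1. Edges are agglomerated with WPGMA
(McQuitty) linkage on d = 1 − S (via `scipy.cluster.hierarchy.linkage`,
`method="weighted"`) with leaves in canonical sorted-edge order, which makes
the dendrogram independent of input edge order. The cut maximizes the
partition density `D = (2/M) Σ_c m_c (m_c − n_c + 1)/((n_c − 2)(n_c − 1))`
over every distinct dendrogram level plus the all-singletons partition; ties
prefer the cut with more communities, then the lower height. Clusters with
at least two edges are reported as communities; single-edge clusters are
background (mirroring the reference implementation of the link-clustering
algorithm, which ignores trivial clusters in community counts). D = 1 iff
every community is a clique spanning its nodes; two-node communities
contribute zero. The cut criterion is partition density — the clustering
algorithm's native objective — rather than modularity; users comparing with
modularity-based tools should expect different counts on weakly modular
networks.

## Statistical comparison

Interval variables: two-sided Wilcoxon rank-sum with the tie-corrected
normal approximation (`scipy.stats.mannwhitneyu`, asymptotic, no continuity
correction — identical samples then give p = 1 exactly). Categorical
variables: Pearson chi-square without Yates correction (the common
statistical-package default for r×c tables). Levels with zero total count
are dropped with a warning; tests with any expected cell < 5 are flagged
`low_expected_cell` rather than replaced by an exact test. Percentages in
the report recompute exactly from the underlying counts at the table's
printed precision.

## The synthetic generator

The generator emulates the *structure* of a one-year level-I pediatric
trauma cohort, not its clinical content:

* **Cohort**: 413 encounters by default, 65.9 % arriving in day shifts;
  age/sex/activation/origin/injury distributions differ by arrival shift the
  way such cohorts do (night arrivals older, more transfers, more
  penetrating injuries). ED length of stay ~ U(150, 360) min; 17 % of
  encounters pass through the PICU (18–48 h) and about half reach the floor
  (12–60 h); Table-1 LOS/admission fields are derived from the simulated
  ADT timeline so the tables and the timelines never disagree.
* **Planted structure**: per (location, shift type) a community spec lists
  role sets plus hub roles added to every burst. Defaults: one merged
  community per location by day; at night five specialty communities in the
  ED and on the floor sharing the `GPS_AT`/`GPS_R` hubs, and one PICU
  community. Within each shift a location window receives 1–3 bursts; each
  burst activates one community, whose roles all document within
  within-burst gaps ~ U(1, 10) min, while bursts are separated by
  U(150, 240) min. The two supports are disjoint by construction (validated
  in the config), so a recoverable break scale always exists; distributions
  are uniform on the stated supports — the simplest choice satisfying the
  separation invariant. Inter-event gap distributions of real EHR logs are
  not publicly characterized for this setting; the supports are stated
  assumptions, not estimates.
* **Nuisance structure**: spurious one-off cross-community pairings occur at
  rate 0.1 per shift window, capped at 3 occurrences per pair so noise stays
  strictly below the planted co-occurrence regime (planted pairs share ≥ 15
  shifts under the defaults); noise pairs avoid resident/rad-tech roles
  because their notes fan out a cosigning attending, which would create
  uncapped attending-side pairs. 5 % of records reference HCPs whose service
  is unrecoverable and 5 % are student/system records; records carry a
  `truth_burst_id` annotation column that the pipeline ignores but tests use
  to compare recovered segments against planted bursts.
* **What passing tests show**: that the full chain recovers a known diurnal
  team structure from raw metadata under realistic burst/noise geometry.
  What they do not show: performance on real EHR data, where role resolution
  errors, non-uniform gap distributions, location-inference noise and roles
  that rarely document (a known blind spot of metadata-based team
  reconstruction) will all degrade recovery.

## Problem sizes and determinism

The default validation runs the full 413-encounter cohort (~25 000 raw
records, ~28 000 master events) through all six networks in well under a
minute on one core; the test suite's brute-force oracles run on networks of
≤ 8 edges and sublogs of ≤ 50 events, where exhaustive enumeration is exact
and cheap. All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical config + seed reproduces byte-identical
CSV/JSON/GraphML/PNG artifacts, and the run manifest records the config
hash, seed and library versions.

## Known limitations

* Role-resolution heuristics assume one generic role per HCP and clean
  cosigning metadata; real extracts need curation the pipeline replaces
  with exclusion.
* The elbow rule's ε and LOWESS fraction are declared conventions; on
  curves without a clear plateau the selected threshold should be reviewed
  against the exported curve.
* Single-edge link-community clusters are reported as background, so
  sparsely connected peripheral roles never form communities of their own.
* Day networks under the default generator contain no spurious edges (a
  merged community has no cross-community pairs), so their removal curves
  are degenerate and thresholding is a no-op there by design.
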