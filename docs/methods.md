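# Methods

`multimorbnet` implements a network view of multimorbidity in type 2 diabetes
(T2DM) cohorts: diseases are nodes, and an edge connects two conditions that
co-occur in the same patients more often than chance. This note documents the
model, the parameters that matter, the synthetic data generator, and the
numerical and design choices.

## Cohort construction

Input is a long table of diagnosis events (patient, date, outpatient/inpatient
flag, ICD-10 code), a patient table (sex, birth date), and a condition catalog
(ICD-10 chapter, chronic/acute flag, index-code flag).

* **Eligibility.** A patient is retained when every calendar year between
  their first and last appearance contains at least three outpatient visits or
  at least one hospitalisation. "Annually" is read as *every* calendar year in
  the span, including partial first/last years; `exempt_partial_years=True`
  relaxes the quota for those two years. Patients with conflicting sex records
  or missing sex/birth date are excluded, each with a reason code.
* **Index date and age.** The index date is the earliest T2DM-coded visit
  (codes matching the configured index set, by exact code or three-character
  stem). Only diagnoses on/after it count as comorbidities. Age is the mean of
  the fractional ages (days/365.25) at the index date and at the last visit,
  stratified into `<40, 40–49, 50–59, 60–69, 70–79, ≥80`.
* **Condition selection.** Analyzable codes are restricted to ICD-10 chapters
  1–14 with pooled-cohort prevalence ≥ `min_prevalence` (default 1%); the bare
  index code is excluded while flagged subcodes of it remain analyzable. A
  three-character code whose four-plus-character subcodes carry *both* chronic
  and acute flags is dropped in favour of the subcodes. The prevalence filter
  is pooled across sexes, so both sex-specific networks draw nodes from one
  shared universe.
* **Multimorbidity rule.** Patients contribute marginal counts `c_i` always,
  but contribute pair counts `c_ij` only when their post-index condition set
  contains at least one chronic condition plus at least one other condition
  (`require_chronic_anchor=True`, the default; set to `False` to require only
  two conditions of any kind).

## Edge statistics and the SCI cut-off

For each unordered pair (i, j) in a stratum of N patients with marginal counts
c_i, c_j and co-occurrence count c_ij:

    SCI_ij = c_ij / sqrt(c_i * c_j)
    phi_ij = (c_ij*N − c_i*c_j) / sqrt(c_i*c_j*(N−c_i)*(N−c_j))
    t_ij   = phi_ij * sqrt(c_ij − 2) / sqrt(1 − phi_ij²)

The SCI (cosine similarity of the two patient sets) is the edge weight: it
depends only on the diseased patients, so enlarging the cohort with unaffected
patients, or exactly duplicating every record, leaves it unchanged, whereas
phi moves with N. Note that phi, being a correlation of proportions, is itself
invariant under *exact* duplication; the sample-size sensitivity of the
phi-based screen enters through t, which carries the c_ij count.

Because the SCI is positive even for negatively correlated pairs, the edge set
is calibrated against the phi screen:

1. compute SCI and phi for every pair with c_ij > 0 (q such pairs);
2. count the pairs (e) with t > t_critical **and** c_ij > mean(c_ij over the
   q pairs); `t_critical` defaults to 2.58, the two-sided standard-normal
   critical value at p = 0.01;
3. the SCI cut-off is the e-th largest SCI; every pair with SCI ≥ cut-off is
   kept (ties included), so the SCI network has (at least) as many edges as
   there are significantly positively correlated pairs.

Numerical conventions: t is set to 0 when c_ij ≤ 2 (the radicand would be
non-positive), and to +∞ when phi = 1 exactly; pairs with c_i = N or c_j = N
have undefined phi and are excluded with an explicit reason rather than
returning NaN. Since t > 2.58 > 0 forces phi > 0, negatively correlated pairs
can never enter the screen count. The degrees-of-freedom term in t uses the
pair's co-occurrence count c_ij; at a few thousand patients this makes the
screen conservative (small c_ij caps t regardless of phi), which is why
desk-scale networks are much sparser than those from registry-scale data.

Networks are built per stratum (sex × age band, up to 12) and globally per
sex, each with stratum-internal N, counts, and cut-off. Strata below
`min_stratum_size` (default 30) patients are skipped with a warning.

## Network metrics

Degree; weighted degree (sum of incident SCI weights); density
2m/(n(n−1)); closeness centrality; harmonic centrality. Harmonic centrality
(Σ 1/d, unreachable pairs contribute 0) is the headline proximity measure
because stratified networks are often disconnected. Distances are unweighted
hop counts: SCI is a similarity and no weight-to-distance transform is
imposed. Average harmonic centrality is reported both raw and normalized by
(n−1) so strata of different sizes are comparable; closeness is averaged over
the largest connected component with a disconnectedness flag.

## Crucial diseases

* **Hubs** — top `k=10` nodes by PageRank on the per-sex global weighted
  network, damping 0.85 (the conventional default). Ties are broken by higher
  weighted degree then code order and flagged.
* **Communities and roots** — Louvain partition maximizing weighted
  modularity (resolution 1.0), best of `n_restarts=20` seeded restarts; the
  root of each community is its member with maximum eigenvector centrality on
  the induced weighted subgraph (dense symmetric eigendecomposition; a
  single-node community is its own root by convention, flagged).
* **Bursts** — on the per-sex age-stratified networks, a node whose degree
  grows by ≥ `burst_threshold=6` between *adjacent* bands (inclusive); a node
  absent from a band has degree 0 there.
* **Cores** — the per-sex intersection hub ∩ root ∩ burst. Hubs and
  communities are computed on the global per-sex network; the stratified
  networks feed only the burst analysis.

**Temporal trends.** The continuous-record subcohort contains patients whose
index date falls in the first study year and who appear in every year through
the last. For each year y from the baseline (default 2015) to the end (2021),
a network is built from all their post-index diagnoses dated ≤ Dec 31 of y —
seven cumulative networks at the defaults — and the degree of each tracked
disease is tabulated (0 when absent). Windows are nested, so pairwise counts
are monotone non-decreasing in y.

## Perturbation analyses

* **Node removal** — each crucial disease removed independently (the network
  is restored between removals); nodes isolated by the removal are dropped
  (the networks never carry degree-0 nodes), the summary metrics recomputed,
  and signed percent changes reported; a summary retaining the isolates is
  also emitted for transparency.
* **Edge removal** — `round(level·m)` edges deleted uniformly without
  replacement at levels 1%/3%/5%, three repetitions each, every (level, rep)
  cell on an independent RNG stream derived from the master seed; the overlap
  of the perturbed top-10 PageRank set with the unperturbed one measures hub
  stability. A level whose removal count rounds to zero is skipped with a
  warning; level 0 is the identity.

## Synthetic data generator

Registry EMR data of this kind is access-restricted, so the generator emulates
its structure with known ground truth. Each patient independently activates
each of `n_clusters` latent clusters with probability
`cluster_activation_prob=0.3`; a condition with baseline prevalence b (drawn
uniformly from `baseline_prevalence_range=(0.05, 0.25)`, the range spanned by
common T2DM comorbidities above a 1% floor) is acquired with probability
`min(b·cluster_effect, 0.95)` when its cluster is active and b otherwise.
Planted hubs respond to *any* active cluster and receive the top of the
prevalence range, so they co-occur across the whole universe. At
`cluster_effect=1` the model is exact independence, which makes the type-I
behaviour of the screen testable. Visit histories: entry year uniform over the
window (never the last year), an index T2DM visit in the first 60 days of the
entry year, Poisson(6) routine outpatient visits plus Bernoulli(0.3)
hospitalisations per year (so the eligibility filter excludes a non-trivial
minority), condition onsets dated uniformly between index and window end.
Catalog codes are ICD-10-shaped (chapter-consistent letter + two digits,
30% with a subcode), 60% flagged chronic.

The default scale is 10,000 patients over 2013–2021 with 120 conditions in 6
clusters — large enough that all 12 age-band networks are non-empty while the
full pipeline runs in seconds. Parameter-recovery checks use 5,000 patients,
60 conditions, 4 clusters, 2 hubs, `cluster_effect=4`; under those conditions
Louvain recovers the planted partition with adjusted Rand index ≈ 1 and the
planted hubs always rank in the PageRank top 10 (hubs are excluded from the
ARI, as they belong to every cluster by construction, and recovery is measured
on the pooled-cohort network since the planted structure is sex-independent).

What the generator does **not** emulate: realistic ICD-10 semantics or
prevalence calibration, age-dependent onset (bursts arise only from sampling
variation across bands), mortality/censoring, coding error, or secular trends.
Passing recovery tests therefore demonstrates that the pipeline detects
block-structured co-occurrence and planted connectivity when present — not
that real EMR data satisfies the model's assumptions.

## Reproducibility

Every stochastic step (generation, Louvain restarts, edge deletion) draws from
RNG streams derived deterministically from a master seed; a full pipeline run
writes a manifest (config, seed, config hash) and re-running the same
configuration reproduces every output byte for byte. All artifacts are plain
text (CSV/JSON/GraphML/GEXF); edge weights are serialized with
shortest-round-trip float representation so export→import is exact.

## Known limitations

* The conservative printed form of t makes edge retention strongly dependent
  on cohort size; cross-cohort comparisons should hold N roughly constant.
* The SCI cut-off retains edges by SCI rank, not by screen membership, so a
  high-prevalence independent pair can displace a low-prevalence associated
  pair — inherent to the calibration, visible in synthetic data.
* Louvain is a heuristic; restarts mitigate but do not eliminate local optima.
* Closeness on disconnected graphs is a within-component quantity; prefer the
  harmonic values for cross-stratum comparisons.
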