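# Methods

## The model

`exprdriver` calls per-patient *functional* somatic mutations from two
matrices: a real-valued expression matrix (features × patients, normalized
upstream) and a binary gene-level mutation matrix (genes × patients, 1 =
the patient carries at least one qualifying somatic event in the gene;
qualifying classes are missense, nonsense and frame-shift — silent events
are retained in the per-event record list but never enter the matrix).

The method rests on two assumptions: (1) a functional mutation directly or
indirectly reshapes the carrier's expression profile, and (2) patients
carrying the same functional mutation therefore resemble each other
transcriptionally. Under those assumptions a functional mutation should be
*enriched* among a patient's expression neighbors, whereas a passenger
should be spread randomly over the cohort no matter how recurrent it is.

### Similarity and neighborhoods

Patient similarity is Pearson correlation r over the k highest-variance
expression features ("biomarkers", default k = 2000; distance is 1 − r).
The neighborhood of patient P is P itself plus the up-to-(n − 1) other
patients with the largest r, all required to satisfy r ≥ r_min
(defaults n = 10, r_min = 0.6). "Most similar" is interpreted as largest
r — with a common vector length, ordering by r and by correlation-test p
coincide. Ties on r break lexicographically by patient ID so runs are
reproducible. A patient whose neighborhood stays below n_min members
(default 5) is *uncallable* and receives no calls: the statistic has no
power there, and such patients are reported in a skipped-patients list
instead of being forced through the test. Because the appropriate n is
not identifiable a priori, `scan_neighbor_sizes` re-runs the caller for
every n in 5..30 and reports each result side by side; results for
different n are never pooled.

### The enrichment statistic

For patient P mutated in gene g, let k = mutated members of P's
neighborhood (P included), n = neighborhood size, K = cohort-wide carriers
of g, N = cohort size. The null model — neighborhoods drawn uniformly at
random — makes the mutated count hypergeometric, so

    p = P[X ≥ k],  X ~ Hypergeometric(N, K, n)

which is identically the one-sided (greater) Fisher exact p of the 2×2
table [[k, n−k], [K−k, N−n−K+k]]. The call is functional when p < α
(default α = 0.01, no multiple-testing correction by default; a
Benjamini–Hochberg flag is provided). A seeded permutation sampler
(`permutation_null_p`) draws random size-n neighborhoods and reproduces
the analytic p empirically; it exists purely as a validation mode, since
uniform subsets without replacement *are* the hypergeometric model. The
sampler's default draws are unconditional; a `condition_on_focal` switch
forces the focal patient into every draw for the stricter reading of
"random neighbors of P".

**Focal inclusion and calibration.** Following the published design the
focal patient counts in both k and n, so every tested pair has k ≥ 1.
Because only mutated (patient, gene) pairs are tested, the observed count
is conditioned on k ≥ 1 while the unconditional tail is not; the default
test is therefore *anti-conservative for rare genes* (e.g. K = 3,
N = 300, n = 10 gives a null rejection rate near 6% at α = 0.01). This is
a property of the design, not an implementation artifact. The
`include_focal=False` switch removes the focal patient from k, n, K and N
consistently, which yields an exactly calibrated (discretely conservative)
variant. The null-calibration checks in the test suite verify both: the
focal-inclusive rate against its exactly computed analytic expectation,
and the focal-exclusive rate against α. Those checks disable r_min
(set to −1), because with no expression signal no pair reaches r ≥ 0.6
and no neighborhood would exist to measure.

### Term annotation

The mutated-gene *pool* of a patient is the union of genes mutated
anywhere in the patient's neighborhood. Each gene-set term (flat GMT; no
ontology propagation) is tested gene-level, one-sided Fisher, pool vs the
rest of a background universe. The default background is the genes
mutated anywhere in the cohort intersected with the gene-set universe —
the self-contained choice given that only the mutation data at hand
define "background occurrence"; the full gene-set universe is available
via `universe="genesets"`. Terms with p < α_term (default 0.01) are
assigned to the patient. Downstream contrasts: annotated-patient counts
between two disjoint patient groups (two-sided Fisher by default, since
the contrasts of interest are "differences" without a stated direction),
and variant-class composition between functional and non-functional
mutations of one gene (per-record counting — one patient can contribute
several classes — with per-class class-vs-rest Fisher tests).

### Synergy network

For genes a, b with functional-carrier sets A, B the synergy score is

    s(a, b) = |A ∩ B| / max(|A|, |B|)  ∈ [0, 1]

0 for disjoint carrier sets, 1 exactly when the overlap equals the larger
set. A union numerator (|A ∪ B|, ≥ 1 by construction) is retained as
`literal_union=True` for audit only; as a bounded co-occurrence weight the
intersection form is the one consistent with "synergy = functional
co-occurrence". Edge significance is a one-sided Fisher test of the
observed overlap against independent carrier sets of the same sizes.
Edges require at least `min_shared` = 2 shared functional carriers — one
shared patient is trivially co-occurrence — and the graph (GraphML or
TSV edge list) carries carrier counts as node weights and
(shared, score, p) on edges, with sorted insertion for determinism.

## The synthetic cohort generator

`simulate_cohort` emulates the statistical structure the caller assumes,
with full ground truth. Each of D driver genes owns a disjoint block of
`signature_size` expression features; each patient carries each driver
independently with probability `driver_prevalence`; carriers get the
driver mutation with probability 1 and an additive shift of `effect` on
the driver's signature features over i.i.d. Gaussian noise
(`noise_sd`). Passenger mutations hit every gene independently at
`passenger_rate` with no expression consequence. One designated large
gene (TTN-like) uses `passenger_rate × large_gene_factor`, again with no
expression effect — the canonical length-driven recurrence confounder.
Qualifying event classes are drawn per event (missense 0.70, nonsense
0.12, frame-shift insertion 0.10, frame-shift deletion 0.08 — a
missense-dominated spectrum); silent events are sampled separately at
`silent_rate` and appear only in the record list. An optional
`coupled_pair` correlates two drivers' assignment indicators (bivariate
Bernoulli with P(both) = p² + ρp(1−p)) for co-occurrence/network tests.

Default scenario: N = 300 patients, F = 3000 features, G = 100 genes,
D = 5 drivers, signature_size = 100, effect = 3.0, noise_sd = 0.2,
prevalence = 0.15, passenger_rate = 0.01, large_gene_factor = 17 (large
gene recurrence ≈ 0.17·N, echoing the relative recurrence of the large
muscle-protein gene in real breast-cancer cohorts). The effect/noise
ratio was fixed by Pearson algebra, not by tuning: with 500 of 2000
biomarkers carrying signal, two carriers of the same driver correlate at
≈ 0.9, patients sharing one of two drivers at ≈ 0.62, and unrelated
patients near 0 — so the r ≥ 0.6 rule reconstructs driver cliques the way
strong subtype structure behaves in bulk tumor expression. Baseline
expression is 0 with additive shifts: Pearson correlation is
location/scale free per patient, so absolute levels are irrelevant.

What the generator does *not* emulate: platform/batch noise, correlated
background expression, realistic mutation spectra per gene, probe-level
redundancy, or subclonality. Passing the recovery tests therefore shows
that the implementation is correct and the statistic behaves as designed
*when the model's assumptions hold*, not that the method attains these
operating characteristics on real tumors.

## Numerical choices and degenerate inputs

- Hypergeometric tails come from `scipy.stats.hypergeom.sf` (log-space,
  exact for deep tails); Fisher tests from `scipy.stats.fisher_exact`.
  A chi-square 2×2 helper (`chi2_2x2`, Yates by default) is provided
  because published contingency statistics are often chi-square
  approximations even when labelled "Fisher".
- Percentages in recurrence summaries are rounded to one decimal.
- Biomarker ties on variance and neighbor ties on r break
  lexicographically; all output tables have fixed column order and sorted
  insertion, so identical inputs + seed give byte-identical files.
- Zero-variance patient vectors have undefined correlation: they become
  NaN, are excluded from neighbor candidacy, and trigger a warning.
- Degenerate 2×2 margins (an empty row/column) return p = 1 with a
  warning rather than raising.
- Missing expression values: default policy drops the feature (variance
  ranking is undefined on incomplete rows); per-feature mean imputation
  is available; unparseable garbage is always a hard error naming the
  cell. Duplicate feature or patient identifiers are hard errors.
- Unknown MAF variant classifications map to `other` (not a qualifying
  class) with a logged warning; MAF barcodes collapse to patient level by
  a configurable prefix (default 12 characters).

## Test problem sizes

The suite's heavy checks are sized for a single CPU: the exhaustive
Fisher-vs-enumeration grid covers all 46 371 tables with N ≤ 30; the
permutation cross-check runs 50 random configurations at 20 000 draws;
recovery, null-calibration and determinism checks use the default
300-patient cohort; annotation calibration uses 1000 null pools of 40
genes against a 300-gene background with term sizes 20–40 (sizes chosen
so the exact discrete rejection rates at α = 0.01 sit near 0.009, inside
the [0.005, 0.02] acceptance band, λ ≈ 8–10 expected hits per 1000).

## Known limitations

- Power depends on K and n: private or very rare mutations cannot reach
  p < 0.01 (for K = 1 the bound is p = n/N), and patients without enough
  similar peers are uncallable — the method's stated sensitivity caveat.
- The default focal-inclusive test is anti-conservative for rare genes
  (above); use `include_focal=False` or the BH flag for calibrated
  inference.
- Gene identity is the case-preserved symbol string; no alias resolution,
  no probe-to-gene collapsing (each expression row is an independent
  feature), no CNV handling, and no background-mutation-rate or
  protein-length modeling — recurrence bias from gene length is handled
  implicitly by the expression-neighborhood statistic itself.
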