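# Methods

## Data model and identity conventions

A catalog is a tidy table of donor-level somatic mutation calls
(`donor_id, cancer_type, chromosome, start, ref, alt, consequence, gene`)
plus a roster of enrolled donors per cancer type. Mutation identity is the
exact tuple (chromosome, 1-based start, ref allele, alt allele) on a single
assumed genome build; there is no liftover. Chromosome labels are normalized
(leading `chr` stripped, upper-cased, `M → MT`) so that `chr7` and `7` denote
one mutation. `-` is the empty allele of a pure insertion or deletion.

ICGC-style SSM inputs carry one row per donor × mutation × consequence. We
collapse these to one call per (donor, mutation), keeping the most severe
consequence by a fixed priority list (stop_gained > stop/start_lost >
frameshift > missense > inframe indel > exon > synonymous > splice/UTR >
intron/intergenic). Without this collapse a multi-transcript annotation
would double-count recurrence. Multiple specimens per donor are not modeled;
recurrence counts distinct `donor_id`s only.

National projects of one tumor type (`BRCA-US`, `BRCA-UK`) are merged by
stripping the trailing two-letter country suffix before any statistic is
computed, including the pooled PanCancer scope (`merge_national_projects`
disables this). The default exonic consequence include-list is
missense/synonymous/stop_gained/stop_lost/start_lost/frameshift/inframe
insertion and deletion/exon_variant; it is configurable and echoed in the
run manifest.

**Donor denominators.** Every "fraction of donors" uses the enrollment
roster, not the mutation-bearing donors: cohorts can enroll more donors than
carry passing calls, and a per-donor burden median of ~1 is only possible if
zero-burden donors stay in the denominator. When no manifest is supplied the
roster defaults to the donors observed in calls.

## Recurrence statistics

Recurrence of a mutation is the number of distinct donors carrying it within
a scope (one cancer type, or the pooled PanCancer catalog); *recurrent*
means recurrence ≥ 2. The cohort-overview table reports, per scope, unique
mutations, the recurrent subset with its percentage, and the donors carrying
≥ 1 recurrent mutation with their percentage of the roster. Percentages are
rounded half-up at one decimal — the convention that exactly reproduces
published table cells from their count pairs.

The complementary cumulative distributions over thresholds k = 1..k_max are

* mutation_fraction(k) = |{m : rec(m) ≥ k}| / unique mutations,
* donor_fraction(k) = |{d : d carries some m with rec(m) ≥ k}| / roster size,

both non-increasing in k with mutation_fraction(1) = 1. Re-parameterizing by
mutation fraction (descending k; duplicate x keeps the larger y) yields the
monotone donors-vs-mutations staircase used for fitting.

## Coverage decay model

The staircase is fitted with y = A·x^b by ordinary least squares in
(log x, log y). The two-parameter power law is an interpretation chosen
here, not an established form: it is the minimal monotone family expressing
both fast-saturating regimes (b ≈ 0: a tiny recurrent core covers nearly
everyone) and slow regimes (b ≈ 1: coverage grows with the retained
fraction). Consequences of that choice — and of the unknown error model —
mean fitted parameters from different model families are not comparable;
treat A and b as descriptive.

Numerical choices: points with y = 0 have no logarithm and are excluded from
the regression (counted in `n_excluded`) but retained for interpolation;
fits with fewer than 4 usable points are refused and the scope reported
nonparametrically (small cohorts, below 50 donors by default, are not fitted
at all); the target-coverage estimate interpolates linearly between observed
bracketing points whenever the target is bracketed and only otherwise
inverts the fitted law, clamping to (0, 1].

## Burden summaries

Per-donor burden is the exonic call count per roster donor (zero-burden
donors included by default, flag to drop). Five-number summaries use
median-of-halves quartiles (Tukey hinges: the median splits the sorted
sample, excluding itself at odd n; hinges are the halves' medians) — a fixed,
documented convention since boxplot conventions vary.

## Tumor-type similarity and clustering

From the PanCancer-recurrent mutation set, each cancer type t gets a gene
vector: component g counts distinct donors of t carrying ≥ 1 recurrent
mutation in gene g (donor counted once per gene regardless of how many
recurrent mutations it carries there; calls without a gene label are
excluded and logged; all-zero gene columns dropped). Donor counts — not
binary flags or fractions — are used, and a normalization flag is off by
default. Types are compared by cosine similarity (in [0, 1] for
non-negative vectors) and clustered agglomeratively on distance
1 − similarity.

Average linkage (UPGMA) is implemented in-house with a deterministic
tie-break — among equidistant candidate pairs, the lexicographically
smallest pair of sorted label tuples merges first — so identical inputs give
byte-identical trees; single and complete linkage are available. Newick
output uses the height-halving (ultrametric) convention: a node merged at
height h sits at depth h/2, so the path length between two leaves equals
their merge height. A two-leaf tree merged at 0.2 therefore serializes as
`(A:0.1,B:0.1);`.

## Synthetic catalog generator

The generator emulates the statistical structure the analysis assumes, not
mutational mechanism. Per cohort (cancer type):

* **Burden**: per-donor counts are negative binomial with mean
  `burden_mean` and size `burden_dispersion` (variance μ + μ²/r). The heavy
  tail matters: real cohorts contain hypermutators and medians far below
  means; a Poisson would miss both.
* **Hotspots**: each drawn mutation is, with probability `shared_fraction`,
  a draw from a finite hotspot pool with Zipf popularity weights
  w_i ∝ (i+1)^−s — one skew parameter reproduces the few-mountains /
  many-hills recurrence landscape. Hotspot identity (key, gene, consequence)
  is fixed pool-wide, and cohorts sharing a `pool_label` share the identical
  pool, which is what creates cross-type recurrence and clusterable gene
  vectors. Otherwise the draw is a *private* mutation, collision-free by
  coordinate construction, making the recurrence-1 class exact.
* **Determinism**: all draws derive from a seed via per-cohort
  `SeedSequence` streams; identical (config, seed) gives byte-identical
  catalogs.

Draws are with replacement; a donor re-drawing the same hotspot collapses to
one call. Total calls therefore equal the drawn burden sum only up to these
rare within-donor collisions (exactly, when `shared_fraction = 0`);
`drawn_burdens` replays the burden stream so the bound is testable. This
convention was chosen deliberately because it makes the calibration oracle
exact: hotspot i is included by a donor with probability
p_i = 1 − G(1 − f·q_i), where G is the negative-binomial probability
generating function, f the shared fraction and q_i the Zipf weight; its
recurrence is then Binomial(D, p_i) independently across hotspots'
marginals, and across cohorts sharing a pool the recurrence distribution is
the convolution of the per-cohort binomials. `expected_recurrence_ccd`
computes E[#hotspots with rec ≥ k] exactly (convolution over 0..k_max with
an overflow bin) and reports the expected mutation-fraction CCD under the
ratio-of-expectations convention, with the expected private count
D·μ·(1−f) per cohort in the denominator.

**Presets** (chosen once as realistic regimes): `low-burden` (129 donors,
mean burden 1.6 → median ~1, the chronic-myeloid-disorder regime),
`high-burden` (323 donors, mean 470, dispersion 3 → median ~400, the
melanoma regime), `pan-mini` (six cohorts, 440 donors, one shared pool of
1,500 hotspots with Zipf 0.8 and per-cohort shared fractions 0.06–0.60,
sized so the pooled recurrent fraction lands in the ~1–2% band real
pan-cancer catalogs show), and `pan-large` (eight cohorts, 650 donors,
~10⁶ calls) for end-to-end scale runs. Problem sizes used by the test suite
and the acceptance script (200–650 donors, 10³–10⁶ calls, 20–100 replicates)
were chosen as the smallest scales at which the checked statistics are
stable.

**What passing synthetic tests does not show**: the generator has no
sequence-context signatures, no copy-number or structural variation, no
subclonality, no inter-cohort batch effects, and its hotspot popularity law
is an assumption — agreement on synthetic data validates the statistical
machinery, not any claim about a particular real catalog.

## Pipeline and reproducibility

`run_pipeline` executes ingest/generate → project merge → consequence
filter → cancer-type filter → recurrence summaries (per type + PanCancer) →
coverage curves → fits and target-coverage estimates → burden summaries →
similarity and dendrogram, writing TSVs, Newick, an optional pair of plots,
and a JSON manifest (config echo, versions, seed, per-stage call/donor
counts). A conservation audit asserts that filtering stages never increase
calls or donors and the run aborts, naming the stage, on any failure. Cancer
types are dropped when below `min_mutations` (default 4 — a cohort with 3
mutations supports no recurrence statistic) or `min_donors`; exclusions are
logged so they are auditable.

## Known limitations

* Exact published cohort figures depend on the underlying controlled-access
  catalog and are reproduced only where they are arithmetic consequences of
  printed counts (the percentage cells); headline per-cohort coverage
  estimates additionally depend on the unknown regression form and are out
  of scope.
* The power-law family and the 1 − cosine distance are documented choices,
  not identified from data.
* One genome build is assumed; mixed-build inputs will silently split
  mutations.
* The quadratic-time clustering is intended for tens of cancer types, not
  thousands of leaves.
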