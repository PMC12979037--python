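# Methods

## Natural-abundance correction

A metabolite with `n` tracer atoms is measured as intensities at nominal
mass shifts M+0 … M+n. Naturally occurring heavy isotopes inflate the
higher isotopologues: a molecule carrying `j` tracer-derived labels is
measured at shift `j + Δ`, where `Δ` is the total extra shift drawn
independently per atom from its element's isotopic composition. Collecting
these per-column distributions gives a lower-triangular correction matrix
`M` with `y = M f`:

* **tracer-only mode** (default): column `j` is the distribution of extra
  shifts from the `n − j` unlabeled tracer atoms — a binomial
  `Binom(n − j, a)` for a two-isotope tracer element (`a` = 0.00364 for
  ¹⁵N). Columns sum to 1. This is the right model for high-resolution
  orbitrap data, where e.g. ¹³C and ¹⁵N isotopologues of a nitrogen tracer
  are mass-resolved and the integrated M+i peaks already isolate the
  tracer-element shifts.
* **all-elements mode**: the tracer binomial is additionally convolved with
  the mass-shift distributions of every non-tracer atom in the formula
  (tracer-element atoms beyond the `n` labelable positions count as
  non-tracer atoms). Mass shifts beyond M+n fall outside the measured
  window and are truncated, so columns may sum to < 1. This is the model
  for unit-resolution data — and for this package's simulator, which
  contaminates spectra with all-element natural abundance; all analyses of
  simulated data therefore use all-elements mode.

Isotopic compositions default to IUPAC representative values
(`tracescore._elements.NATURAL_ABUNDANCE`, overridable per run from YAML).
The matrix dimension is capped at 64 isotopologues.

The inverse problem is solved by non-negative least squares rather than
matrix inversion: on noisy data a plain inverse produces negative
fractions, while NNLS returns the closest feasible distribution; on
noiseless data the NNLS solution is the exact inverse (relative residual
~1e−16 in tests). Recovered fractions are renormalized to the simplex;
all-zero measurements are flagged *undetected* and flow through the
pipeline (they must not crash it — real datasets contain "n.d."
metabolites) but raise if queried for enrichment.

## Labeling metrics

Total labeling is `1 − f₀`. The Metabolite Labeling Score divides each
metabolite's total labeling by the reference metabolite's total labeling in
the *same* sample (glutamate for a glutamine tracer; configurable). The
per-sample choice — rather than dividing by a group-mean reference — keeps
replicate variance honest: each replicate's score is a self-contained
ratio, and group comparisons then see the true between-replicate scatter.
Group-mean normalization is available as an option
(`normalization="group-mean"`), as is normalizing to a specific reference
isotopologue (`reference_isotopologue=1` for amide-¹⁵N-only designs).

Quality filters before scoring:

* total labeling strictly > 0 (default threshold 0, configurable);
* pool size ≥ 1% of the sample's median detected-metabolite pool by
  default. "Adequate pool size" is inherently instrument-dependent; the
  fraction-of-median form is scale-free, and an absolute intensity floor is
  available (`pool_size_mode="absolute"`).

Tracer-free samples are never scored — their reference labeling is ~0 and
the ratio is meaningless — they are routed to the QC report, which checks
reference labeling in traced samples (floor 0.05) and median background
labeling in unlabeled samples (ceiling 0.01).

Scores are invariant to rescaling all intensities of a sample by any
constant (units cancel inside fractions), strictly increasing in total
labeling for a fixed reference, and the reference's own score is exactly 1.
Every metabolite × traced-sample pair appears in the score table exactly
once, with `passed_filters` explaining any absent score.

## Differential labeling

Per metabolite with ≥ 2 scored replicates per group: unpaired two-sample
t-test on scores, two-tailed. Welch's unequal-variance form is the default
— the safer choice at n = 3 metabolomics replicates — with the
pooled-variance form available for exact reproduction of classical
analyses. Degenerate inputs are defined rather than NaN: equal means with
zero variance give t = 0, p = 1; unequal means with zero variance give
p = tiny. Significance requires both p < 0.05 and
max(FC, 1/FC) > 1.25 (FC = mean_B/mean_A); p-values are reported raw (the
volcano convention), with Benjamini–Hochberg q-values as an extra column.

A metabolite scored in ≥ 2 replicates of one group but < 2 of the other is
reported as `exclusive_to_A`/`exclusive_to_B` — the structural-zero case
(e.g. GDP-mannose undetected in cell-line monocultures) — with no p-value,
rather than a pseudo-infinite fold change. Fewer than 2 scored replicates
in both groups gives status `filtered`. No silent drops: every metabolite
observed in the two groups' samples yields a row.

Concordance between conditions (e.g. different preconditioning times) is
ordinary least squares of per-metabolite mean total labeling, reporting
Pearson r, r², slope, intercept and the two-tailed slope p-value.

## Quantitative set enrichment

Set statistic: mean over tested members of the squared two-sample
t-statistic between groups — a quadratic association statistic in the
spirit of globaltest-style QEA. The null distribution permutes the sample
group labels jointly across all metabolites, which preserves
inter-metabolite correlation (scores share a per-sample reference
denominator, so independence assumptions would be wrong). Scores enter the
QEA as-is — no additional normalization, filtering or scaling beyond the
score's own filters.

Members must carry a score in every sample of both groups to be tested:
with complete vectors, a permuted split never changes which values exist,
so the permutation null is exact. Incomplete members and set names not
matched to any scored metabolite (matching is case-insensitive, with an
optional synonym map) are reported, never silently dropped; sets with no
testable member get status `untestable`.

When `C(n_A + n_B, n_A) ≤ 10000` all label splits are enumerated and
`p = #{splits with statistic ≥ observed} / #splits` — exact multiples of
`1/#splits`. With equal group sizes each split and its mirror give
identical statistics, so achievable p-values are *even* multiples: at 3 vs 3
the floor is 2/20 = 0.1. Otherwise Monte Carlo with
`p = (1 + #{perm ≥ obs}) / (1 + n_permutations)` (default 9999, seeded,
bit-reproducible).

## Synthetic data

The simulator generates the statistical structure the analysis assumes,
at steady state:

* **Label propagation.** Each metabolite carries `n` nitrogen positions; a
  transfer rule maps each product position to one precursor position (or to
  the unlabeled pool). Positions filled from the same precursor molecule
  stay correlated (a salvaged purine ring keeps its labels together);
  separate draws are independent (two amide transfers use two glutamines).
  Labeling state is propagated in topological order as a joint distribution
  over the 2^n position configurations; cyclic networks are rejected.
* **Fraction-new mixing.** Each pool is a mixture: a fraction
  `f_new × activity(pathway)` was synthesized from labeled precursors
  during the tracing window, the rest is pre-existing unlabeled material.
  This matches a single-timepoint fractional-enrichment snapshot; kinetic
  ODE machinery would add parameters no single-timepoint design can
  identify, so it is deliberately out of scope (no flux estimation).
* **Tracer.** ¹⁵N₂-glutamine labels both nitrogens jointly (pure M+2
  diluted by unlabeled molecules) at enrichment 0.7 by default — a typical
  intracellular glutamine replacement after 24 h of tracing; an
  independent-position mode exists for testing.
* **Measurement.** True distributions are forward-convolved with
  all-element natural abundance, scaled by pool size, and given lognormal
  replicate noise: a shared per-(metabolite, sample) factor with CV =
  `noise_cv` (default 0.10 — typical replicate scatter of integrated LC-MS
  intensities) times independent per-isotopologue factors with CV =
  `noise_cv × 0.3`. The split reflects that isotopologue *ratios* on an
  orbitrap are much more precise than absolute intensities, whose variance
  is dominated by extraction and injection; fully independent per-peak
  noise would overstate fraction-level error severalfold. Metabolites can
  be flagged undetectable per group (intensities 0), and tracer-free
  replicates carry no label.
* **Ground truth** (true fractions, total labeling, glutamate-normalized
  score, differential flags) is always emitted; tests consume the emitted
  truth, never the simulator's internals.

Preset scenarios: `sxo_vs_gsc` — 21 metabolites across amino acid, purine,
pyrimidine, GDP-mannose and urea-cycle pathways; an explant-like group
(purine degradation at 0.3× activity, pyrimidine degradation on, 3 traced +
2 tracer-free replicates) versus a cell-line-like group (purine degradation
1×, pyrimidine degradation off, GDP-mannose not detected, 3 traced
replicates). `null` — identical groups, 5 traced replicates each: group
size chosen from permutation granularity (achievable exhaustive QEA
p-values are even multiples of 1/C(2n, n); n = 5 puts the largest
rejectable p at 6/126 ≈ 0.048, so a 5% level is meaningful, whereas n ≤ 4
makes rejection impossible or vanishingly granular).
`preconditioning_concordance` — identical truth, independent noise (CV
0.05), for regression-concordance checks.

The preset network uses textbook nitrogen atom mappings and round
fraction-new values; it is a pedagogical fixture. What passing tests show:
the pipeline recovers known differential labeling, controls type-I error
and inverts its own measurement model. What they do not show: correctness
of any particular biochemical stoichiometry, chromatographic artifacts,
missing-not-at-random detection, or batch structure — none of which the
simulator emulates.

## Numerical choices and conventions

* NNLS via `scipy.optimize.nnls`; solver residual reported per vector as
  `‖Mx − y‖₂ / ‖y‖₂`.
* Correction matrices are cached per (formula, n, tracer element, mode) for
  the default abundance table.
* Volcano rows sort by p ascending, ties by |log2 FC| descending, then
  metabolite id; enrichment rows by (p, statistic). Stable sorts, so output
  order is deterministic.
* Fold-change direction is B relative to A, taken from argument order and
  recorded in the run manifest.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  (inputs, config, seed) reproduce byte-identical pipeline outputs,
  verified by manifest checksums.
* Metabolite ids join case-sensitively after whitespace trimming in the
  data model; set-membership matching alone is case-insensitive (set
  libraries and LC-MS naming conventions differ).
* Missing isotopologue rows are zero-filled with a logged warning; an
  isotopologue index above M+n or a negative intensity is an error.

## Scale of the shipped checks

The acceptance script and test suite size simulations to their purpose:
200 random molecules for oracle equivalence, 1000 random vectors for noisy
round-trip, 100 simulated studies for differential recovery, 1000 null
simulations for type-I calibration, 10 seeds per noise level for
concordance. These run in about a minute on one CPU while leaving Monte
Carlo error well inside the asserted bands.

## Known limitations

* No resolution-aware partial-overlap correction (only the two discrete
  modes); no carbon-tracer presets, though the data model and correction
  support any tracer element.
* Scores require a detected, labeled reference metabolite in every traced
  sample; datasets violating this fail loudly rather than imputing.
* The QEA complete-case rule ignores sets' partially-missing members when
  computing the statistic (they are listed as untested); with heavy
  missingness the set statistic reflects the complete members only.
* The t-tests assume approximate normality of scores within groups; at
  n = 2–3 replicates the Welch test is conservative rather than exact.
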