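# Methods

## Scope and data model

`singlefiber` analyzes label-free quantification (LFQ) tables from single
dissected skeletal muscle fibers. Two inputs define a dataset: a per-fiber
table of summed unique-peptide intensities for the three adult myosin
heavy chain isoforms (MYH7, MYH2, MYH1) plus a subject id, and a protein
quantification table (proteins × fibers) carrying, per protein, a gene
name, the number of theoretically observable peptides and one summed
peptide intensity per fiber. A stored intensity of 0 is converted to
*missing* on load: in MaxQuant-style LFQ output an absent quantification
is written as 0, and the downstream valid-value logic must distinguish
"not detected" from a true abundance. Missing stays `NaN` throughout; no
value is ever imputed for testing (imputation is used only inside the PCA,
see below).

## Fiber typing

MYH isoform fractions are the isoform's share of the summed
MYH7+MYH2+MYH1 unique-peptide intensity. A fiber is called pure type 1,
2A or 2X when the corresponding fraction is at least the purity threshold
(default 0.8, boundary inclusive — "at least 80%"); otherwise it is a
hybrid and excluded from all group statistics. Only the three adult
isoforms enter the denominator; developmental isoforms are out of scope.
Fractions are scale invariant and the purity filter is monotone in the
threshold (both property-tested).

## Normalization

Relative abundance is computed in two linear-scale steps:

1. iBAQ-style scaling: intensity divided by the number of theoretically
   observable peptides, making values comparable *across proteins*.
2. ACTA1 normalization: each fiber's column divided by that fiber's scaled
   ACTA1 value, cancelling fiber volume differences and making values
   comparable *across fibers*. ACTA1 is located by exact gene-name match
   and must be present in every fiber — it is the denominator, so absence
   is a hard error rather than something to impute. The ACTA1 value used
   as denominator is itself iBAQ-scaled, keeping units consistent; the
   ACTA1 row becomes exactly 1 everywhere.

The operation is idempotent and per-fiber scale invariant: multiplying a
fiber's raw column by any c > 0 changes nothing downstream.

The valid-value filter then keeps a protein iff at least one fiber-type
group has ≥ `min_valid` (default 4) non-missing values. Group membership
counts only pure fibers. The filter is monotone in `min_valid`.

Normalization stays on the linear scale because the pattern ratios and
percent-of-max summaries are defined on linear-scale medians; the log2
transform happens only inside the differential module.

## Differential abundance

Statistics are computed on log2 of the normalized values, missing values
excluded listwise per protein. A type group is usable for a protein when
it has ≥ 2 valid values; a protein is testable when ≥ 2 groups are usable.
Untestable proteins are flagged `NOT_TESTED` (NaN statistics) and excluded
from pattern classification — ANOVA is undefined for them, and no
imputation is attempted.

**ANOVA.** Classical one-way fixed-effects F over the usable groups, with
between-groups df = (usable groups − 1). Zero within-group variance yields
F = +inf (p = 0) for unequal means and F = 0 (p = 1) when all values
coincide. The implementation is vectorized over proteins from per-group
sufficient statistics (counts, sums, sums of squares via one matrix
product each) and is tested to 1e-10 against a brute-force sum-of-squares
oracle. An optional `s0 ≥ 0` (default 0) is added to the within-group mean
square as a variance-stabilizing offset; the default reproduces the plain
F statistic.

**Permutation FDR.** Fiber labels are permuted globally — one permutation
per iteration applied to every protein, preserving group sizes and the
correlation structure between proteins — and all F statistics recomputed
(default 250 permutations, seeded). For a threshold t,

    FDR(t) = [mean over permutations of #{F_perm ≥ t}] / max(1, #{F_obs ≥ t})

and the truncation point t\* is the smallest observed F with
FDR(t) ≤ α (default 0.05); the significant set is every tested protein
with F_obs ≥ t\*, hence an upper set of F by construction. On all-null
data the observed exceedance counts track the permuted ones, FDR(t) stays
near 1 at every attainable threshold, and the significant set is empty for
most seeds — the realized false discovery proportion measured over 20
seeds is far below the nominal α (see `scripts/acceptance.py`). Proteins
that lose testability under a permutation (too many values concentrated in
one group) contribute no permuted statistic for that iteration; the
divisor stays the number of permutations.

**Tukey–Kramer post hoc.** For each tested protein, pairwise p-values from
the studentized range distribution with
q = |x̄_i − x̄_j| / sqrt(MSW/2 · (1/n_i + 1/n_j)), k = number of usable
groups and df = pooled within df; the Kramer form handles the unequal
group sizes (19/29/13 in a typical study). The studentized-range tail
probability is evaluated by direct two-level Gauss–Legendre quadrature of
the classical double integral, vectorized over thousands of q values; it
agrees with `scipy.stats.studentized_range` to ~1e-9 and with a 10^6-draw
Monte-Carlo oracle to < 2e-3 (both asserted in tests), while being ~50×
faster than per-point quadrature at pipeline scale. A pair involving a
group with < 2 values is `NOT_TESTED` (NaN).

**Volcano statistics.** Per pair of types, log2 fold change = difference
of group means of log2 values and a two-sided Welch t-test (unequal
variances, Welch–Satterthwaite df); proteins with < 2 valid values in
either group are omitted.

## Pattern classification

Per-type medians are computed over non-missing linear-scale values; a
group with no valid values has an undefined median. Percent-of-max scales
the medians so the largest defined one is 100. Classification applies the
following rules in precedence order to each FDR-significant protein
(fold threshold f = 3, pairwise α = 0.05; first match wins):

| rule | label | condition |
|------|-------|-----------|
| R1 | type 1-specific | med₁ ≥ f·med₂ₐ and med₁ ≥ f·med₂ₓ, Tukey 1–2A and 1–2X < α |
| R2 | type 2A-specific | symmetric, 2A on top |
| R3 | type 2X-specific | symmetric, 2X on top |
| R4 | type 2-specific | med₂ₐ ≥ f·med₁ and med₂ₓ ≥ f·med₁, Tukey 1–2A and 1–2X < α |
| R5 | type 1/2A-specific | med₁ ≥ f·med₂ₓ and med₂ₐ ≥ f·med₂ₓ, Tukey 1–2X and 2A–2X < α |
| R6 | gradient 1 > 2A > 2X | strict median ordering, Tukey 1–2X < α |
| R7 | gradient 2X > 2A > 1 | strict median ordering, Tukey 1–2X < α |
| R8 | minor | any remaining significant protein (incl. the atypical low-2A shape) |

Specificity precedes the gradients because the taxonomy is disjoint and a
≥ 3-fold specific protein usually also satisfies a gradient ordering. The
3-fold boundary is inclusive ("at least 3-fold"); ratios use linear-scale
medians. An undefined (or zero) denominator median satisfies any fold
ratio provided the numerator group has ≥ 4 valid values — extreme marker
proteins are often entirely absent from the other types, and the
valid-value guard keeps a single stray identification from producing a
marker call. Strict ordering (no ties) was chosen for the gradient rules.
The tabulation reports per-pattern counts, the total of significant
proteins, and a `major_total` over R1+R3+R4+R6+R7 — the five major
patterns; the rare 2A-specific and 1/2A-specific shapes are tabulated but
not counted as major.

The classification is total and disjoint over tested proteins, invariant
to global rescaling of the matrix, and monotone in the fold threshold
(lowering f never loses a specific label) — all property-tested.

## QC: PCA and volcano records

PCA of fibers uses proteins quantified in ≥ 5 fibers of *every* type
(AND over types), with MYH-family rows excluded — they define the grouping
and would dominate trivially. Remaining missing values are imputed from a
per-fiber downshifted normal (mean − 1.8·SD, width 0.3·SD of that fiber's
observed log2 values, seeded), the standard LFQ stand-in for values below
the detection limit; this imputation exists *only* for PCA and never
touches the test statistics. Components come from the SVD of the log2,
per-protein centered matrix; explained-variance fractions are
non-increasing and sum to ≤ 1. Volcano records floor p at 1e-300 so
−log10 p stays finite.

## Synthetic data generator

The generator emulates the structure of a single-fiber study so that every
downstream stage has recoverable ground truth:

- **Fibers.** Defaults 19/29/13 pure type 1/2A/2X fibers (a realistic
  young-adult vastus lateralis sample) plus optional hybrids. Pure fibers
  draw their dominant MYH fraction uniformly in [0.85, 1.0]; hybrids put
  0.45–0.75 on one isoform of an adjacent pair (1–2A or 2A–2X) and the
  rest on the other, so no isoform reaches the 0.8 purity cut.
- **Proteome.** Raw intensity of protein i in fiber f is
  2^(μ[i, type] + ε) · n_pep[i] · s[f] with ε ~ N(0, σ_within) on the log2
  scale (default σ_within = 0.5, a typical LFQ within-group spread),
  per-protein baselines N(base, σ_between) (defaults 14, 2.0, giving a
  broad abundance spectrum below ACTA1), theoretical peptide counts
  uniform in [5, 60], and a per-fiber volume factor s[f] that the ACTA1
  normalization must cancel. Group means μ encode the planted pattern:
  e.g. type 1-specific means (base + log2 fold, base, base); gradients
  place the 2A mean a fraction `grad_mid_fraction` up the log2 span.
  Hybrid fibers draw each value's component type from a categorical
  mixture weighted by their MYH fractions, so the purity filter has
  something meaningful to exclude. ACTA1 (high abundance, never missing)
  and MYH7/2/1 rows (reusing the fiber table's intensities) are always
  present, so the PCA's MYH exclusion rule is exercised.
- **Dropout.** Each cell goes missing with probability
  logistic(intercept − slope · log2 intensity) (defaults 6.0 / 0.45,
  chosen once to give ~10–20% missingness at the default abundance scale,
  concentrated in faint proteins — the left censoring that the
  valid-value filter addresses). Setting slope = 0 and intercept = −inf
  disables dropout exactly.
- **Study-sized default.** `DEFAULT_PATTERN_SPECS` plants 30 type
  1-specific, 41 type 2X-specific and 70 type 2-specific proteins at
  8-fold, and 100 + 81 gradient proteins at a 4-fold extreme ratio with
  the 2A group halfway on the log scale, on a 1,000-protein null
  background. The gradient effect size is deliberately smaller than the
  specific one: with an 8-fold end-to-end ratio at least one adjacent step
  of a three-point gradient necessarily approaches or exceeds 3-fold, and
  the taxonomy would then classify the protein as a specific pattern —
  which is correct behavior, not an error. Real muscle gradients (e.g.
  OXPHOS proteins at roughly 100/77/46 percent of max) are nearer 2-fold
  end to end; a 4-fold extreme with 2-fold steps is a strong but
  taxonomy-consistent gradient, and keeps the planted labels recoverable
  (each step sits ~4 median-SDs below the 3-fold boundary).

All randomness flows from a single seed through named substreams
(fibers, proteome), so identical configurations regenerate bit-identical
datasets; the pipeline seed fans out the same way to the permutation
stage.

## What the synthetic tests do and do not show

Passing the planted-recovery and null-calibration suites shows the
pipeline's algebra, filters and error control behave as specified under a
log2-normal noise model with logistic left-censoring. Real single-fiber
data additionally contain between-subject structure, correlated protein
modules (the generator draws proteins independently), peptide-level
effects folded into LFQ values, and non-logistic missingness; none of
these are simulated, so the tests validate the *method*, not any claim
about a particular biological dataset.

## Numerical choices and degenerate inputs

- F on zero within-variance: +inf with p = 0 (unequal means) or 0 with
  p = 1 (all values equal); both survive TSV round-trips.
- Permutation FDR with no attainable threshold returns an empty
  significant set rather than an error; a single protein with infinite F
  dominates whenever any set passes.
- Tukey with zero pooled variance: p = 1 on exact ties, 0 otherwise.
- Results TSV serializes floats with 12 significant digits (round-trips
  to ~1e-12 relative), missing as empty cells; fiber and protein order are
  never silently permuted on load.
- An empty kept group after the purity filter warns instead of failing;
  downstream statistics simply treat the group as unusable.
- The studentized-range quadrature uses 80 outer × 120 inner
  Gauss–Legendre nodes over u ∈ 1 ± 10/√(2·df) and z ∈ [−8.5, 8.5],
  accurate to ~1e-9 for df ≥ 2 (checked against scipy).

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on synthetic data at
study scale: 61–66 fibers, 10²–10³ proteins for unit/property tests, and
20 × 2,000-protein null proteomes with 250 permutations each for the
calibration experiment — the full suite completes in well under a minute
on one core.

## Known limitations

- No between-subject modelling: fibers are treated as exchangeable
  replicates within type, matching the original fixed-effects design; a
  mixed-effects extension is out of scope.
- The MaxQuant dialect is a best-effort column mapping (`LFQ intensity *`,
  reverse/contaminant flags, optional theoretical-peptide column defaulting
  to 1); exotic proteinGroups variants may need the native format.
- No moderated variance (limma/SAM-style) beyond the optional s0 offset;
  with ~13–29 fibers per group the plain F is adequately powered for
  3-fold effects.
- Hybrid fibers are excluded, not modelled; sub-classifying them is out of
  scope.
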