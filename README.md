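# singlefiber

Fiber-type resolved analysis of single muscle fiber proteomes.

Human skeletal muscle is a mosaic of slow type 1, fast 2A and fast 2X
fibers, defined by their dominant myosin heavy chain isoform (MYH7, MYH2
and MYH1 respectively). Bulk muscle lysates average over this mosaic, so
quantifying which proteins are enriched in which fiber type requires
label-free quantification (LFQ) of *single dissected fibers* and a
statistical pipeline that handles small, unequal groups and abundant
missing values. `singlefiber` implements that pipeline for people working
with single-fiber (or small-pool) muscle proteomics data, from MaxQuant
`proteinGroups.txt`-style tables to a fiber-type pattern inventory, plus a
ground-truth synthetic data generator so every stage can be validated
without raw mass-spectrometry data.

## What it computes

1. **Fiber typing** — per fiber, MYH isoform fractions
   `f_i = I_i / (I_MYH7 + I_MYH2 + I_MYH1)` from unique-peptide intensities;
   fibers with `max f_i >= 0.8` are called pure type 1 / 2A / 2X, the rest
   are hybrids and excluded.
2. **Normalization** — iBAQ-style scaling (summed peptide intensity divided
   by the number of theoretically observable peptides) followed by division
   by each fiber's ACTA1 (α-skeletal actin) value, which cancels fiber
   volume; then a valid-value filter keeping proteins quantified in ≥ 4
   fibers of at least one type group.
3. **Differential abundance** — per protein, one-way ANOVA on log2
   abundances with significance truncation by permutation FDR: fiber labels
   are permuted globally, and for a threshold *t*,
   `FDR(t) = E_perm #{F_perm >= t} / #{F_obs >= t}`; the significant set is
   everything above the smallest observed F with `FDR(t) <= 0.05`.
   Tukey–Kramer post hoc p-values come from the studentized range
   `q = |x̄_i - x̄_j| / sqrt(MSW/2 (1/n_i + 1/n_j))`; Welch tests and log2
   fold changes feed volcano plots.
4. **Pattern classification** — each significant protein is labelled from
   its linear-scale per-type medians: fiber-type specific (≥ 3-fold above
   both other types), type 2-specific, type 1/2A-specific, graded
   `1 > 2A > 2X` / `2X > 2A > 1` (strict ordering with a significant 1 vs 2X
   difference), or minor; medians are also reported as percent of the
   per-protein maximum.
5. **QC** — PCA of fibers (proteins quantified in ≥ 5 fibers of every type,
   MYH rows excluded, downshifted-normal imputation) and volcano tables.

## Worked example

Simulate a study-sized dataset (61 pure fibers: 19 type 1, 29 type 2A, 13
type 2X, plus 5 hybrids; 322 planted pattern proteins on a 1,000-protein
null background with intensity-dependent dropout) and run the full
pipeline:

```python
from singlefiber import PipelineConfig, SimConfig, run_all

result = run_all(PipelineConfig(simulate=SimConfig(seed=7, n_hybrid=5),
                                out_dir="example_out", seed=7))
for pattern, count in result.summary.items():
    print(pattern, count)
```

prints

```
type1_specific 31
type2a_specific 1
type2x_specific 42
type2_specific 70
type1_2a_specific 0
grad_1_2a_2x 102
grad_2x_2a_1 84
minor 7
not_significant 989
not_tested 0
major_total 329
significant_total 337
```

The planted truth was 30 / 41 / 70 / 100 / 81 proteins across the five
major patterns: every planted count is recovered within a few proteins
even with ~10% missing values (the extra type 1- and 2X-specific calls are
the MYH7 and MYH1 marker rows themselves; MYH2 is the lone 2A-specific
protein, as expected for real muscle). The per-protein results table
(`example_out/results.tsv`) carries medians, percent-of-max, F, p, Tukey
p-values and the pattern label, e.g. for the planted type 1 marker
`GENE00001`: medians (2.05e-4, 2.3e-5, 2.5e-5) in ACTA1 units → percent of
max (100, 11, 12), F = 169.5, pattern `type1_specific`.

The same stages are available as a CLI:

```sh
singlefiber simulate --seed 7 --out-dir sim
singlefiber typefibers sim/fibers.tsv --out calls.tsv
singlefiber normalize sim/proteins.tsv calls.tsv --out normalized.tsv
singlefiber diff normalized.tsv calls.tsv --out diff.tsv --seed 7
singlefiber classify normalized.tsv calls.tsv diff.tsv --out results.tsv
singlefiber tabulate results.tsv --out summary.tsv
singlefiber run-all --config config.yaml   # all of the above
```

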