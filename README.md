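# dehop

Estimate and correct **index-hopping contamination** in plate-based
single-cell RNA-seq expression matrices.

When hundreds of dual-indexed (i5 + i7) single-cell cDNA libraries are
pooled on one flow cell, free index primers can re-label fragments from
other wells, so a small fraction of every gene's reads is misassigned
across the pool. In a library containing transcriptionally distinct
cell types this leaves a characteristic fingerprint: signature genes of
one cell type appear at a low, expression-proportional level in cells —
and even in *empty wells* — that cannot express them. `dehop` turns
that fingerprint into a rate estimate and a matrix correction. It is
aimed at anyone analysing deep plate-based (e.g. Smart-seq2) data
sequenced on patterned-flow-cell instruments, where hopping rates are
highest.

## The statistics

For gene *A* in a pooled library of *n*<sub>lib</sub> single cells with
TPM values `TPM`:

- library average: TPM̄<sub>A,lib</sub> = (1/n<sub>lib</sub>) Σᵢ TPMᵢ
- detection ratio of cell *B*: φ<sub>A,B</sub> = TPM<sub>A,B</sub> / TPM̄<sub>A,lib</sub>
- mean detection ratio of cell type *T*: φ̄<sub>A,T</sub> = mean of φ over the cells of *T*
  (equivalently TPM̄<sub>A,T</sub> / TPM̄<sub>A,lib</sub>)

For a gene *not* natively expressed in *T*, φ̄<sub>A,T</sub> measures the
hopped fraction of that gene's library-average expression — the
**index-hopping rate r**. Three estimators are provided:

1. **Rank-curve tangent** — rank all genes increasingly by 1/φ̄ in a
   reference cell type, rescale both axes to [0, 1], and report φ̄ at
   the point where a slope-1 line is tangent to the curve from below
   (computed as argmax(x − y)). Genes detected only through hopping
   pile up near the 1/r ceiling, producing the inflection the tangent
   finds.
2. **Side-population mean** — the mean φ̄ of highly expressed non-self
   marker genes whose detection in the reference type is proportional
   to their library average.
3. **Empty-well sensor** — the median per-gene ratio of empty-well
   average to library average; empty wells carry nothing but
   misassignment.

The correction then replaces each single-cell entry by
`max(0, TPM − r · TPM̄_lib)`.

A built-in simulator generates dual-indexed plate libraries (distinct
cell types, planted markers, empty wells, Poisson-sampled hopped reads
at a known rate, under a library-wide or an index-sharing "pairwise"
contamination model), so every estimator and the correction are
verifiable by parameter recovery.

## Worked example

Simulate a contaminated 384-well pool (true rate 0.65%), estimate, and
correct — from the shell:

```sh
dehop simulate --out-dir demo --seed 1 --n-genes 1500
dehop estimate --matrix demo/matrix.tsv --wells demo/wells.tsv \
               --markers demo/markers.tsv --method all --out report.json
dehop correct  --matrix demo/matrix.tsv --wells demo/wells.tsv \
               --rate 0.0065 --out corrected.tsv
```

The estimate report (seed 1) contains:

```
rank_tangent          0.004633
side_population_mean  0.006608
empty_well            0.006585
consistency           1.426
```

i.e. the side-population and empty-well estimators recover the planted
0.65% rate to ~1.5%, and the rank tangent lands within a factor of 1.5
(it reads the noisy lower edge of the hopping floor, so it runs a
little low). The same pipeline from Python:

```python
from dehop import (SimConfig, simulate, compute_ratios, identify_side_population,
                   estimate_rate_side_population, correct, most_abundant_type)

truth = simulate(SimConfig(seed=1))                 # 5000 genes x 384 wells
ratios = compute_ratios(truth.contaminated, truth.wells, pool_id="pool1")
ref = most_abundant_type(truth.wells)               # 'MC'
side = identify_side_population(ratios, truth.markers, ref)
est = estimate_rate_side_population(ratios, side)   # est.rate ~ 0.0066
fixed = correct(truth.contaminated, truth.wells, est.rate)
```

After correcting at the estimated rate, the side population's mean
detection ratio drops to under 10% of its pre-correction value and
within-type cell-to-cell Spearman distances increase — contamination
had made distinct cells look artificially similar.

## Layout

| module | contents |
|---|---|
| `dehop.io` | TSV / MatrixMarket matrices, well metadata, marker tables, alignment |
| `dehop.layout` | dual / i7-only / i5-only / none hop-potential classification |
| `dehop.ratios` | library & type averages, φ and φ̄ |
| `dehop.rate` | rank-curve tangent, side-population and empty-well estimators |
| `dehop.correction` | subtraction correction and before/after reports |
| `dehop.simulate` | plate-library simulator with known contamination |
| `dehop.diagnostics` | marker selection, Spearman cell distances, panel tables |
| `dehop.cli` | `dehop simulate / estimate / correct / diagnose` |

Method details, parameter defaults and known limitations are in
[docs/methods.md](docs/methods.md).
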