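# ctpos

Quantitative analysis of chromosome-territory positioning in the interphase
nucleus from 3D-FISH confocal stacks, with the matching expression-side
statistics — built for studies that ask whether perturbations (e.g. nuclear
lamin depletion) move chromosomes, change their copy number, or deregulate
their genes.

Chromosome territories (CTs) occupy preferred radial positions: gene-rich
chromosomes sit toward the nuclear interior, gene-poor ones toward the
periphery. This package measures that organization and its statistics:

- **% radial distance (%RD).** With *A* the geometric center of the
  DAPI-stained nucleus and *B* the geometric center of a painted territory,
  the ray *A→B* is extended to the collinear point *C* where it crosses the
  nuclear periphery. With *X* = |AB| and *Y* = |AC|,

  ```
  %RD = (X / Y) × 100        (0 = nuclear center, 100 = periphery)
  ```

  %RD values are binned into five concentric sub-shells of 20 % each
  (I innermost … V peripheral, upper-inclusive, so %RD 60 → shell III and
  %RD 80 → shell IV).
- **Locus-to-lamina distance.** The closest Euclidean distance between a
  gene locus' center of mass and the surface of a lamina anchor mask, in μm.
- **Interphase ploidy.** Copy number per nucleus = number of segmented
  territory objects in a paint channel; 2 = diploid, >2 = aneuploid gain,
  <2 = loss. Metaphase spreads classify as 45–46 pseudo-diploid, <45 loss,
  >46 gain.
- **Per-chromosome deregulation burden.** From a knockdown-vs-control gene
  table, genes with |fold change| ≥ 2.0 (inclusive) and p < 0.05 (strict)
  are deregulated, and per chromosome

  ```
  % deregulation = 100 × (deregulated genes on chromosome)
                        / (coding genes on chromosome)
  ```

  with chromosomes above a strict 0.7 % cut called significant, plus the
  OLS r² of % deregulation against gene density (genes/Mbp).
- **Condition-level tests.** χ² and per-shell Fisher's exact tests for
  shell distributions, two-sample Kolmogorov–Smirnov for raw distance
  distributions, Kruskal–Wallis for volumes across shells; medians and
  IQRs reported throughout.

Because raw confocal stacks for such studies are rarely deposited, the
package ships a first-class synthetic-data generator: ellipsoidal nuclei
with territories planted at known fractional radial positions and copy
numbers, rendered through a Gaussian PSF with Poisson shot noise and
Gaussian read noise onto anisotropic voxel grids (default 0.105 × 0.105 ×
0.34 μm, 8-bit), plus expression tables with exact planted per-chromosome
deregulation. Every measurement is validated against this planted truth.

## Worked example

```python
import numpy as np
from ctpos.synthetic_data import AcquisitionSpec, CohortSpec, CohortChromosome
from ctpos.pipeline import PositioningConfig, run_positioning, compare_shell_tables

control = CohortSpec(
    n_cells=25,
    chromosomes=[
        CohortChromosome("CT18", rd_low=0.65, rd_high=0.90),  # peripheral
        CohortChromosome("CT19", rd_low=0.45, rd_high=0.65),  # interior
    ],
    acq=AcquisitionSpec(), seed=101,
)
report = run_positioning(PositioningConfig(condition="control", cohort=control, seed=101))
print(report.median_iqr_table)
```

Running the full contrast in `analysis/02_territory_positioning.py`
(control vs a knockdown cohort in which CT19 gains copies in 30 % of cells
and its planted positions drift outward) prints:

```
== control: 25 nuclei, 100 territories ==
chromosome stratum  n  median_rd    iqr_rd
      CT18  pooled 50  77.578938 13.052991
      CT19  pooled 50  54.209590 11.716897
ploidy: {'CT18': 0.0, 'CT19': 0.0}

== knockdown: 25 nuclei, 107 territories ==
      CT19    pooled 57  68.508702 12.892471
ploidy: {'CT18': 0.0, 'CT19': 28.0}

CT18: chi2 p = 1.0000 -> conserved
CT19: chi2 p = 0.0000 -> shifted
```

i.e. the gene-poor CT18 keeps its peripheral median (%RD ≈ 78, shell IV),
the planted 30 % CT19 gain is recovered as 28 % of nuclei, and the planted
outward shift of CT19 (median %RD 54 → 69) is detected by the 2×5 χ² shell
test while CT18's distribution is unchanged.

The other drivers follow the same pattern: `analysis/01_simulate_demo_cell.py`
round-trips one fully annotated cell through TIFF I/O and re-measures every
planted quantity, `analysis/03_ploidy_and_volumes.py` recovers a planted
30 % aneuploid-gain fraction exactly and shows territory volumes do not
vary across sub-shells when no trend is planted, and
`analysis/04_expression_deregulation.py` contrasts a density-biased with a
uniform knockdown (r² = 0.986 vs 0.059 against gene density).

## Layout

```
src/ctpos/          library: imaging_io, synthetic_data, segmentation,
                    geometry, population_stats, expression, pipeline,
                    validation, reference
analysis/           numbered narrative drivers (01–04) writing results/
tests/              pytest suite incl. end-to-end recovery tests
scripts/acceptance.py   results-reproduction script
docs/methods.md     methods note: models, conventions, limitations
```
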