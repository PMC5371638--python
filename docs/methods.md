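# Methods

## Coordinate and calibration conventions

Arrays are indexed `(Z, Y, X)`, voxel indices are 0-based, and the physical
coordinate of voxel `(k, j, i)` is `(k·vz, j·vy, i·vx)` μm — physical
coordinates are voxel centers. All geometry (placement, distances, ray
marching) is computed in physical μm so the anisotropic calibration is
honored throughout; rasterization happens last. The default calibration is
0.105 × 0.105 × 0.34 μm (x, y, z) with 8-bit channels, matching a 63×/1.4 NA
confocal acquisition; both are configurable per
`AcquisitionSpec`/`VoxelImage`. TIFF voxel sizes are read from ImageJ-style
tags (and OME-XML when present) and written ImageJ-style.

## Percent radial distance

For each territory, A is the unweighted centroid of the filled nucleus mask
("geometric center"), B the centroid of the territory object. The ray A→B
is marched at a step of 0.25 × min(voxel dimension); the periphery point C
is the midpoint of the last sample inside the mask and the first sample
outside it. This sub-voxel construction is cheaper than an isosurface and
accurate to roughly half a voxel (~0.13 μm at default calibration in xy).
%RD = 100·|AB|/|AC|, clamped to [0, 100]: with a noisy mask a segmented
territory centroid can land marginally outside the nucleus, which would
otherwise produce %RD > 100. Degenerate B = A (within 1e-9 μm) returns
%RD = 0 with C undefined. A nucleus mask that touches the image border is
an error rather than a silent truncation. Whether the original
surface-rendering software found C on a rendered isosurface or a binary
mask edge is not determinable; the mask-edge dialect used here is
documented and tested (rotation invariance < 1 %RD point; recovery of
planted positions to < 3 points mean error, in practice ~0.7).

Shells are upper-inclusive 20 %-bins: shell k covers ((k−1)·20, k·20], with
%RD 0 in shell I — forced by the labeling that places %RD ~60 in shell III
and ~80 in shell IV. Every territory copy in an aneuploid nucleus is
measured independently and pooled, so the distribution unit is the
territory, not the cell.

## Segmentation

Otsu is the default threshold (a fixed value is available and logged; the
comparison is inclusive, foreground = intensity ≥ t). Connectivity is
26-connected in 3D. Components under `min_voxels` (default 50, ~0.2 μm³ at
default calibration) are dropped to suppress hybridization speckle. The
nucleus is the largest component with holes filled slice-wise and in 3D
before measurement, since uneven DAPI staining otherwise biases the
geometric center and volume; whether the original analysis filled holes is
unknown, so the choice is documented here. Nuclei and territories are
summarized by the unweighted centroid, gene-locus spots by the
intensity-weighted center of mass — mirroring the field's distinct usage
("geometric center" vs "center of mass"); the two coincide exactly on
uniform objects.

## Lamina distance

The anchor surface is the set of anchor-mask voxels with at least one of
six face-neighbors outside the mask; the reported distance is the minimum
Euclidean distance from the locus CM to those voxel centers, which equals
the exhaustive search by construction (verified exactly in tests). The
discretization error of this estimator is one-sided and bounded by the
largest voxel dimension when the CM lies inside the anchor's cavity; for a
lamina rim enclosing the nucleus the measured distance slightly overshoots
the true boundary distance (by well under half a voxel diagonal in the
tested configurations) because all rim voxels lie beyond the boundary.

## Statistics

Shell distributions are compared both ways the field uses: a 2×5 χ²
contingency test (shells empty in both conditions dropped with a warning)
and five per-shell 2×2 Fisher's exact tests; both are always reported and
disagreement is flagged, since neither test is canonical for this
comparison. Identical distributions short-circuit to χ² = 0, p = 1. Raw
distance distributions use the two-sample KS test (≥ 5 samples per group);
volumes across shells use Kruskal–Wallis, implemented in-package with
midranks and tie correction against a χ² reference distribution and
cross-checked against an independent implementation to 1e-9. Medians and
IQRs (Q3 − Q1, linear-interpolation quantiles) are reported per condition.
Raw p-values are reported; a Benjamini–Hochberg adjustment exists but
defaults off, matching the reporting style of small-panel imaging studies.

Null calibration: randomly splitting a pooled shell sample (n = 200, a
realistic interior-weighted profile) into halves and testing rejects at
3.5–5.5 % across seeds at nominal 5 %. KS power for a planted lognormal
median shift 0.72 → 1.40 μm at n = 60/group is ~100 %.

## Synthetic data

The generator emulates what the measurements need, not optics in detail:

- **Nucleus**: a convex ellipsoid (semi-axes ~3.2 × 5.5 × 5.0 μm, ±8 %
  jitter, random orientation), auto-fitted into a field with ≥ 2-voxel
  margin. Convexity keeps the ray-exit construction unambiguous. Real
  lamin-depleted nuclei show invaginations and blebs; such non-convex
  shapes are not modeled, so tests validate the measurement chain, not its
  robustness to pathological nuclear shape.
- **Territories**: spherical blobs whose rasterized volume is tuned to the
  target (default 3 μm³, the scale of measured CT volumes) within 2–5 %;
  the centroid is planted at `fractional_rd` × (center-to-surface distance
  along a direction), the exact quantity %RD estimates. Copy number is the
  number of planted blobs per channel; cohort placement enforces a physical
  separation of one blob diameter + 0.7 μm where the nucleus allows it, so
  copies stay resolvable (closely apposed homologs merge, as in real data).
- **Lamina**: the shell between the nucleus ellipsoid and a version shrunk
  by the rim thickness (default 0.4 μm). **Loci**: isotropic Gaussian spots
  (σ 0.25 μm).
- **Acquisition**: Gaussian PSF (σ default 0.1 μm xy / 0.25 μm z), Poisson
  shot noise at `photon_scale` (default 180) plus Gaussian read noise
  (SD 2), quantized to 8 or 16 bits. The real detector is uncharacterized;
  defaults were chosen so Otsu segmentation recovers planted objects
  essentially completely. Identical seeds give bit-identical stacks.
- **Expression tables**: per chromosome, exactly
  `round(fraction/100 × coding_genes)` genes receive |FC| ≥ 2 (2 + an
  exponential tail) and p < 0.05 (uniform on [1e-6, 0.05)); all other genes
  draw |FC| from [1.05, 1.85] and so fail the fold-change cutoff regardless
  of p. The paired-knockdown helper plants an exact overlap between two
  deregulated id sets over one gene universe. Locus distances are simulated
  lognormal (σ_log 0.55) with a specified median, matching the skewed,
  non-negative shape of such measurements.

What passing tests show: the measurement chain recovers planted geometry,
copy number and deregulation under realistic noise at the study's
calibration. What they do not show: robustness to non-convex nuclei,
spectral bleed-through, hybridization variability, or segmentation of
touching nuclei (fields are single-nucleus by design).

## Problem sizes and numerical choices

Validation experiments run at study scale: 100 cells for %RD recovery
(planted positions U(0.05, 0.95)), 100 nuclei with an exactly planted 30 %
gain fraction for ploidy, 200 replicates for null calibration and KS power,
60 loci per group. Ray-march step 0.25 × min voxel; territory-volume tuning
tolerance 2 % with up to 20 radius iterations; Otsu's strictly-greater cut
converted to the next occupied intensity level so the package-wide
inclusive ≥ convention preserves the same partition; ploidy/metaphase class
boundaries and the 0.7 % deregulation cut are strict as specified by their
definitions and boundary-tested.

## Default annotation

`ctpos.reference.default_annotation()` bundles an approximate 24-chromosome
annotation (MapViewer-era gene counts). Densities for chromosomes 1, 11,
16, 17, 18, 19 follow published values for this assay context; the rest are
approximate and intended for simulation defaults only — real analyses
should supply their own annotation TSV.

## Known limitations

- The ellipsoid nucleus omits the low-order surface perturbations seen in
  lamin-depleted cells; the ray construction would remain valid for mildly
  non-convex shapes but C would be the first exit point.
- No equal-volume erosion-shell variant is provided (shells are
  equal-radius percentage bins by design); no 2D projection mode.
- Proprietary microscope formats (LSM/CZI) are out of scope — convert to
  TIFF first.
- Fold changes are declared linear in the schema; log2 inputs must be
  converted upstream.
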