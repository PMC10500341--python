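# Methods

`cinquant` quantifies chromosomal instability (CIN) from fixed-cell 3D
fluorescence imaging of interphase nuclei.  The readout is the per-nucleus
count of CENP-A centromere spots — a proxy for chromosome number in G1 — plus
the rate of micronuclei (MN) per 100 cells.  This note describes the models,
the parameters that matter, the synthetic-data generator the tests run
against, and the numerical choices made where the design was open.

## Processing model

Stages run in a fixed order; each nucleus or field excluded along the way
carries a machine-readable reason, and the QC report balances exactly
(`n_input = n_retained + Σ exclusions`).

1. **Entropy field filter.**  Fields without cells are rejected when the
   Shannon entropy of the DAPI max-projection histogram falls below a
   threshold (bits).  Histogram bins have fixed width (one camera count), so
   the entropy reflects absolute dynamic range: a noise-only field scores
   ~5–6 bits, a field with chromatin ~7 bits.  The threshold is a config
   parameter; `calibrate_entropy_threshold` sets it to the midpoint between
   the two populations on labelled fields.

2. **Nuclei segmentation.**  A per-pixel foreground probability is estimated
   classically: the DAPI max-projection is Gaussian-smoothed (σ = 2 px),
   passed through a logistic centred on an Otsu threshold, binarised at 0.5
   (ties are foreground), then hole-filled, opened (disk radius 2) and
   filtered to ≥ 500 px.  Interphase nuclei are flat, so segmentation is 2D
   and labels are broadcast across z for 3D work.  A guard rejects fields
   whose Otsu threshold is within 5 robust SDs of the background median
   (Otsu would otherwise split pure noise).  The segmenter sits behind a
   plain function interface so a learned model producing the same
   probability map could be swapped in.

3. **Segment filtering.**  Segments touching the xy field border are
   excluded (`edge`).  Remaining segments are classified keep/discard by a
   LightGBM gradient-boosted tree over seven morphological features (volume,
   equal-volume-ball diameter, extent, principal axis lengths, convex
   volume, solidity, exposed-voxel-face surface area; all in voxel units).
   Training data come from the synthetic generator with ground-truth labels
   (single nucleus vs debris vs unresolved touching pair).  A rule-based
   fallback filter (volume window + solidity ≥ 0.92) is used when no trained
   classifier is supplied.

4. **Cell-cycle filters.**  S-phase nuclei are excluded when the mean EdU
   intensity within the projected segment mask exceeds a threshold on the
   channel's intensity scale (default 300 for the synthetic conditions,
   which separate EdU-positive ≈ 590 from negative ≈ 125).  Late-S/G2
   nuclei — EdU-negative but with replicated centromeres — are excluded when
   more than 20 sister-chromatid pairs are found: pairs are disjoint spot
   pairs closer than 0.8 μm (about the rest length of a sister pair),
   matched greedily in ascending distance order with lexicographic
   tie-breaks.  Greedy matching is deterministic, cannot double-count a
   centromere, and agrees with exhaustive maximum-cardinality matching on
   nucleus-scale point configurations (checked against a brute-force
   oracle).  The boundary is strict: 20 pairs is retained, 21 excluded.

5. **Centromere counting.**  Within the convex hull of each segment:
   candidate point sources are 3D local maxima (26-connectivity, plateau
   ties to the lowest lexicographic index) brighter than a robust background
   estimate plus 5 robust SDs.  "Robust" is median and 1.4826·MAD
   throughout.  Candidates are fitted with 3D Gaussian PSF models by
   least squares (analytic Jacobian, Levenberg–Marquardt) in a local window
   of half-width 3σ per axis — first with free per-axis widths to estimate
   the PSF size (median over fits), then refitted at that fixed size to
   extract amplitudes.  Failed fits (non-convergence, non-positive
   amplitude, drift out of window, implausible width) are dropped with a
   logged reason.  The amplitude distribution is modelled with a Gaussian
   mixture of 1–4 components selected by BIC; the smallest-mean component is
   the single-centromere intensity standard.  Spot multiplicity is
   `round(amplitude / standard)` (half away from zero), clipped to 1–4; the
   nucleus count is the sum of multiplicities.  The count is invariant under
   global intensity rescaling because amplitudes and standard scale
   together.  The mixture is fitted per nucleus by default (pooled mode is
   available; a nucleus with < 8 spots falls back to one component).

6. **Micronuclei.**  On the DAPI max-projection, connected components
   brighter than background median + 10·MAD, outside the nucleus masks
   dilated by 5 px (soft nuclear rims bleed past the 0.5 probability cut),
   with projected area 0.5–12 μm² and within 8 μm of a retained nucleus,
   are counted as MN.  The rate is `100 · MN / retained nuclei`.  The
   detector is a classical stand-in behind a one-function interface; a
   learned counter honouring the same contract could replace it.

## Statistics

A condition's counts are summarised by a Gaussian KDE evaluated as an exact
kernel sum over the integer count histogram (needed because the statistic is
recomputed ~10⁵ times inside resampling loops; it agrees with
`scipy.stats.gaussian_kde` to machine precision at equal bandwidth).
Bandwidth is Silverman's rule floored at 0.8 counts — the floor prevents
integer spacing from inducing spurious multimodality, at the cost of adding
0.8² in quadrature to the density's variance.  Reported measures:

- **mode** — grid argmax of the density (0.1-count grid, ties to the lowest
  count, snapped to the nearest integer);
- **FWHM** — distance between the outermost half-maximum crossings, linearly
  interpolated; with multimodal densities this measures overall spread;
- **modal-deviation fraction** — share of nuclei with |count − mode| > 2,
  a direct tally (exact, no density involved);
- **MN per 100 cells**.

Inference between conditions: two-sided nucleus-level permutation tests
(default 10,000 permutations) for FWHM and deviation fraction, with the
add-one correction p = (1 + #{|T_perm| ≥ |T_obs|}) / (n_perm + 1) so p > 0
always; percentile-bootstrap CIs (default 1,000 resamples); and a two-tailed
unpaired t-test across replicate-level MN rates (the one parametric test
kept, because MN rates are replicate-level means).  Permutation p-values are
reported raw; an optional Benjamini–Hochberg column exists but is off by
default.  The permutation unit is the nucleus; replicate-level shuffling is
not implemented.

## Synthetic assay generator

`synth.generate_field` renders calibrated three-channel stacks (DAPI,
CENP-A, EdU), default 17 × 0.5 μm z-planes and 0.1 μm xy pixels, with
per-spot/per-nucleus ground truth.  What it emulates, with defaults:

- **Nuclei**: flattened ellipsoids (z semi-axis 1.6 μm, in-plane semi-axis
  4.5 μm ± 8%), soft-edged, ~4 per 32 μm field.  G2 nuclei are drawn 25%
  larger in-plane.
- **Centromeres**: 46 per nucleus (configurable ploidy distribution),
  rendered as 3D Gaussians with the PSF σ = (0.4, 0.15, 0.15) μm (z, y, x)
  and single-centromere amplitude ~N(1000, (10%)²) counts.
  `superimposed_fraction` (default 0.1) is the fraction of centromeres
  residing in co-located pairs: a nucleus holds Binomial(23, 0.1) double
  positions rendered as two unit spots at the same coordinate, so ~43.7
  distinct positions carry 46 centromeres.  An optional sub-PSF jitter can
  displace the two members.  Other spots are kept mutually resolvable
  (≥ 0.45 μm in-plane or ≥ 1.1 μm axially, and ≥ 0.9 μm in 3D so chance
  G1 pairs stay above the 0.8 μm pairing cutoff); spatial placement is
  uniform in the nuclear ellipsoid, since the true spatial statistics of
  interphase centromeres are not modelled.
- **Cell cycle**: a configurable fraction of nuclei are EdU-positive
  (S phase, default 0.3); a fraction of the rest are G2, rendered as 46
  sister pairs separated by 0.4–0.75 μm, oriented mostly in-plane.
- **Micronuclei**: spheroids of radius 0.6–1.0 μm placed 1.5–4 μm from a
  nucleus rim, at `mn_rate` per 100 nuclei (Poisson per field).
- **Debris and merged nuclei**: irregular unions of dim flat ellipsoids, and
  nuclei placed touching a neighbour, for classifier training.
- **Noise**: Poisson shot noise in its Gaussian approximation (exact to
  < 1% at the ≥ 100-count background) plus additive Gaussian read noise
  (σ = 10).

Determinism: every stochastic draw flows from one master seed through named
`SeedSequence` substreams; identical seed + config gives bit-identical
images, ground truth and pipeline outputs.

`synth.generate_condition` is the count-level model for the statistics
layer: each chromosome of a nucleus independently gains or loses one copy
with probability r/2 each (r = the mis-segregation rate), so the count
variance is 46·r and the distribution widens monotonically in r while the
mode stays at the base ploidy; per-field MN counts are Poisson.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: optical aberrations and chromatic shift, intensity
variation across the field, chromatin texture inside nuclei, clustered (non-
uniform) centromere placement, partially-overlapping (rather than
co-located) spot pairs at sub-PSF distances, apoptotic/mitotic morphologies,
and CENP-A level variation between cells.  Detection and counting on real
images will degrade relative to these benchmarks, particularly where true
spot spacing falls below the resolvability floor the generator enforces.

## Numerical choices and degenerate inputs

- Voxel index i maps to physical coordinate (i + 0.5)·spacing (voxel
  centres); all distances are Euclidean in μm with per-axis spacing, so z
  anisotropy is respected.
- Candidates closer than one voxel (Chebyshev) are deduplicated before
  fitting; duplicate candidates produce identical fits.
- A constant volume yields background (c, 0) and is flagged; an empty count
  set raises; all-equal counts give a delta-like KDE (mode at the value,
  zero deviation fraction, FWHM = 2.355 × bandwidth floor) and zero-width
  bootstrap intervals, flagged in the log.
- A permutation draw on which the statistic is undefined is redrawn and
  logged; p-values are never exactly 0 by construction.
- BIC ties prefer fewer components; mixture fits use a data-scaled
  covariance floor so identical amplitudes remain fittable.
- GMM initialisation is k-means with a fixed seed, so model selection is
  deterministic.

## Benchmark problem sizes

The bundled benchmarks use sizes chosen to give stable estimates at
interactive runtimes: 500 nuclei for count recovery, 200–500 fields for the
MN detector, 500 null repetitions (500 permutations each) for test
calibration, 300 simulated datasets (1,000 resamples) for bootstrap
coverage, and 2,000 nuclei per condition for the dose–response simulation.
FWHM point checks average 10 independent draws of n = 5,000 because a
single draw's KDE-FWHM has a sampling SD of ~0.3 counts.  Test calibration
uses the FWHM statistic (effectively continuous, so permutation p-values are
near-exact); the deviation fraction is heavily tied across permutations,
which makes its permutation p conservative.  Coverage simulations draw from
the package's own mis-segregation count model, whose modal-deviation truth
is computable exactly by convolving the two binomials.

## Known limitations

- The G2 filter depends on resolving both members of most sister pairs; in
  very small or unusually crowded nuclei, pair merging at detection can
  leak a G2 cell through the filter with an inflated count.
- The classical MN detector assumes MN are bright, compact and separated
  from the nuclear rim by more than the exclusion dilation; blebs touching
  the rim are deliberately not counted.
- Counting accuracy degrades when more than ~4 centromeres superimpose at
  one position (multiplicity is capped at the mixture's maximum component
  count).
- The segment classifier is trained on synthetic morphologies; applying it
  to real data requires retraining on labelled real segments.
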