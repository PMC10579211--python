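# Methods

## What is being modeled

The study question is how the penalization factor β of BSREM's relative
difference penalty (RDP) moves the noise/recovery operating point of PET
reconstruction, relative to routine OSEM, as a function of lesion size and
lesion-to-background ratio (LBR).  The package answers it in silico: a
digital NEMA IEC body phantom is projected, corrupted with Poisson counting
noise, reconstructed six ways (BSREM at β = 100…500, OSEM), and read out
with the standard NEMA analysis.  A packaged 45-lesion clinical SUVmax table
(27 lesions ≤ 10 mm, 18 lesions > 10 mm; 15 primary rectal tumors, 12 lung
and 18 pelvic metastases, each measured under the same six reconstructions)
carries the clinical arm; all clinical numbers flow from that CSV.

## Phantom

* Interior volume 9780 ml over a 194 mm height.  The body cross-section is a
  half-ellipse over a rectangle, uniformly scaled so the analytic volume is
  exact; only the volume, not the outline, enters the metrics.  Voxelized
  volume is within 1.2% of nominal at 2 mm spacing.
* Six spheres (10, 13, 17, 22, 28, 37 mm inner diameter) on a 57.2 mm ring
  at 60° increments in one transverse plane, the largest spheres in the
  upper half where background clearance is widest.  The standard ring radius
  and layout are used because the phantom unit's drawings are not published;
  both are configurable.
* Cold lung insert: 50 mm diameter cylinder at zero activity (the physical
  insert's diameter is not published; 50 mm follows the NEMA standard and is
  configurable).
* Background concentrations 5.1 / 4.9 / 5.0 kBq/ml at LBR 2:1 / 4:1 / 8:1,
  matching the study's filling scheme; sphere truth = background × LBR.
* Voxels take the label of their center point.  This biases sphere volumes
  by up to a few percent at 2 mm spacing and is why volume-error convergence
  is tested over two halvings (error oscillates under a single halving).

## Acquisition model

2-D parallel-beam projection per transverse slice (192 angles over π,
2.5 mm radial bins), radial Gaussian PSF of 4.5 mm FWHM in the projection
domain, and independent Poisson noise after rescaling the expectation to
2×10⁵ counts per slice.  The count level is a tuning default chosen to put
OSEM background variability in the qualitatively reported 5–15% band (it
lands at the top of it); it stands in for acquisition duration.  No
attenuation, scatter, randoms, or time-of-flight: the scanner being emulated
is non-TOF, and these corrections are orthogonal to the penalty-strength
question.  The projector is pixel-driven with linear interpolation; its
adjoint uses identical weights (exact to machine precision), which EM-type
updates require.  Pixel-driven deposition shows high-frequency ripple at
resonant angles (e.g. 45°); its local average and integrals are accurate,
and in practice the PSF blur suppresses the ripple.

## Reconstruction

* **OSEM** (routine protocol): 4 iterations × 24 subsets, PSF modeling as a
  self-adjoint image-space Gaussian (zero-padded boundary), 4.8 mm Gaussian
  post-filter.  Incompletely converged by design, like the clinical default.
* **BSREM**: 25 iterations × 12 subsets on L(x) − β·U(x), preconditioner
  x/s_m, relaxation αₙ = 1/(1 + 0.1 n), nonnegativity by projection.  The
  relaxation schedule is a stability choice (the source protocol does not
  publish one); the objective is verified non-decreasing on noiseless
  instances, and a non-finite or repeatedly decreasing objective aborts with
  a diagnostic.  With β = 0 and unit relaxation the update is algebraically
  OSEM — a tested identity.
* **RDP**: γ = 2 (the value published for the commercial implementation),
  ε = 1e−9 guarding 0/0, inverse-distance weights over the 8-neighborhood
  (2-D) / 26-neighborhood (3-D), each pair counted once in the value.
* **β scale**: this simulator's penalty is not numerically commensurate with
  the vendor's 100–500 scale.  The familiar labels are kept and multiplied
  internally by a single calibration constant `BETA_CALIBRATION = 0.013`,
  chosen once so that β = 300 matches OSEM background noise on the default
  LBR 4:1 phantom — the operating point at which the two protocols are
  conventionally compared (measured BV 16.7% vs 16.9% at calibration time).
  The constant is recorded in every result's metadata.  β-dependent *trends*
  are meaningful; absolute correspondence to vendor β values is not claimed.

## Read-out

Sixty 10 mm background ROIs — 12 per slice on the central sphere slice and
two slices either side — each ≥ 15 mm from every sphere surface and from the
phantom edge, placed deterministically (fixed 30° angular template offset
15° from the sphere ring, greedy inward radius search).  The ROI diameter
follows the methods text (10 mm); the alternative 5 mm reading that appears
in figure material is available as `roi_diameter_mm`.  One VOI per sphere
with the sphere's physical diameter, centered on truth.  Lung error uses a
30 mm ROI at the lung center.  Population SD (ddof = 0) everywhere; the
background mean C_B is the mean of per-ROI means (the per-ROI/pooled
convention is not published; this is the NEMA convention).  The phantom
"SUVmax" analog is VOI max / true background concentration, so the ideal
hot-sphere value equals the LBR — no body-weight normalization exists in a
phantom.

**Replicate slices.**  The sweep runs in a 2-D fast mode (128×128 at
2.5 mm).  A single slice gives only 12 ROIs and a 12-pixel 10 mm VOI, far
noisier than the 60-ROI/3-D-VOI read-out the metrics are defined for, so the
pipeline reconstructs five independent Poisson realizations of the sphere
plane per configuration and pools them: 12 ROIs × 5 slices = 60 background
ROIs, and VOI voxels pooled across slices.  Every configuration sees the
same five sinograms, so differences across the sweep reflect penalty
strength alone.

## Clinical arm

Lesion SUVmax values are read verbatim from the packaged CSV (checksum
pinned).  Liver noise follows the standard procedure: nine 30 mm ROIs on the
three largest liver slices, noise = SD/mean of ROI means; SNR = SUVmax /
liver noise, SBR = SUVmax / liver SUVmean.  Group-level relative differences
are computed under both aggregations — mean of per-lesion ratios (default)
and ratio of group means — because the two differ and the source analysis
does not state which it used.  For ΔSUVmax(OSEM−500) the small-lesion
ratio-of-means value (−12.1%) reproduces the reported −12.0%; the reported
ΔSUVmax(500−100) percentages (−47.7/−33.1, with −31.1 elsewhere for the
large group) are not recoverable from the table under either aggregation
(−19.8/−17.8 mean-of-ratios, −18.3/−13.7 ratio-of-means); this discrepancy
is surfaced, not reconciled.  Six table rows violate monotone SUVmax
decrease along the β sweep (four small lung metastases bumping at β = 300,
two large lung metastases at β = 200); they are reported as exceptions.

The synthetic clinical volume emulates structure, not physics: a liver slab
at SUVmean 2.2 with additive white Gaussian noise (SD 0.15 at 4 mm voxels)
and spherical lesions with lognormal SUVmax (median 17, log-SD 0.45, matched
to the small-lesion spread).  White noise is uncorrelated, so ROI-mean liver
noise (~0.013) is far below clinically reported levels (~0.05–0.13, where
reconstruction correlates noise over centimeters); synthetic SNR values are
therefore inflated and are used to exercise the procedure, not to estimate
clinical SNR.

## Statistics

Paired designs throughout (each sphere/lesion measured under every
reconstruction): two-sided paired t, one-way repeated-measures ANOVA
(subject = lesion/sphere; verified F = t² at k = 2 and against the
statsmodels implementation), Bonferroni over all C(k,2) pairwise post hocs,
α = 0.05.  Repeated measures was chosen because the omnibus test's flavor is
not published and the design is paired.

## What passing tests do and do not show

The simulator reproduces the *directions* the scanner study reports — BV
strictly decreasing in β; CR and VOI-max non-increasing in β for every
sphere; SNR rising from β 100 to 500; the 10 mm sphere's ΔCR(500−100)
magnitude exceeding the 37 mm sphere's and shrinking as LBR rises; lung
error below OSEM for every β at 8:1; OSEM lowest in group-mean SUVmax.  The
published *magnitudes* derive from a specific scanner, 3-D acquisition and
vendor reconstruction, and are not comparable at desk scale.  The 2:1-LBR
contrast-recovery deltas are the noisiest quantities here (the CR
denominator is smallest there); their LBR ordering holds at the default
conditions but can invert for an unlucky noise realization.

## Problem sizes and determinism

Default study conditions: 128×128 slices at 2.5 mm, 192 angles, 2×10⁵
counts/slice, 5 replicate slices, β grid {100…500} + OSEM, three LBRs —
about 90 s on one CPU for the full set.  All randomness descends from a
single experiment seed through CRC-based sub-seeds (stable across
processes); reconstruction itself is deterministic.
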