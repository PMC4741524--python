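# Methods

## Scope and model

`dualpet` analyses dual-tracer FCH/FDG PET of the mouse brain at the level
of reconstructed count images. Tomographic reconstruction is deliberately
not modelled: the simulator emits a reconstructed-image surrogate directly,
because every quantity the analysis consumes — target-to-background ratios,
hot-spot masks, subtraction residuals — is defined on the reconstructed
image, and only count *ratios* carry meaning downstream. Absolute count
scales are package choices.

The forward model for one scan is

    counts ~ Poisson( G_psf * [ uptake(label) · c_bg · dose/5.5 MBq ] )

where `uptake(label)` is the tissue's activity relative to normal brain
(brain ≡ 1, outside head ≡ 0), `c_bg` the expected background counts per
voxel, and `G_psf` an isotropic Gaussian with the scanner's FWHM. Noise is
applied after the blur, i.e. to the reconstructed mean field — adequate for
ratio-level validation, though real reconstructed noise is spatially
correlated. The two tracer sessions are statistically independent; decay
between sessions is absorbed into per-scan dose scaling, so no cross-talk
term exists.

## Phantom geometry

* Brain: 10 × 8 × 6 mm ellipsoid. Axis order is (x left–right, y
  dorsal–ventral, z rostral–caudal) with semi-axes (5, 3, 4) mm: the
  longest axis is placed left–right so that the largest tumor (4.2 mm
  diameter) at the lateral xenograft site stays wholly inside the
  ellipsoid. The phantom is a geometric envelope, not an atlas.
* Tumor: sphere at 2 mm lateral of midline, 2.5 mm deep from the dorsal
  surface (the orthotopic inoculation site); diameters 2.8–4.2 mm.
* Physiologic hot spot: 1.5 mm sphere at a fixed ventral-midline site
  (pituitary / choroid-plexus surrogate), kept about one PSF FWHM clear of
  the brain boundary so boundary spill-out does not dominate its signal.
  It is deliberately smaller than any tumor, so size alone cannot separate
  the two classes.
* Voxels: 0.4 mm isotropic by default (≥ 7 voxels across the smallest
  tumor); membership by voxel-center inclusion; labels partition the grid.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| PSF FWHM | 2.0 | mm | typical reconstructed rodent-PET resolution |
| background counts | 100 | counts/voxel | gives per-animal TBR ± SDs of ~0.1, the tabulated order |
| scan duration | 10 | min | protocol value; metadata only |
| dose | 5.5 | MBq | protocol value; counts scale linearly with it |
| k_sigma | 3.0 | – | detection threshold mean + k·SD; with min_voxels=5 the false-alarm rate per control scan is ≤ 5% while 2.8 mm tumors at uptake ≥ 2 are always found |
| min_voxels | 5 | voxels | suppresses single-voxel Poisson excursions |
| τ (tau) | 1.10 | – | fused-FDG TBR cut between control foci (~1.04) and the weakest tabulated tumors (1.12); configurable |
| background erosion | 2.0 | mm | the "normal brain area" excludes the PSF falloff at the brain edge (see below) |

## Partial-volume calibration — the central numerical fact

A 2 mm PSF on millimetre-scale objects is not a small perturbation:

* a 3.5 mm sphere retains ~76% of its contrast at the peak and ~42% in the
  ROI mean;
* a 1.5 mm sphere retains ~15% at the peak.

Three design choices follow directly from this arithmetic.

1. **Generator uptakes are pre-blur tissue contrasts.** The measured ratios
   of the reference study are post-blur quantities. To make the simulated
   study *measure* like the real one, the hot-spot FCH uptake defaults to
   (4, 12) — measuring as TBR ≈ 1.4–1.8 on a sub-resolution focus — and
   the tumor FDG uptake band defaults to (1.2, 1.6), measuring as
   fused-image TBR ≈ 1.0–1.2 while remaining hard to see against the FDG
   background. Narrow near-1 FDG bands or hot-spot uptakes below ~3.5
   produce *nothing* to detect or classify under a 2 mm PSF, i.e. they
   cannot reproduce the study's false-positive phenomenon at all.
2. **Plain TBR is reported as measured, never "corrected".** It is the
   study's readout and is reproduced as such; its PSF bias is negative and
   shrinks with object size (asserted in the tests).
3. **True uptake recovery uses an explicit recovery-coefficient
   correction** (`recovered_uptake`): the background level is fitted by
   least squares against the blurred brain-mask profile (modelling the
   edge falloff instead of averaging over it), and the ROI's recovery
   coefficient is the ROI mean of the PSF-blurred ROI indicator. Under the
   linear blur model this is unbiased; simulations at uptakes 1.5–4.0
   recover the truth to within ~1% when the ROI delineates the object
   (e.g. a drawn ROI), and within the tests' 10% band throughout.

The background-erosion choice belongs to the same arithmetic: with a 2 mm
PSF roughly half the voxels of a mouse-brain mask lie in the edge spill-out
zone, and a whole-mask background mean (~0.7 of the true level) would
inflate every TBR by ~1.5×. Quantification backgrounds therefore use the
brain mask eroded by 2 mm; hot-spot *detection* keeps whole-brain
statistics (mean + 3 SD over a region containing the lesion is robust
enough, and re-estimation after the first pass removes the lesion's
contamination).

## Analysis chain

1. Detect FCH hot spots: threshold at background mean + k·SD, 26-connected
   components ≥ min_voxels, one background re-estimation pass with detected
   components (dilated by 2 voxels) excluded; components sorted by mean
   counts, ties broken by size then centroid.
2. Normalize each scan by its interior background mean (normal brain ≡ 1).
3. Register the FCH to the FDG volume by exhaustive integer-voxel
   translation maximizing normalized cross-correlation (ties toward zero
   shift); rotation is out of scope, consecutive-day repositioning of a
   fixed-chamber mouse is approximated as translation.
4. Merge (voxel-wise sum) and subtract the shifted FCH — the FDG component
   is exact by construction, and out-of-field voxels after the shift are
   excluded via a validity mask.
5. Transfer each FCH ROI unchanged onto the FDG component; TBR against the
   residual interior background.
6. Classify: no ROI → negative; max fused TBR > τ → tumor; otherwise FCH
   false positive. Serial records of one animal give a fused-TBR growth
   trajectory with a strict-increase flag.

Group statistics use the sample SD (n−1). A single-value group returns
SD 0 with an explicit degeneracy flag rather than failing (serial
trajectories can have singleton groups). Both the pooled-variance Student
t and the Welch t are implemented; pooled is the default. On the reference
table's fused columns the two disagree across the 0.01 level (pooled
p ≈ 0.043, Welch p ≈ 0.005), so no test asserts a p-value bound — both are
reported.

## What the simulator does and does not emulate

Emulated: the two-group design (10 tumor / 14 control), the ~4/14 control
hot-spot prevalence, FCH tumor contrasts spanning the tabulated 1.1–4.2,
FDG tumors that are hard to read on the single-tracer image yet carry a
measurable fused residual, Poisson counting noise, scanner blur, and
between-session repositioning (as integer translation).

Not emulated: anatomically realistic uptake heterogeneity, correlated
reconstruction noise, attenuation/scatter (matching the study's omission of
those corrections), rotational misalignment, partial-volume tissue
fractions, and the bioluminescence modality (its ratios ride along as
annotation only). Consequently, passing tests demonstrate that the
*analysis* behaves correctly under the stated forward model — not that the
forward model captures every property of real scans.

Simulated sensitivity is intentionally not forced to the reference value:
tumors drawn with low FCH contrast (< ~1.6) fall below the automated
detection threshold, and tumors with fused residuals near τ can be called
false positives under noise — the same marginal cases visible in the
reference table itself (FCH 1.08; fused 1.12 and 1.14 on either side of
the cut). The tabulated per-animal data overlap between groups, and no
single τ separates them perfectly; the classifier reports per-animal calls
honestly instead of asserting a categorical claim.

## Numerical conventions

* Connectivity: 26-neighbour throughout; dilations/erosions use the
  corresponding structuring elements (erosion of the background region uses
  the 6-neighbour element for an ~isotropic metric margin).
* Blur kernels are normalized and zero-padded; total expected counts are
  conserved for objects away from the grid border (tested).
* Rounding to the printed precision (half-up) happens only when comparing
  against printed values, never inside computations.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical seeds give bit-identical cohorts,
  scans and analyses.

## Problem sizes

The default grid is 64³ voxels at 0.4 mm. The test suite simulates single
scans for property checks, 50-seed batches for detector operating
characteristics, 20-seed batches for uptake recovery, and ten full
24-animal cohorts for the end-to-end group-statistics check; the complete
suite runs in well under a minute on one CPU.
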