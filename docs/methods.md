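# Methods

## Measurement model

A scanned particle's size is summarised by its equivalent spherical
diameter: the diameter of the circle whose area equals the particle's
measured 2-D silhouette, `ESD = 2·sqrt(A/π)`.  Biovolume is the volume of
the sphere with that diameter.  Both are geometric conveniences, not
anatomical volumes: a copepod is not a sphere, but ESD/biovolume are the
standard currency for comparing size structure across taxa and
instruments.  Pixel areas convert to mm² through the square of the pixel
pitch; the default pitch of 10.58 µm per pixel corresponds to a 2400-dpi
class plankton scanner.  Both conversions are strictly monotone, and
`esd_from_area` inverts the circle-area formula exactly, which the
property tests exercise.

The per-object pixel area is defined here as the foreground pixel count
of the connected component.  Instrument software ("area excluded" in one
vendor's jargon) may treat interior holes or appendage gaps differently;
that semantics is not published, so the foreground-count definition is
the documented stand-in, and calibrated comparisons across instruments
should recalibrate against sorted specimens.

## Segmentation

Dark objects on a light background (the scanner convention) are isolated
by optional background-image subtraction, Otsu or fixed thresholding,
and 8-connected component labelling; components below `min_area_px`
(default 30 px ≈ 0.34 mm ESD, just under a 335-µm net mesh) are dropped
as noise.  Border-touching objects are kept but flagged — no published
exclusion rule exists, and discarding them silently would bias abundance
low.  Labels are assigned in raster-scan order of each region's first
pixel, coordinates are 0-based and bounding boxes half-open.  A uniform
image segments to an empty list, not an error.

This is deliberately not a re-implementation of any instrument's
firmware pipeline: the accuracy contract is stated against rasterised
ground truth from the package's own image generator (object count exact,
per-object area within 2% for objects of radius ≥ 10 px), which the
acceptance suite checks on 20 images.

## Abundance accounting

Each layer sample carries a filtered volume `V` (m³, from a flowmeter)
and an aliquot fraction `f` (the proportion of the catch actually
scanned, 1/2–1/128 in practice).  A count `k` in the aliquot scales to a
concentration `(k/f)/V` per m³.  Multiplying by the layer's *thickness*
(bottom − top, in m) gives an areal value per m² — thickness, not
absolute depth, is the only reading under which per-m³ × m = per-m²
integration is dimensionally correct.  Areal values sum over the eight
strata (0–50, 50–100, 100–150, 150–200, 200–300, 300–500, 500–750,
750–1,000 m) to a water-column total, and per-layer fractions are shares
of that total.  Biovolume profiles run the same arithmetic on summed
individual sphere biovolumes.

Missing layers are distinguished from zero-count layers: a profile over
the standard scheme that lacks a stratum raises unless partial columns
are explicitly allowed, because the column total would otherwise be a
silent underestimate.  Day/night is taken from tow metadata, never
recomputed from sun angles.

Weighted mean depth (WMD) is the areal-weighted mean of layer midpoints
— a resolution-limited summary: with eight strata it cannot resolve
structure finer than the midpoint spacing, which is why the no-diel-
change acceptance check uses the mean inter-midpoint spacing (~121 m) as
its indifference band.  DVM amplitude is WMD(day) − WMD(night), positive
for nocturnal ascent.

## Size structure and stage assignment

Histograms use half-open `[x, x+w)` bins aligned to zero, default width
0.1 mm, with a small epsilon (1e−9 of a bin) guarding the edge rule
against float division; weights default to each individual's areal
contribution `thickness/(f·V)` so the histogram total equals the
water-column total.  The size-by-depth matrix distributes the same
weights over (bin × layer) cells and normalises to percent of the column
total, grand total 100.

Stage assignment treats each copepodite stage's ESD as Normal(mean, sd)
from the reference table and computes equal-prior posteriors at the
observed ESD.  The call is the posterior argmax; when the top-two ratio
is below 3 (configurable) the call is flagged ambiguous.  This surfaces,
rather than hides, the genuine overlap among late *E. bungii* stages
(C4F/C4M, and C5F/C5M with small adult males): ESD alone cannot separate
them, and the posterior vector is returned so downstream code can
propagate that uncertainty.  When every density underflows (an ESD far
outside all bands) the nearest mean in sd units is assigned with
posterior 1.  Per-stage references are estimated from stage-sorted
measurements as sample mean and sd (n−1); fewer than two measurements
per stage is an error and a zero sd is rejected at table load.

The 2-mm split separates *M. pacifica* (all stages < 2 mm ESD) from its
three larger congeners, which ESD cannot resolve to species; the
boundary value is assigned to the large group, a documented and
configurable convention.

## Synthetic data

The generator emulates the sampling design, not any particular field
dataset: per-phase (day/night) populations of `n_individuals`, stages
drawn from abundance weights, ESD from the stage's Normal truncated at
zero by resampling (truncation is negligible for the packaged
parameters: the smallest cohort mean is 12 sd above zero), layer drawn
from an explicit per-layer probability vector (per-stage overrides allow
stage-specific behaviour such as adult males skipping the nocturnal
ascent), and binomial aliquot thinning — each individual survives the
split with probability `f`, as a physical sample splitter behaves, so
emitted counts are Binomial(n, f) rather than exactly n·f.

Preset scenarios encode the qualitative patterns of the study system as
explicit probability vectors: `mpacifica_dvm` (deep day modes, 60%
surface mass at night, adult males deep in both phases),
`ebungii_svm_october` (identical day/night distributions with 90% of
mass at 200–500 m, stages C3+), `ebungii_july_recruitment` (young stages
dominant and surface-bound), `metridia_mixture` (the packaged cohorts
plus a >2-mm congener component at mean 2.75 mm, sd 0.25 — chosen to sit
centrally in the published >2-mm congener range).  Tests therefore
compare pipeline output against the preset's own ground truth, which the
`GroundTruth` record exposes (every generated individual with its true
stage, phase, layer and thinning outcome).

Field tow metadata ship as a packaged fixture reproducing the published
eight-tow scheme (four seasons × day/night, eight strata, aliquots
1/32–1/2); per-layer filtered volumes were not published, so the fixture
uses plausible synthetic values (layer thickness × 1.5 m² mouth × an
oblique path factor of 2, i.e. 150–750 m³), and is labelled accordingly.

What the generator does *not* emulate — and what passing tests therefore
do not establish about field data: taxonomic misidentification,
size-selective net avoidance and mesh extrusion, non-Normal or skewed
size distributions within a stage, patchiness (overdispersion beyond
binomial), and day/night differences in catchability.

## Numerical and interface choices

Sample cohort statistics use the n−1 sd.  Tabular output is written at 6
significant digits, and the detection-type consistency check between
stored biovolume and ESD runs at 1e−4 relative tolerance to accommodate
that round trip.  Seeds propagate through `numpy.random.default_rng`;
the acceptance script derives independent sub-seeds per target from a
`SeedSequence` so targets do not share streams.  Problem sizes
throughout (1,000 per stage cohort, 2,000 per migration scenario, 20
images for the segmentation check) match the package's stated recovery
contracts: 2 SE bands at n = 1,000, binomial 95% bands on layer
fractions at n = 2,000.

## Known limitations

ESD-based stage assignment is a stand-in for microscope sorting and is
unreliable for late-stage *E. bungii* by construction; the ambiguity
flag is the honest output there.  WMD-based migration amplitude is
bounded by the layer resolution.  The segmentation accuracy contract is
stated for non-overlapping objects — touching organisms merge into one
region, which operators avoid physically during scanning.
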