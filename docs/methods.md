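# Methods

## System and scope

The talin-1 rod R3 subdomain is a four-helix bundle (mouse numbering,
residues ~795–911) with two cryptic vinculin binding sites; it unfolds under
~5 pN, the lowest of the rod subdomains, and its mechanical stability is
tuned experimentally by substituting hydrophobic-core residues with serine
(the cumulative ladder I805S → I812S → L890S → L897S, labelled 1S–4S). This
package implements the downstream quantifications of such perturbations —
not the MD engine, image reconstruction, or tracking, whose outputs are
taken as inputs.

## Pull-plan construction

A pull plan is a declarative description of a constant-force steered-MD
setup: the α-carbons of H1 anchors Q800/T804/V808/S815 fixed, the α-carbons
of H4 anchors Q888/G896/A900/A904 pulled along +z, force in pN (default
150; 0 is valid equilibration mode), inside a 10 × 10 × 30 nm box. Before
planning, the bundle is rigidly oriented so the V808→G896 α-carbon vector
(d3) is parallel to +z. The orientation uses the minimal (Rodrigues)
rotation taking d3 onto +z, applied about the bundle centroid; optionally
the centroid is then translated to the box center. Coincident anchor atoms
are rejected. Helix boundaries are nowhere printed numerically in the source
material, so the defaults H1 796–815, H2 824–849, H3 856–880, H4 886–909
were chosen to contain all anchor and mutation residues and are configurable
on every entry point. Author (mouse talin-1) numbering is used throughout,
with no renumbering on file read.

## Core water penetration

A water molecule is counted as penetrating the hydrophobic core when its
oxygen lies within a cutoff (default 0.5 nm) of at least one heavy atom of
*every* one of the four helices. This conjunctive reading is the only one
that isolates core water; water hydrogens are excluded because water models
differ in them, and protein hydrogens are excluded for the same reason.
Waters at the open ends of the bundle satisfy the criterion and are counted
— the clipping planes sometimes used in visualizations are cosmetic. The
production counter uses one KD-tree per helix; an all-pairs brute-force
implementation is kept as an independent code path and the two are asserted
equal on randomized configurations. The count is invariant under rigid
motions and water permutations and monotone non-decreasing in the cutoff.

Per-frame counts are smoothed with a 10-frame sliding average. The default
window convention is *trailing* (mean of the last min(i+1, 10) frames),
matching progressive plotting of a trace; a *centered* truncated window is
available as an option. Replicate runs (typically 5 pulls per construct) are
averaged element-wise; series on different time grids are linearly
interpolated onto the first grid.

## Displacements and refolding

H1–H4 separation is followed on four α-carbon vectors: d1 = 800–904,
d2 = 804–900, d3 = 808–896, d4 = 815–888, reported in nm per frame. All
trajectory operations take explicit per-frame timestamps and never assume a
frame rate. Refolding of a relaxation run is scored on d3: the refold time
is the earliest t\* such that |d3(t) − baseline| ≤ tol for *all* t ≥ t\*
(default tol 0.05 nm). The stays-in-band criterion, rather than first touch,
avoids counting transient crossings; a series ending outside the band
returns a "not refolded" sentinel (`None`).

## FRAP

Normalization follows the double ratio
F(t) = [B(t)/⟨B⟩_pre] / [Cell(t)/⟨Cell⟩_pre], with the pre-bleach reference
taken as the mean over all pre-bleach frames (more robust to shot noise than
the last frame alone). Whole-cell acquisition fading multiplies both
channels and cancels exactly in the ratio — a property the synthetic
generator verifies algebraically. The subsequent "normalization to zero" is
implemented full-scale (first post-bleach value → 0, pre-bleach plateau → 1,
the EasyFRAP convention), so the fitted plateau reads directly as the mobile
fraction; a subtract-only mode is available. The post-bleach curve is fitted
by least squares with F(t) = M·(1 − e^{−kt}), t measured from the bleach
frame, M bounded to [0, 1.5] (values slightly above 1 flag normalization
problems rather than being clipped silently) and k > 0. Initialization: M₀
from the last decile of the curve, k₀ = ln 2 / (time to half of M₀).
Non-convergence, a rate pinned at its bound, or a near-zero plateau (rate
unidentifiable) are reported in the fit's `flags`, never silently. The
plateau is fitted unconstrained within the 90 s acquisition window; a
single-exponential model only (no diffusion-vs-binding model selection).

## Adhesion imaging

Adhesion/cytosol ratios are quotients of mean intensities over disjoint
masks; they are invariant to a global gain (hence robust to expression
differences) but *not* to additive offsets — a property asserted by test to
motivate the optional background subtraction. Adhesion segmentation (not
described in the source material) defaults to Gaussian blur (σ = 0.2 µm),
white top-hat background removal, Otsu threshold, and a 0.25 µm² minimum
object area; the cytosol mask is the cell mask minus the adhesions dilated
by 0.5 µm. All values are configurable.

The paxillin mask is a Gaussian blur (default σ = 0.3 µm) followed by
thresholding — manual threshold with Otsu fallback, since no values are
printed. Colocalization uses the Mander's split coefficient M1: the fraction
of channel-a intensity, inside the mask, on pixels where channel b exceeds a
manual threshold; it lies in [0, 1] and is invariant to uniform scaling of
channel a. The fibronectin fraction is the adhesion-mask area intersecting
the pattern mask over the total adhesion-mask area (area-weighted, per the
source's phrasing "of adhesion area"). Micropattern masks are periodic
square lattices decided at pixel centers; coverage equals (square/pitch)² up
to discretization, exactly when the pitch divides the field.

Migration speed is path speed — summed step lengths over total duration, in
µm/h — with net-displacement speed reported alongside; zero-duration tracks
are rejected and logged. Pixel coordinates are 0-based, row-major,
pixel-center convention; areas in µm² via pixel_size².

## Melt fitting

Single-wavelength melts are fitted with a two-state van 't Hoff model with
linear folded/unfolded baselines (the standard equivalent of proprietary
global-fit packages for this task): signal(T) = (b_f(T) + b_u(T)·K)/(1 + K),
K = exp[−ΔH/R·(1/T − 1/Tm)], temperatures in Kelvin internally and °C at the
interface. Initialization: Tm₀ at the steepest finite-difference slope,
baselines from straight-line fits to the first/last temperature quartiles,
ΔH₀ = 200 kJ/mol. A transition weaker than 5× the local noise (estimated
from second differences) or a fitted midpoint outside the scanned range is
flagged. By construction the fitted Tm is the temperature where the fraction
unfolded crosses 0.5. Spectral deconvolution (helical content) is out of
scope: it requires an external basis-set library.

## Synthetic data generators

The generators define the conditions under which the pipeline is exercised;
their defaults mirror the study's acquisition settings where stated.

- **Bundle trajectories**: four straight dummy-CA chains at the corners of a
  0.6 nm square prism, residue-numbered to contain all anchors; the 0.6 nm
  side puts the core centroid 0.42 nm from every helix, inside the 0.5 nm
  cutoff. H4 translates away at a chosen opening rate, with the 808/896
  anchors at equal height so d3 opens exactly linearly. A requested number
  of core waters (constant or a function of time) is placed near the core
  centroid and *verified against the brute-force counter before each frame
  is emitted*; decoy waters sit ≥ 3 nm outside. Infeasible schedules (core
  opened beyond the cutoff) raise. These are geometric stand-ins, not
  physical helices: the analysis operators consume only coordinates.
- **FRAP records**: 0.5 s sampling, 5 s pre-bleach, 90 s post-bleach; the
  two channels are constructed so the double ratio recovers
  M·(1 − e^{−kt}) exactly at zero noise, with optional exponential
  acquisition fading (which cancels) and relative Gaussian noise per channel.
- **Scenes**: 512² rasters at 0.1 µm/pixel; lattice pitch 6.4 µm (8 whole
  periods in the 51.2 µm field, so rasterized coverage is exact) at 56.25 %
  coverage by default. Elliptical adhesions (semi-axes ~0.2–0.9 µm) are
  placed entirely on or entirely off the fibronectin squares, greedily
  steering the painted area fraction to the requested value — realized
  fractions land well within ±2 percentage points at 500 adhesions.
- **Melts**: model-exact two-state curves, 20–90 °C in 2 °C steps, noise as
  a fraction of the signal span.
- **Tracks**: persistent random walks at 2 min steps over 12 h with *exact*
  step length (speed · dt), so path speed equals the generating speed;
  persistence ∈ [0, 1] scales the per-step heading noise (1 → straight
  line).

All randomness flows through one `numpy.random.Generator` seeded per call;
the same seed reproduces outputs bit-for-bit on a platform. Artifacts
written to disk get a JSON ground-truth sidecar.

What the generators do **not** emulate: physical forces or thermostats,
microscope PSFs beyond Gaussian blur, bleaching during acquisition of the
reference channel, segmentation-confounding structures (vesicles, ruffles),
or heterogeneous adhesion intensity. Passing round trips therefore
demonstrate correctness of the estimators under their stated models, not
robustness to every artifact of real data.

## Problem sizes and numerical choices

The test and acceptance runs use trajectories of tens of frames, 100-seed
FRAP and 50-seed melt noise sweeps, 200 random solvated configurations
(≤ 500 waters) for oracle equivalence, and 500-adhesion scenes at 512² —
sizes chosen so the full suite completes in seconds while keeping sampling
error far below the decision thresholds. Distances are in nm, times in
ns/s/min as appropriate per module; rigid transforms preserve pairwise
distances to 1e-9 nm; angular alignment tolerance is 1e-6 rad.

## Known limitations

- The water-penetration criterion is a geometric proxy; it does not
  distinguish transiently diffusing waters from stably core-bound ones.
- The two-state melt model cannot represent oligomerization-coupled
  unfolding (relevant for heavily destabilized constructs that dimerize);
  such curves fit with inflated ΔH or flagged residuals.
- FRAP fitting assumes a single exponential; reaction–diffusion mixtures
  bias M and t½.
- Adhesion segmentation defaults are generic; real SIM data may need tuned
  thresholds, supplied via the configurable parameters.
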