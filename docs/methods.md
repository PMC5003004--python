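# Methods

## The measurement problem

A liver spheroid is a dense, roughly spherical aggregate sitting on the
bottom of a round-bottom well. Confocal imaging samples it as a stack
of optical sections from the well bottom upward; staining with Hoechst
(all nuclei), calcein AM (live cytoplasm) and EthD-1 (dead nuclei)
turns viability into per-channel fluorescence. Two physical facts shape
the analysis: optical sections at 10× are thick (comparable to the 5–10
μm plane spacing), and dye/light penetration into the aggregate is
limited to ~110 μm, so only the lower half of a ~220 μm spheroid is
measurable. The pipeline therefore counts cells plane-wise in 2D and
reassembles them in 3D rather than attempting direct 3D segmentation on
strongly anisotropic voxels (1 μm XY vs 10 μm Z by default).

## Synthetic spheroid model

The generator is the package's test bed: it produces stacks whose
ground truth (cell positions, states, true intensities) is known
exactly.

**Geometry.** Cell centers are packed by random sequential placement in
a sphere of radius R = (d_cell/2)(n/φ)^(1/3), with effective cell
diameter d_cell = 22 μm and packing fraction φ = 1 by default, so
1,000 cells give a 220 μm spheroid and the diameter follows a cube-root
law of the cell number. d_cell is an *effective* diameter including
intercellular spacing; it was calibrated once against the 1,000-cell →
220 μm anchor. Centers keep a minimum spacing of 0.6 d_cell (13.2 μm,
never below one nucleus diameter): confluent cells deform but do not
interpenetrate, and without this floor the generator produces nucleus
pairs stacked almost vertically within the linker's lateral
displacement cap, a configuration real tissue does not show. Packing
infeasibility (volume fraction of exclusion spheres > 0.3, near the
random-packing jamming limit) raises an explicit generation error.

**Compound effect.** A dose d kills a Bernoulli fraction
f(d) = d^h/(d^h + IC50^h) of cells (Hill exponent h, default 1).
Optional phenotypes: radial swelling of all centroids by
1 + s·f(d); detachment of a fraction of dead cells to just outside the
spheroid boundary; Hoechst condensation (brighter dead nuclei, default
×1.3). Defaults model a pure viability effect (s = 0, detachment 5%)
because the magnitude of swelling/loosening is compound-specific;
tests exercise them with explicit values. The random stream is consumed
identically at every dose, so dose 0 reproduces the untreated spheroid
bit-for-bit under the same seed.

**Dyes.** Live cells: calcein in a cytoplasm shell (outer radius
0.4 d_cell) and zero EthD-1; dead cells: nuclear EthD-1, zero calcein;
Hoechst in every nucleus. A lognormal cell-to-cell brightness factor
(CV 10%) gives realistic intensity spread. Optional caspase-3/7 and
MitoTracker channels reuse the same machinery through per-cell marker
flags.

**Optics.** Each plane integrates fluorophore density over an optical
section of thickness equal to the z step (configurable;
`plane_thickness_um = 0` gives ideal infinitesimal cross-sections for
geometry tests). This matters: with infinitesimal planes at 10 μm
spacing, a 10 μm nucleus sampled near its pole presents a
sub-resolution disc and ~20% of nuclei in the covered volume would be
undetectable, contradicting the observed ~half-spheroid counts; a
z-step-thick section is also the physically right model for a low-NA
10× confocal. Depth effects: intensity × exp(−z/L) (attenuation length
L, default ∞) and a hard imaging-depth cutoff (default 110 μm) applied
per cell — a cell whose centroid lies deeper contributes nothing
anywhere. The image is blurred by a lateral Gaussian PSF (σ 1.5 μm),
offset by a constant background (5 counts), degraded by Poisson noise
by default, and quantized to 16 bits.

**What the generator does not emulate** — and hence what passing tests
do not certify about real data: spectral bleed-through, out-of-focus
haze beyond the Gaussian PSF, dye-penetration kinetics (staining is
assumed at plateau), nucleus shape variation (spheres only), debris and
optical artifacts, well-to-well plating variability beyond the seeded
randomness, and HepG2-like proliferation (the HepG2 comparison enters
only through the benchmark table fixtures).

## Segmentation and linking choices

* **Thresholding**: per-plane background estimate (median) plus a
  configurable offset in robust SDs (1.4826 × MAD, default offset 5).
  When the background has no robust spread (idealized noiseless
  renders), the threshold falls back to background + 10% of the
  bright-signal range (99.5th percentile), the percentage-of-range rule
  common in high-content software. Otsu and absolute thresholds are
  available per config.
* **Watershed markers** come from maxima of the distance transform of
  the foreground mask (spaced at least half the minimum nucleus
  diameter): intensity maxima are degenerate on the plateaus that
  noiseless discs produce, while distance-transform maxima split
  touching convex nuclei cleanly.
* **Nucleus size window** 4–20 μm equivalent diameter. The floor sits
  well below the nominal 10 μm nucleus because a thick optical section
  near a nucleus pole shows a small partial-volume disc; a 6 μm floor
  would systematically discard those appearances and break the chain
  continuity the linker relies on.
* **Linking** is optimal bipartite min-cost assignment per adjacent
  plane pair (scipy Hungarian), with the displacement cap as hard
  infeasibility — deterministic and checkable against exhaustive
  enumeration, unlike greedy matching. Caps default to 7.5 μm (nuclei)
  and 25 μm (cytoplasm), midpoints of the compartment-appropriate
  ranges. `max_gap_planes` (default 0) tolerates segmentation dropouts
  when raised.
* **Axial span cap**: a chain may collect at most
  ceil(max_axial_extent/z_step) sections (defaults 15 μm for nuclei,
  25 μm for cytoplasm). This is the z analogue of the 2D size window:
  without it, a column of distinct nuclei whose intermediate section
  falls below the detection floor is absorbed into one chain, and
  counts drop by ~20% on dense spheroids.
* **Spheroid detection**: global threshold on the smoothed nuclear
  channel, per-plane morphological closing (12 μm disk) and hole
  filling, 3D connected components, size window on equivalent diameter,
  then the per-plane convex hull of the winning component — spheroid
  cross-sections are convex, and sparse nuclear signal would otherwise
  carve bays into the region. Volume is voxel-counted in physical
  units; sphericity uses a marching-cubes surface-area estimate.
  "No spheroid found" is a `None` return, not an exception.
* **Coordinates**: pixel-center convention ((i + 0.5) × pixel size),
  z index 0 at the well bottom, all measurements in μm/μm³.

## Scoring and readouts

Dead ⇔ nuclear EthD-1 mean ≥ threshold; live ⇔ EthD-1 exclusion. A
cell positive for both calcein and EthD-1 is dead (conservative toward
toxicity). Live cells need not have a matched calcein object to count
as live — deep cells lose calcein signal before turning EthD-1
positive — but live-cell volume/intensity readouts come only from
matched cytoplasm. The marker threshold defaults to a per-plate
estimate: Otsu over pooled per-nucleus EthD-1 means, accepted only when
the split is clearly bimodal (mode separation > 4 within-class SDs),
otherwise a background-derived fallback (background + 4√(background+1))
— an all-live plate must not be cut through its noise. Normalized
readouts are % of the control-well mean; the dead-cell count is instead
normalized to total counted control cells, since controls have ~0 dead.

## Dose–response statistics

The 4PL is fitted by least squares with IC50 parameterized as
log(IC50), bounds [min positive dose/100, max dose × 100], hill ∈
(0, 10], initialization from response quartiles, and standard errors
from the covariance (IC50 SE by the delta method). Non-convergence,
bound-landing, and amplitude below 3× the residual SD are all flagged;
such fits never report an IC50. Outcome classification mirrors screen
reporting: a detectable effect needs ≥30% top-dose decrease vs vehicle
control, significant at P < 0.05 (Welch t-test across replicates); an
IC50 outcome additionally requires the estimate bracketed — inside the
tested range with the top-dose response at or below half of control —
otherwise "> max tested"; no effect is "no tox (max)". Cross-assay
IC50 comparisons use a two-sided z-test on log IC50 with fit SEs
propagated to the log scale; comparisons without both SEs are
explicitly indeterminate. Sensitivity = % of known toxicants detected,
predictivity = % of negative controls correctly negative, rounded to
whole percent; "not determined" rows enter neither numerator nor
denominator.

## Problem sizes and reproducibility

Simulation-backed tests use 1,000-cell spheroids (the calibration
anchor) for counting and recovery checks, 300–600 cells for
multi-condition sweeps such as dose-monotonicity, 200 Monte-Carlo
replicates for fit-error and interval-coverage checks, and 5 seeds for
the depth-limited counting average — sizes chosen so each property is
measured well above its noise floor while the suite stays quick. All
randomness flows from explicit integer seeds (one per ground truth,
per-well seeds derived from the run seed via a seed sequence), and a
fixed config + seed reproduces stacks and output tables byte-for-byte.

## Known limitations

* The depth cutoff acts on cell centroids, not per voxel: a cell
  straddling the cutoff is all-or-nothing. Adequate at 10 μm sampling;
  too coarse for fine axial work.
* Counting accuracy rests on the axial span cap; in tissue with
  strongly elongated or overlapping nuclei the cap and the size window
  would need retuning.
* The spheroid detector assumes convex cross-sections; fragmented or
  dumbbell-shaped aggregates will be over-covered by the hull.
* 2D monolayer assays are not analyzed; their results enter only as
  benchmark-table values.
* Fitted-IC50 standard errors come from the local covariance; for
  strongly censored designs a profile-likelihood interval would be more
  faithful.
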