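# Methods

`flowbold` implements a periodic ("steady-state") block-design fMRI
analysis for flow-motion selectivity, together with a synthetic-data
generator that provides known ground truth for every stage. This note
records the models, conventions, parameter choices and their limits.

## Stimulus model

The coherent display is a limited-lifetime random-dot field: 100 dots of
1.3° diameter at a constant 5 deg/s, lifetime 10 frames at 60 Hz, on a
27° × 20° field sparing the central 2° (diameter). The flow trajectory
morphs continuously over a 2-s cycle: the local velocity direction is the
radial unit vector rotated by 360°·(cycle phase), giving pure expansion at
phase 0, rotation at 0.25, contraction at 0.5, and spirals in between. The
named waypoints fix only five points of the cycle; the single smooth
rotation parameter is this package's choice of "gradual" interpolation,
and the spiral handedness on the two half-cycles follows from it (any
fixed handedness leaves the analysis unchanged).

The random-motion control reuses the coherent condition's per-frame
velocity *multiset*, reassigned to dots by a seeded permutation drawn
independently each frame (per-frame reshuffling is an interpretation; the
alternative — one permutation per dot lifetime — would equally preserve
local motion power). Dots that exceed their lifetime, leave the field,
enter the central exclusion, or collide (centre distance < dot diameter;
centre-based tests, the unambiguous choice) respawn at a uniformly drawn
legal position, by rejection sampling capped at 1000 attempts before a
density error. Collisions created by motion respawn the older dot of the
pair, so younger trajectories survive.

The `motion_energy_summary` diagnostic projects unit velocities onto the
instantaneous flow direction: ≈1 for the coherent display, ≈0 for the
shuffled control — the quantitative meaning of "matched local motion
power, destroyed global coherence".

## Acquisition and response model

Task runs: 84 timepoints at TR 3 s, six 42-s cycles of 21-s coherent
blocks alternating with 21-s control blocks. Rest runs: 120 timepoints.
Four dummy volumes are bookkeeping only (synthetic runs start
stabilised).

The hemodynamic response is a single gamma variate
h(t) = ((t−δ)/τ)^(n−1) exp(−(t−δ)/τ) for t > δ, with onset delay
δ = 2.5 s, shape n = 3 and dispersion τ = 1.6903 s (peak at
δ + (n−1)τ ≈ 5.9 s). The dispersion is not free: it is fixed by the
phase-convention calibration below. A double-gamma variant with an
undershoot is available but not the default.

Model responses are built by convolving the block boxcar with the HRF on
a 0.05-s grid and sampling at TR, so continuous-time phase relationships
govern rather than 3-s-grid convolution artifacts (which would bias the
canonical phase by about +2°). The design-matrix task regressor uses
causal convolution over the run (the first cycle carries the usual onset
transient); the synthetic generator uses the steady-state (circular)
cycle.

## Phase convention and its calibration

The response of a region is summarised at the stimulus fundamental
(6 cycles per run):

* **S/N** = |F(fund)| / RMS(|F(fund−1)|, |F(fund+1)|), computed on the
  concatenated retained series (not the period average, so adjacent bins
  exist). For white noise the expected *power* is equal across bins; the
  amplitude-ratio statistic itself has mean π/(2√2) ≈ 1.11, so "S/N ≈ 1"
  describes the noise floor, with individual values spread around it.
* **Phase**, wrapped to (−180°, 180°]: 0° means in phase with the
  stimulus square wave (fundamental peaking mid-coherent-block); a pure
  delay of τ seconds adds 360·τ/42 degrees; negating a response shifts
  its phase by 180°, which is where random-preferring (counterphase)
  regions live.

The convention and the HRF dispersion are calibrated jointly against one
anchor: the canonical response (21-s boxcar ⊗ default HRF, TR 3 s) must
carry a phase of 64°, the standard hemodynamic delay. Analytically the
phase lag of the gamma HRF at the fundamental ω = 2π/42 s⁻¹ is
ωδ + n·arctan(ωτ); solving for 64° at δ = 2.5 s, n = 3 gives
τ = 1.6903 s. The implementation reproduces 63.8° (the residual ~0.2°
comes from the 0.05-s convolution grid and TR sampling).

For scrubbed series the Fourier coefficients are evaluated with each
retained sample at its original time index (a nonuniform DFT), so gaps
never corrupt phase alignment; for complete runs this reduces exactly to
the standard DFT bin.

## Synthetic BOLD generator

Each labelled region carries: selectivity sign (+1 coherent-preferring,
−1 random-preferring, 0 null), response amplitude (% of baseline, unit
peak of the demeaned canonical cycle), hemodynamic phase (degrees), and
baseline intensity. Region phases are implemented by circularly shifting
the canonical cycle in the frequency domain, so the phase parameter is
*exactly* the quantity the estimator targets — including for negative
selectivity, where the shape is built 180° away and negated so the
delivered fundamental phase still equals the parameter.

Noise is white Gaussian innovations (default SD 0.5% of baseline) passed
through an AR(1) recursion (coefficient 0.3) plus a slow cosine drift
(0.3%, 128-s period, random phase per voxel). The real data's noise
model is not documented; these defaults give single-region S/N in the
1–5 range the study reports, and all three components are exposed.
`amplitude_for_target_sn` inverts the first-order relationship
S/N ≈ a·A₁·√N·√K/(2σ)·g(AR) to choose a region amplitude for a target
S/N at a given region size K.

Rest runs draw unit-variance ROI latents with a prescribed population
correlation matrix (Cholesky construction) at 1% of baseline, embedded
in region voxels with independent noise on top; ROI-mean sample
correlations are therefore attenuated by ~2–3% at the default region
sizes, well inside the recovery tolerances tested.

The default layout is a 24×24×18 grid at 3 mm with bilateral V1 (null
for coherent-vs-random, strong flow-vs-blank response), MT (+1, 64°),
V6 (+1, 82°), PIVC (−1, −146°) and a precuneus/cuneus patch — desk
scale, so full pipelines run in seconds. Grids, anatomy, partial-volume
and physiological noise are deliberately not realistic: passing recovery
tests shows the *analysis* is correct and calibrated, not that it would
survive real registration error or structured physiological noise.

## Preprocessing

* **Scrubbing**: a timepoint is contaminated when any rigid-body
  parameter exceeds 4 mm (translation) or 5° (rotation), read as absolute
  displacement of the reported parameters (their summaries are means and
  maxima of positions, which favours this over framewise deltas). Task
  runs drop whole half-period (7-TR) bins anchored at block onsets so
  every surviving boundary preserves cycle alignment; rest runs drop
  single timepoints. A run keeping less than half its duration is flagged
  unusable. Surviving segments also feed the six motion regressors to the
  GLM — scrubbing and regression are complementary, not alternatives.
* **Intensity adjustment**: each volume is rescaled so its mean equals
  the run's grand mean.
* **High-pass**: the GLM-Fourier projection removes the constant plus
  sine/cosine pairs at 1 and 2 cycles per run; it is a linear projection
  (idempotent, output orthogonal to the removed span) and leaves the
  6-cycle task fundamental untouched.

## GLM, clusters, group analysis

Voxelwise ordinary least squares with task, six centered motion
regressors and one constant per retained segment; t statistics map to Z
through the probit transform of the exact t CDF, preserving two-sided
p-values (so α = 0.05 ⇔ |Z| ≥ 1.96). Clusters are connected components
(6-neighbourhood — the conservative choice, stated because nothing in the
analysis fixes it) of supra-threshold voxels, positive and negative
labelled separately, below-floor components dropped (81 mm³ = three 3-mm
voxels). Centres of mass are |Z|-weighted over cluster voxels, reported
in mm from the grid centre (the stand-in for the anterior-commissure
origin). The fixed-effects group model stacks subjects with a shared
task column and subject-specific nuisances; voxelwise p-values are
Benjamini–Hochberg corrected at q < 0.05 before the cluster floor.

## Seed and lagged-correlation mask

The bilateral V1 seed is the union of supra-threshold flow-vs-blank
voxels (p < 0.001) in each hemisphere, optionally restricted to candidate
calcarine voxels (in synthetic data, the layout's V1 labels — the
stand-in for anatomical localisation); a missing hemisphere is an error
naming the side. The seed's mean series is correlated with every voxel at
delays 0 and 3 s (longer delays configurable; they were found to add
little), on high-pass-filtered, z-scored series computed segment-wise so
scrubbing gaps never pair non-contiguous samples. The critical value is
r* = t*/√(df + t*²) at df = n − 2 (two-tailed α = 0.05), ≈ 0.25 for
n ≈ 63; each delay uses its own n. The mask is the union over delays, so
it can only grow as delays are added.

## Vectorial phase statistics

Each subject contributes the vector (S/N·cos φ, S/N·sin φ). The group
resultant is the Cartesian mean; the dispersion is the point cloud's
standard deviation about the resultant — the RMS of the distances
|vᵢ − resultant| with an n−1 denominator — and the phase SD converts the
assumed 2-D normal spread to an angle, arctan(dispersion/|resultant|).
(For unit vectors with 40° angular spread this recovers ≈38°; taking
instead the SD of the distance *magnitudes* would give ≈21° and was
rejected for that reason.) Groups are compared with a pooled-variance
two-sample t-test: each point's signed angular deviation from its own
group resultant supplies the variance, the wrapped difference of
resultant phases the effect; whether the original analysis tested angles
or vector components is not fully specified, and this projection choice
is recorded as ours.

## Resting-state connectivity

ROI-mean series are high-pass filtered (hence negative correlations are
meaningful and retained), Pearson-correlated per subject, and averaged
elementwise across subjects. Significance comes from the super-subject:
per-subject z-scored series concatenated, with p from the t distribution
at df = total length − 2; for equal-length subjects the super-subject r
equals the mean per-subject r exactly (an identity the tests verify at
1e-10). Group matrices are compared cell-wise with two-tailed t-tests on
Fisher-z transformed correlations (a variance-stabilisation choice of
this package; raw-r mode is available), flagged at p < 0.01 and p < 0.05.
Rest correlations are computed at lag 0; a nonzero lag is configurable.

## Problem sizes used in the shipped experiments

The recovery experiments behind the reproduction script use 12-subject
cohorts, 500 replicates, one 12-voxel region on an 8×8×4 grid, 5 cycles
(70 timepoints) at S/N ≈ 2.5 — the package's desk-scale choice that
leaves the generator conditions (dispersion 40°/35°, block timing, noise
model) untouched. The end-to-end pipeline tests use the full default
layout with 12-subject cohorts.

## Known limitations

No motion *estimation* (synthetic traces are ground truth), no slice
timing, no spatial smoothing or registration, no random-effects group
model, no permutation-based cluster inference. Phase calibration assumes
the single-gamma default; switching HRF families moves the canonical
phase and would require re-deriving the dispersion. The white-noise S/N
floor statistic is biased above 1 by construction (mean ≈ 1.11); tests
quote the exact value rather than pretending the estimator is unbiased.
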