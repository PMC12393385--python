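# Methods

## Coordinate and unit conventions

Right-handed coordinates, membrane normal along +z, extracellular side at
larger z. Lengths in Å, times in ns (frame intervals quoted in ps),
voltages in mV, currents in pA, conductances in pS, charges in elementary
units with e = 1.602176634 × 10⁻¹⁹ C. Trajectories are analysed unwrapped;
ingestion applies per-axis minimum-image continuity correction
(orthorhombic boxes only), which is idempotent on already-continuous
paths.

## Counting region and event detection

The region is a right cylinder bounded by two z-planes and a radial gate.
For the receptor this package was built around, the planes are the
centroid z of the backbone Cα atoms of the two glutamate rings at the
ends of the transmembrane pore (Glu-258 above, Glu-237 below) and the
radius is 17.3 Å — wide enough that a conducting ion cannot slip out the
side of the tilted helix bundle. Which backbone atoms define the rings,
and whether the planes are recomputed per frame or averaged, are both
configuration options (per-frame Cα centroids by default for MD input);
no claim is made that either choice is canonical.

Detection is a per-ion three-zone state machine (above / inside / below,
with the radial gate applied while inside):

* a TB event is one continuous passage above → inside → below; BT is the
  mirror image;
* a radial excursion beyond the gate while inside resets the ion to
  "outside, on the side of its entry ring" — the conservative reading of
  a completion rule that the geometry is meant to make unreachable;
* residencies already open at the first frame, or still open at the last,
  contribute no event (only complete traversals count);
* an ion re-entering later can contribute further events;
* an ion that jumps clean across the region between consecutive frames is
  counted but flagged with a `CoarseSamplingWarning` — at sane frame
  intervals this indicates the sampling is too coarse to trust.

Event start/end times are linearly interpolated between the frames
bracketing each ring crossing (switchable to frame-snapped). Waiting
times are differences of consecutive same-direction start times, pooled
across segments for fitting but never spanning a segment boundary.
Cl⁻ waiting times are not modelled: at the default conditions Cl⁻ events
are too rare for a distributional fit.

## Conductance bookkeeping

Per segment: net events = TB_K⁺ + BT_Cl⁻ − BT_K⁺ − TB_Cl⁻;
I = e·net/Δt; G = I/|Vₑ| reported as a magnitude (inward cation flux at
negative voltage is a positive conductance). Aggregation reports column
means with standard errors computed as population sd/√n — the convention
that reproduces the published average row — while variability (sd-to-
mean) ratios use the sample sd. Current–voltage fits are per voltage-sign
branch, ordinary least squares with an intercept by default (a
through-origin option exists) and a 95% t-based confidence band on the
slope; slopes in pA/mV are reported ×10³ as pS.

A note on per-segment comparisons: published per-row conductances carry a
~1% internal inconsistency (each simulation box has its own height, hence
its own Vₑ = L_z·EF at fixed field). Row-level comparisons at a single
nominal voltage should therefore allow the implied per-box voltage to
vary by a couple of percent; the mean over segments is the robust
quantity.

## Waiting-time models

Single Poisson: f(t) = λe^(−λt). Estimators: count rate λ = N/Δt, and the
order-statistic quantile regression — sorted intervals t₍ᵢ₎ against
−ln(1 − i/N), i = 1..N−1 (the i = N point diverges and is dropped),
forced through the origin; the slope is 1/λ. On data generated exactly
from the inverted relation the estimator is exact to machine precision.

Double-Poisson (hypoexponential): sum of independent exponential lag and
conduction stages. The density is implemented in the order-symmetric form
(swap-invariant in the two rates, nonnegative everywhere), with the
Erlang-2 closed form λ²te^(−λt) substituted when the rates coincide to
within 10⁻⁹ relative; the CDF is continuous through that limit, and for
λ_lag → ∞ it collapses onto the single-exponential CDF. The printed
textbook form of this density is antisymmetric in the rates and goes
negative in the regime where the lag is the faster stage — the
order-symmetric form is the intended distribution.

Fitting: maximum likelihood by Nelder–Mead on log-rates (default), with a
stable log-density using `expm1`; initial values from moment matching
(stage means a + b = mean, a² + b² = variance). Least squares against a
binned empirical density is available for comparison with histogram-based
fits. Rates are labelled λ_lag ≥ λ_cond: in every fit of interest the lag
is the faster stage (mean ~1–1.5 ns against waiting means of ~3.6–8 ns).
Degeneracy: a sample with variance ≥ mean² admits no two-stage solution
(moment flag), and a fitted rate ratio above 50 means the lag stage has
fitted away; both raise a near-degenerate warning rather than an error,
since the single-exponential limit is a legitimate answer.

Predicted event count over a window T: λT (Poisson) or
T/(1/λ_lag + 1/λ_cond) (double-Poisson). With the fitted stage means of
1 and 3.62 ns (TB) this gives 200/4.62 ≈ 43.3 events per 200 ns, and
200/9.67 ≈ 20.7 for the BT pair (1.53, 8.14 ns).

Event durations are fitted log-normal by closed-form MLE on logs; the
implied arithmetic mean is exp(μ + σ²/2).

## Pathway classification

An entry leg is lateral when, within a look-back window (default 5 ns)
before the event start, the ion's radial distance exceeded the wall
threshold (default: the counting radius, 17.3 Å) while its z lay in the
extracellular-vestibule range (default: top ring to top ring + 40 Å).
Only top entries can be lateral — the side fenestrations are in the
extracellular wall, and the intracellular portals are out of scope (their
structure is unresolved in the parent system). If the look-back would
extend before the trajectory start the event is labelled axial with a
warning. All three window parameters are configuration values; the
defaults are this package's choice, since no numeric threshold is
published for the boundary.

## Profiles

* **Ion density**: ions inside the counting radius binned in 0.5-Å disks;
  per-frame mean counts divided by the bulk expectation c·N_A·πr²·Δz
  (at 150 mM and r = 17.3 Å: 0.0425 ions per disk). Profile sampling
  defaults to a 100-ps stride, independent of the 10-ps detection stride.
* **Pore radius**: a deliberately simplified, deterministic variant of
  the Monte-Carlo inscribed-sphere profilers — per 0.5-Å slab, hill-climb
  on a 0.1-Å lattice from the nominal axis, maximizing the minimal
  (3-D distance − vdW radius) over nearby atoms (slab half-width 8 Å).
  Tests hold it to within 0.05 Å of an exhaustive 2-D grid search on
  constructed fixtures; it is not a replacement for a full profiler on
  tortuous pores whose centre line wanders more than a few Å off axis.
* **Hydration**: water oxygens strictly within 3.52 Å of an in-pore K⁺
  (the first-shell radius from a bulk radial distribution at the same
  concentration), with protein oxygens in the same shell counted as
  replacements. The strict inequality is a deterministic tie-break;
  exact-threshold contacts have measure zero in real data.
* **Residue position density**: z-histogram of all atoms (hydrogens
  included) of all copies of each residue type, normalized to unit area
  per type.
* **Axial diffusion**: 1-D MSD over contiguous in-region residencies of
  ≥ 10 frames, slope fitted over lags 1–20, D = slope/2 in Å²/ns
  (1 Å²/ns = 10⁻¹¹ m²/s), with the log-log MSD exponent checked first —
  above 1.5 the motion is drift-dominated and no coefficient is reported.
  Under a strong applied field the in-pore motion is drift + diffusion,
  so this estimator is meant for the diffusive regime.

## Synthetic generator

The generator emulates the statistics the analysis assumes, with ground
truth, not the physics: event start times per (species, direction) follow
a configurable renewal process; each event is realized by a fresh ion
that dwells in the entry-side reservoir, approaches the pore (axially
from above the vestibule, or laterally through the wall at vestibule
height for a configurable fraction of top entries), crosses with linear z
and radially-reflected in-plane jitter (1 Å/frame), exits, and random-
walks away; non-permeant bulk ions random-walk in the reservoir slabs.

Defaults are the study conditions: 200-ns runs sampled every 10 ps at
−102 mV in a 50 × 50 × 160 Å box; TB K⁺ entries double-Poisson with stage
means 1 and 3.62 ns, BT 1.53 and 8.14 ns; Cl⁻ single-Poisson at rates
giving ~0–1 events per segment; log-normal transits with mean 1.24 ns and
log-sd solved so 99% of durations exceed three frame intervals; lateral
fraction 0.006; 150 mM bulk (≈36 ions per species in the default box).
Transits shorter than five frame intervals are resampled so every
generated event is resolvable at the frame spacing — this is the domain
on which detector/ground-truth equivalence is exact, and it biases the
mean transit by under 2%. Events that could not complete before the run
ends are not realized (only complete events exist, matching the counting
rule). Reproducibility: one root seed sequence, deterministic child
stream per ion.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no forces, no ion–ion interactions (the lag
stage exists only in the entry-time statistics, not in the geometry of
delayed ions), no protein/water dynamics, no voltage dependence of rates
unless configured, and bulk ions never approach the pore. Detector
validation on this data demonstrates bookkeeping correctness, not
robustness to diffusive recrossings of the rings; the hand-built fixture
tests cover those edge cases separately.

Test and acceptance problem sizes are the package's own choice of desk
scale: 20–30-ns detector-equivalence runs across 20 seeds, 10⁴–10⁵-draw
estimator-recovery samples, 120–200-ns single runs for end-to-end
statistics.

## Known limitations

* Unwrapping assumes orthorhombic boxes.
* The pore-radius search can undershoot on pores whose widest centre at a
  level lies far (≫ a few Å) off the starting axis, since the hill climb
  is local.
* The quantile-regression rate estimator is biased upward a few percent
  on heavy right-tailed samples (it drops the largest order statistic).
* Segment boundaries assign an event wholly to the window containing its
  start; a traversal straddling the boundary is not split.
* The double-Poisson model is a two-stage chain only; longer chains and
  time-varying rates are out of scope.
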