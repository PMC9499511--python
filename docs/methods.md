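# Methods

`srptrack` reimplements, as a tested pipeline, the analysis used to follow
the signal recognition particle (SRP) cycle in live *E. coli* by
single-particle tracking of dye-labeled 4.5S RNA: stroboscopic widefield
movies of a handful of labeled molecules per cell, a diffusion-state hidden
Markov model over trajectory displacements, membrane/cytosol decomposition
of the states and of ribosome binding/release events, and a closed-form
dual-pathway kinetic model of translocon targeting.  Because re-analysis of
the deposited movies is out of scope, every quantitative claim is validated
by parameter recovery on synthetic data whose generators are first-class,
tested code.

## Cell geometry

The model cell is a spherocylinder: a cytosol cylinder of radius 0.42 µm
and length 3 µm capped by hemispheres of the same radius, wrapped in a
0.05-µm membrane shell (outer envelope radius 0.47 µm); a single-compartment
variant uses radius 0.47 µm.  Coordinates are continuous µm with x along
the long axis, z along the optical axis, origin at the cell center;
rasterization happens only at rendering.  Normalized coordinates put the
pole tips at long-axis 0 and 1 and divide the in-plane short-axis offset by
the local cytosol half-width, so the inner membrane edge sits at r = ±1 and
membrane-shell molecules reach |r| ≈ 1.12.  Pole caps use the same rule
with the local cap half-width; all quantitative profiles exclude the poles,
so the cap convention cannot affect results.

Radial (short-axis) profiles are histograms of r restricted to the
cylindrical part: positions with long-axis coordinate within margin
m = 0.15 of either pole or of mid-cell (possible septum) are excluded.
Presentation profiles use 18 bins over [−1, 1], unit-normalized.

## Ground-truth generators

**Reaction–diffusion Brownian dynamics.**  Independent particles switch
among four species — RNA (free 4.5S RNA, D = 8 µm²/s), SRP (RNA·Ffh,
2.4 µm²/s), RC (ribosome-bound SRP in the cytosol, 0.08 µm²/s) and RM
(ribosome-bound SRP at the membrane, 0.05 µm²/s) — while taking isotropic
Gaussian steps of per-axis std √(2 D dt) and reflecting off the envelope of
their allowed compartment (radial folding about the axis segment, iterated;
an error is raised if √(2 D dt) would exceed the shell thickness for a
membrane species).  Conversions are first-order with exponential waiting
times; membrane-gated reactions fire only within the outermost 0.05 µm of
the cytosol (or in the shell itself).  At most one conversion fires per
particle per step, selected against the species at step start.  Default
rates are calibrated so that: the total SRP→ribosome binding rate is
1/1.5 s⁻¹, split so ~75% of bindings are cytosolic; the cytosol-bound
complex reaches the membrane in ~350 ms on average (RC→RM rate 28 s⁻¹ in
the gate region, set by the provided bisection calibration for the default
D_RC — the mean includes the diffusion-limited approach, so a well-mixed
rate estimate would be wrong); the membrane dwell before release is 500 ms;
RNA↔SRP exchange is over an order of magnitude slower than everything else
with a ~16% stationary free-RNA fraction.  The reference protocol runs ten
replicates of 200 molecules with dt = 5.7 ms, 56 s equilibration and 20 s
recording; tests and the virtual experiments run reduced versions (a few
seconds, tens of particles) and can draw initial species from the effective
stationary distribution to shorten equilibration.

**Observation model.**  Ground truth is subsampled at the 20 ms frame
interval (nearest simulated time point; the ≤2.85 ms timing error is far
below the frame interval).  One normally distributed z offset per cell
(std 100 nm, cells sit at slightly different heights) and one x–y shift
per trajectory (std 80 nm, segmentation imprecision) are added, and
ground-truth species labels ride along for scoring.

**Geometry-free Markov-switching tracks.**  For HMM validation, hidden
states evolve as a discrete-time chain (the matrix exponential of a CTMC
generator at the frame interval), displacements are Gaussian with per-axis
variance 2 D Δt using the state at the step start, localization noise of
std 30 nm is added, and track lengths are geometric (mean 30 frames,
photobleaching-like).  The wild-type chain uses occupancies 28/56/16% at
D = 0.05/1.7/4.3 µm²/s with a 1.0 s bound dwell and 1.9 s free-SRP dwell;
detailed balance then fixes the slow RNA↔SRP exchange.  The generator's
chain-level statistics, not the HMM, define the ground truth that recovery
is scored against.

## Rendering, detection, linking

Rendering uses a parametric Gaussian PSF (σ₀ = 0.11 µm) with defocus
broadening σ(z) = σ₀√(1+(z/z_R)²), z_R = 0.4 µm, 0.08 µm pixels, expected
200 signal photons per 1.5 ms stroboscopic pulse over a uniform background
of 10 photons/px, Poisson pixel statistics × gain plus Gaussian read noise;
EMCCD excess noise is omitted.  Motion blur within the 1.5 ms pulse (RMS
< 0.12 µm even for the fastest species) is represented by a single
position sample.  Emitters photobleach irreversibly with geometric
lifetimes (mean 40 frames).  These defaults give single-spot localization
errors of ~20–40 nm depending on defocus, and are deliberately exposed in
the configuration: the original experiment used a measured PSF and
recorded background, which this parametric model replaces.  Segmentation
masks are the rasterized envelope, hole-filled and eroded by 240 nm.

Detection finds candidate pixels by band-passed local maxima, seeds each
with the gradient-based radial-symmetry center, and refines it by
maximizing the Poisson log-posterior of a Gaussian-spot + flat-background
model (flat position prior within the candidate neighborhood, wide
log-normal intensity prior); the localization uncertainty is the Laplace
posterior std and matches the repeated-measurement RMS error within ~20%.
The quality score is the log-likelihood ratio against a background-only
model; the default threshold (20) was calibrated on blank noise frames for
a well-under-5% per-frame false-detection rate, because a single false
spot late in a movie would otherwise disqualify all earlier frames through
the track-start rule.  Detections are assigned to cells through the
segmentation mask dilated by ~0.5 µm, since the eroded mask ends well
inside the membrane where many genuine spots live.

Linking minimizes summed squared displacement per frame pair (optimal
bipartite assignment) with a hard maximum step (default 5√(2 D_max Δt)),
free births/deaths beyond it, and single-frame gap closing at doubled
cost; per cell, track building starts at the first frame from which at
most one spot (two in membrane-marker mode) remains in every later frame.
The full u-track cost framework is unnecessary at ≤1–2 spots per cell.

## Diffusion-state HMM

Hidden states are diffusion coefficients; the emission for state k at step
i is an isotropic 2D Gaussian displacement with per-axis variance

    v_{k,i} = 2 D_k Δt_i (1 − t_E/(3 Δt_i)) + σ_i² + σ_{i+1}²,

where Δt_i is the frame interval (doubled across a recorded gap), t_E the
exposure (the blur factor is a 2.5% correction at 1.5 ms/20 ms), and σ the
per-localization uncertainties.  Gap steps transition with A².  Fitting is
EM: the E-step is a scaled batch forward–backward; the M-step updates the
transition matrix from expected counts (gap-step counts are split over the
unobserved midpoint, a minorize–maximize step that preserves monotone
ascent) and each D by bounded scalar optimization in log space (no closed
form exists when localization variances differ per step).  The
log-likelihood is asserted to be non-decreasing every iteration;
convergence is a relative change below 1e-8 or 1000 iterations.  The
initial-state distribution is free (stationarity is a post-fit check, not
a constraint); reported occupancies are mean posteriors over all steps.

Initialization runs five restarts and keeps the best likelihood: the first
uses D log-spaced over [1e-3, 10] µm²/s, the second quantiles of the
per-step apparent D, and the rest sorted log-uniform draws over the same
range (uniform occupancies, transition diagonal 0.95 throughout).  The
pure log-spaced-grid-with-jitter scheme was found to converge to a
slow-split/fast-merged local maximum on some datasets; mixing in the
data-driven and log-uniform starts removed this failure mode without
changing the model.

Models of size 3–8 are fitted and coarse-grained to three groups by D
thresholds 0.8 and 3 µm²/s (a tie joins the lower group): occupancies add,
coarse D and transition rows are occupancy-weighted averages, and mean
dwell times come from the coarse diagonal, dwell = Δt/(1 − A_kk).  Empty
groups are reported with zero occupancy and undefined D.  Per-frame
probability fluxes (occupancy × transition probability) in and out of each
state are reported with their balance ratio — flux balance is an emergent
self-consistency check, not a fitting constraint.  Decoding runs Viterbi
and per-position posteriors on the coarse model; positions whose maximum
posterior does not exceed 0.95 are flagged ambiguous and excluded from
spatial occupancy analysis.  Uncertainties come from a cell-level
bootstrap (the cell is the independence unit), refit warm-started from the
point estimate, with percentile intervals; a single resample degenerates
to the point estimate by construction.

## Spatial decomposition and transition events

An observed radial profile is modeled as a superposition
α·membrane + (1−α)·cytosol.  The cytosol reference is the analytic
chord-length law √(1−u²) of a uniform disc; the membrane reference is
empirical, built from membrane-marker tracks (a LacY analog confined to
the shell) or from the synthetic shell sampler, inheriting the z/x–y
jitter broadening.  A two-state HMM separates genuine marker diffusion
from tracking artifacts before the reference is built.  The synthetic
shell sampler also applies a Gaussian defocus-detectability weight in
total z (scale 0.4 µm): molecules far from the focal plane are less likely
to be detected, which is how the per-cell z offset changes the apparent
profile; the weight is disabled when the data themselves had no detection
stage (fast-mode virtual experiments).

The fitted weight is obtained by maximizing the multinomial bin likelihood
with α constrained to [0, 1], on an extended histogram covering |r| ≤ 4/3
at the standard bin width (24 bins): positions beyond the cytosol
half-width are reachable only by membrane molecules (plus jitter), so that
region carries most of the discrimination and discarding it inflates the
estimator variance several-fold.  Because normalization is by the cytosol
half-width, part of each component's mass can still fall outside the
histogram; each reference records its in-range retention and the fitted
in-range weight is converted back to a molecule fraction.  Confidence
intervals are position-level multinomial bootstraps; nearly identical
references are flagged ill-conditioned and the interval widened to [0, 1].
Mixture constructions sample both components on the cylindrical part so
the pole/mid-cell margins do not shift the composition; recovery is within
±0.05 across α ∈ {0, 0.25, 0.5, 0.75, 1} at 10⁴ positions.

Ribosome-binding and release events are Viterbi entries into and exits
from the slow coarse state.  Each keeps up to two following (arrival) or
preceding (departure) positions — the slow state (~0.05 µm²/s over 20 ms)
moves little between frames, so the neighbors share the event location —
and is discarded unless at least three displacement steps precede and
follow the transition position ("three segments" is interpreted as three
steps, i.e. four localizations, on each side; configurable).  Event and
neighbor positions are pooled with equal weight.  In the synthetic event
generator, membrane-bound complexes diffuse along the shell surface
(axial + angular) rather than radially off it; pooling the neighbors then
shifts the decomposed fraction by < 0.03.  Event decompositions use
large-sample component references generated with the same observation
model (event + neighbors), which keeps the estimator unbiased at the
experimental event counts (~200): one such construction has an intrinsic
spread of order ±10 percentage points — the same order as the uncertainties
reported for the original event samples — so validation experiments average
several independent constructions at that per-construction scale and
assess the mean recovery.

## Dual-pathway kinetics

The kinetic model allows SRP–ribosome binding anywhere in the cytosol
(fraction f_C of bindings, followed by a 3D search for the membrane) or
directly at the membrane, with release only at the membrane and a common
membrane dwell for both pathways.  Steady-state occupancy apportionment
gives the closed forms

    τ_M = φ_M · τ_bound,      τ_C = (1 − φ_M) · τ_bound / f_C,

where τ_bound is the total mean bound dwell and φ_M the membrane fraction
of bound-state occupancy: every bound molecule passes through the membrane
sub-state, only the cytosol-binding fraction through the search sub-state,
hence f_C τ_C + τ_M = τ_bound exactly.  A forward Monte-Carlo of the
two-pathway renewal process inverts the closed form within sampling error
and serves as the module's oracle.  The derived-arithmetic helpers (cycle
time as search + bound; sampling-time bound as search time over the number
of non-target ribosomes probed; target fraction as the product of the IMP
fraction and the binding-window fraction; nascent-chain growth as bound
time times the elongation-rate range; required cycle time as generation
time × SRP copies / IMP molecules per generation) are generic calculators —
the copy-number inputs behind the published 2–3 s requirement are not
reproduced here, so that calculator documents the formula, not a dataset.

## Virtual experiments and scenarios

`run_pipeline` chains the stages in three modes: `markov` (geometry-free
switching tracks straight into the HMM; spatial statistics come from the
scenario's constructed position/event sets), `fast` (Brownian dynamics +
frame-rate observation, skipping rendering), and `full` (plus rendering,
detection and linking).  Scenario presets encode the experimental
perturbations as parameter changes: wild type; FtsY depletion (bound dwell
19 s, ~90% bound occupancy, slow state delocalized from the membrane);
4.5S RNA overexpression (~90% free-RNA occupancy, empty free-SRP state);
LepB75 overexpression (~60% bound occupancy).  Every run derives all child
seeds deterministically from one root seed, writes plain-text tables and
reports, flags datasets below ~40,000 displacement steps (the observed
convergence scale of the HMM analysis), and ends with a scorecard of
estimates against the scenario's ground truth.  Reruns with the same seed
are byte-identical.

Problem sizes in the shipped tests and validation runs are chosen to keep
each experiment's statistical resolution matched to what it asserts:
recovery tests use ≥40,000 steps; the rendered-pipeline property runs use
25 cells × 3 labeled molecules × 4 s movies × 5 seeded replicates and
assert only one-sided bounds (slow-state dwell not overestimated by more
than ~40%; fastest-state D below its ground truth under confinement),
because point biases at that reduced scale are noisy.

## What the synthetic data do and do not show

The generators emulate the stated experimental conditions: geometry,
stroboscopic timing, localization noise, photobleaching-scale track
lengths, per-cell focus offsets and per-trajectory segmentation shifts,
and membrane-gated kinetics calibrated to the published derived times.
They do not model molecular crowding, inter-particle interactions,
translocon copy numbers, EMCCD excess noise, the measured PSF, real
phase-contrast segmentation, or cell-to-cell parameter variability.
Passing recovery tests therefore demonstrates that the analysis chain is
unbiased and well-calibrated under its own assumptions at realistic data
sizes — not that those assumptions exhaust real movies.  Known
limitations: the displacement HMM ignores positions relative to the cell
(states with similar D near the membrane are not separable, which is why
the spatial decomposition exists); dwell estimates at strongly reduced
rendered scale scatter widely; the bootstrap slightly under-covers at very
small cell counts; and the single-compartment reflection treats the
membrane shell as a 3D volume rather than a surface.
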