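# Methods

`confex` re-creates, at desk scale, the enhanced-sampling stack used to
characterise slow two-state conformational exchange in proteins — a ground
(G) state exchanging with a sparsely populated excited (E) state on
millisecond timescales.  Real applications of this stack need microseconds
of explicit-solvent MD; here every stage runs in minutes on synthetic
systems whose thermodynamics and kinetics are known exactly, so each
estimator can be validated against an independent oracle.

## Synthetic systems and ground truth

**Double well (1-D).**  `V(x) = B((x/a)^2-1)^2 + (delta/2) s(x/a)` with
`s(u) = sin(pi u/2)` clipped to +-1.  The tilt has zero slope at `u = +-1`,
so the minima stay exactly at `x = -a` (G) and `x = +a` (E) and their
energy gap is exactly `delta_G_true`.  Defaults: barrier `B = 7 kBT`,
`delta = 1.5 kBT`, minima at +-1.  At these conditions the minor basin
holds ~19% of the population — more than the ~3% of the real system, but
deep enough that unbiased interconversion is rare on sampling timescales
while brute-force oracles remain affordable.

**Two-state beads.**  A multi-particle toy with two reference
conformations A and B: the same double well along the normalised A->B
projection plus a harmonic restraint (default 50 energy/length^2) on the
orthogonal component, making the system effectively one slow coordinate so
that quadrature along the A->B line is exact up to a constant.

**Ground truth.**  `quadrature_free_energy` integrates the Boltzmann
weight on a dense coordinate mesh and bins it by the CV; basin
free-energy differences and separatrix locations derived from it serve as
the oracle for every biased estimate.  `brute_force_rates` launches
batches of unbiased Langevin walkers from each basin minimum and records
committed first-passage times; it is the oracle for the rate machinery.

**Dynamics.**  BAOAB-split underdamped Langevin (unit mass, reduced units
with kBT = 1, default friction 1, dt = 0.005, all seeds explicit).  BAOAB
was chosen for its accurate configurational sampling at practical step
sizes; the step satisfies `dt * friction < 1` by construction.

**Units.**  Simulations run in reduced units.  All laboratory-facing
conversions use `RT = 0.5925 kcal/mol` (R = 1.987e-3 kcal/mol/K at
298.15 K); two-state populations are quoted as percentages rounded to the
nearest integer when compared with published population statements.

## Path collective variables

The reference path discretises the A->B transition into 31 approximately
equidistant nodes (straight-line interpolation reparameterised by
root-metric arc length; the method needs only a topologically correct
initial path, not the true mechanism).  The metric is the mean-squared
deviation per particle — optionally after Kabsch superposition — so the
distance-to-path variable Z carries length^2 units.  With distances `d_i`
to the nodes and weights `w_i = exp(-lambda d_i)`:

    S = sum_i (i/(N-1)) w_i / sum_i w_i        (progress, in [0,1])
    Z = -(1/lambda) ln sum_i w_i               (softmin distance)

`lambda` defaults to `2.3 / mean(adjacent node distance)`, the customary
order-of-magnitude-per-node choice; it is always overridable.  Because the
metric is squared, refining the path by 2x in node count reduces the
adjacent distance ~4x and raises the default lambda accordingly.  On the
standard 1-D study the path spans x in [-2, 2], placing the G basin near
S = 0.25, the E basin near S = 0.75 and the separatrix near S = 0.5.  The
softmin imprints a small periodic ripple on profiles along S; the
separatrix search therefore uses prominence-based minima detection.

## Well-tempered metadynamics

Gaussian hills are deposited every `pace = 500` steps with initial height
`h0 = 0.5 kBT` and bias factor `gamma = 10`; heights decay as
`h = h0 exp(-V/(kB dT))` with `dT = (gamma-1)T`.  Hill widths follow the
sample standard deviation of the CV over a trailing 500-step window
(adaptive hills), floored to avoid needle kernels (default floor 0.02 in
S; the flat-landscape checks use 1/20 of the CV extent).

Two free-energy estimators are provided:

1. **Bias inversion**: `F = -(gamma/(gamma-1)) V_bias`, per checkpoint,
   with unvisited CV bins held at +inf and excluded from normalisation.
2. **Reweighted histogram**: each sample is weighted by
   `exp((V(s_t,t) - c(t))/kBT)` using the instantaneous bias recorded
   along the trajectory and the standard well-tempered offset c(t); this
   self-corrects the frozen deposition ripple of the inversion.

A single instantaneous profile carries ~0.3 kBT of hill-height noise, so
converged dG values are computed by tail-averaging the inversion estimates
over the second half of the run and averaging four independent walkers
(4 x 500k steps) — the multiple-walker route.  Convergence is declared
when the combined dG(t) series moves by less than 0.1 kBT over its last
quarter.  At the standard conditions this reproduces the quadrature dG
within ~0.1 kBT.

## Thermodynamics

The separatrix s* is the maximum of the 1-D profile between its two most
prominent minima (prominence >= 0.5 kBT).  Populations are Boltzmann sums
of the profile on each side; `dG = -kBT ln(P_E/P_G)` is positive when E is
minor (the G-referenced convention `dG = G_E - G_G` throughout).  Because
the barrier top is flat, moving s* anywhere within 0.2 kBT of the maximum
changes dG by well under 0.05 kcal/mol.  Two-state conversions use
`p_E = 1/(1+exp(dG/RT))` and its exact inverse.

## Infrequent-metadynamics kinetics

Rates come from biased first-passage sampling with deliberately gentle
deposition: pace 10x slower (5000 steps) and hills half as high
(0.25 kBT) as the free-energy stage, so the transition-state region stays
essentially unbiased.  Each biased first-passage time is rescaled by the
acceleration factor `alpha = <exp(V(s(t),t)/kBT)>_t`, accumulated in log
space.  Commitment requires crossing the separatrix by a 0.1 margin in S
(shared with the brute-force oracle) to avoid counting recrossings.
Lifetimes are exponential MLEs (sample means) with seeded 1000-resample
68% bootstrap intervals; validity is checked by a two-sided KS test of the
rescaled times against the exponential with the sample-mean parameter.
No Lilliefors correction is applied, which makes the diagnostic
conservative (it understates evidence against exponentiality); the test
suite verifies it is never anti-conservative.

At the standard conditions, 20 events per direction recover the
brute-force lifetimes within a factor of ~2 and the rate-ratio
`dG = kBT ln(tau_fwd/tau_bwd)` agrees with the free-energy route within
0.5 kBT.

**What actually breaks the protocol.**  On this clean 1-D system, fast
deposition alone does not corrupt the first-passage statistics: intra-well
relaxation (~0.1 time units) is far faster than even the free-energy-stage
pace (2.5 time units), and the narrow adaptive hills never reach the
barrier top.  The failure mode the diagnostic must catch is bias touching
the transition state, so the over-aggressive control protocol combines the
fast cadence with hills wide enough (0.3 in S) to span basin and barrier.
That drives the median KS p over 20 runs below 0.05 while the compliant
protocol stays well above it.

## Replica-averaged restraints

N replicas (default 4) evolve in parallel under the model energy plus one
shared penalty `E = epsilon sum_j (mean_r delta_j(x_r) - target_j)^2` on
the replica-averaged observables — the maximum-entropy way to impose
ensemble-averaged data, since each copy feels only 1/N of the restraint
gradient.  The forward model is a seeded random linear map from
coordinates to observables with per-observable scales and nucleus-type
group labels (Ha, HN, N, C', Ca); linearity makes the maximum-entropy
properties exactly testable.  Real chemical-shift predictors are out of
scope.  `epsilon` defaults to 24 in reduced energy per squared observable
unit, applied every step (no time-averaging window); the restraint is
harmonic.

The standard restraint study lowers the barrier to 3 kBT so that an
E-started unrestrained ensemble measurably leaks into the deeper G basin
within the run, while targets synthesised from a harmonic E-basin
reference ensemble (plus 10%-of-scale noise) hold the restrained ensemble
at >= 80% probability mass in the E window of S — robustly across
(N=4, eps=24), (N=2, eps=24) and (N=2, eps=12).

## Ratchet (adiabatic-biased) escape

The ratchet potential is zero whenever the reaction coordinate
`rho = |x - bound pose|` sets a new record and `(k/2)(rho - rho_best)^2`
otherwise, so it never performs work along forward moves — escape
pathways are chosen by the system's own fluctuations.  Force constants 20
and 50 are both run to check pathway robustness.

The escape toy is a 3-D spherical soft wall (radius 3, height 8 kBT) with
two angular gaps: a fully open wide gap (half-width 0.8 rad) and a
narrow, sterically hindered one (0.28 rad, residual wall ~2.2 kBT).  The
bound pose sits 0.8 off-centre on the hindered side, as a buried binding
cavity sits relative to its dominant exit; this also means the ratchet
coordinate increases along the wall toward the wide opening.  Note that
with an off-centre bound pose the ratchet itself steers along the wall
toward larger rho — placements on the far side of a target opening
suppress that exit.  Under these conditions 18-20 of 20 seeded runs exit
through the wide opening at both force constants, and the median escape
time decreases with k.

## Tunnels

Structures (or synthetic shells) become sets of van der Waals spheres;
PDB text is parsed with Biopython, waters always removed, ligands
optionally stripped, altloc A kept, Bondi-style element radii (unknown
elements fall back to 1.7 A with a warning).  The clearance field on a
regular grid (default spacing 0.4 A) is the distance to the nearest
sphere surface, computed from the 24 nearest centres — exact whenever the
radius spread is below the neighbour-distance slack, which holds for vdW
radii.  Tunnels are maximum-bottleneck (widest) paths from the cavity
seed to the grid boundary via priority-first search over cells with
clearance above the probe radius (default 0.9 A).  Because the exterior
of any closed shell is a single connected region, distinct exits cannot
be separated by boundary connectivity; instead tunnels are extracted
iteratively, blocking a corridor around each found tunnel's wall passage
(radius 2x its bottleneck) and re-searching.  Each tunnel reports its
centerline, clearance profile, bottleneck and arc length; the search is
validated against an exhaustive threshold-bisection oracle (the largest
clearance threshold at which seed and boundary stay connected).  Tunnel
ensembles are grouped by average-link hierarchical clustering of mean
distances between arc-length-matched centerlines, clusters ranked by
population with the widest member as representative.

## Numerical choices and degenerate inputs

- Gaussian evaluation subtracts the minimum distance before
  exponentiation (softmin) and accumulates acceleration factors with
  log-sum-exp; no overflow at any bias magnitude.
- Divergence (energy above 1e8 or non-finite) aborts a run with a
  diagnostic rather than propagating NaNs.
- Degenerate inputs raise: coincident path endpoints, zero bead
  displacement, non-positive lifetimes, monotone profiles without a
  barrier, sealed cavities (empty tunnel list), empty ensembles.
- Identical seeds reproduce every stochastic result bit-for-bit on one
  platform.

## Problem sizes

Defaults were sized so each stage gives statistically decisive results:
metadynamics 4 walkers x 500k steps; kinetics 20 events per direction
plus 20 brute-force walkers per direction; the aggressive-protocol
control 20 runs x 9 events; restraints 4 (or 2) replicas x 40k steps per
configuration; escapes 20 seeds per force constant; shells of 600-800
spheres on grids of ~50^3.

## Known limitations

- The synthetic systems have a single slow coordinate and a perfect CV;
  they cannot probe CV-quality failure modes (hidden barriers, projection
  artefacts) that dominate real applications — which is also why the
  over-aggressive kinetics control must widen its hills to misbehave.
- The minor-state population (~19%) is an order of magnitude larger than
  in the motivating protein system; desk-scale statistics would be
  prohibitive at 3%.
- The linear observable model omits the nonlinearity and noise structure
  of real chemical-shift predictors; restraint results demonstrate the
  maximum-entropy machinery, not predictor accuracy.
- Tunnel geometry is static (one sphere set per model); no per-frame
  dynamic tunnel tracking.
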