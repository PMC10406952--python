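# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `hydrashell`. Units are Å, ps, kJ/mol and elementary
charges e throughout; the Coulomb prefactor is k_e = 1389.35458
kJ·Å/(mol·e²) and k_B = 8.314462618×10⁻³ kJ/(mol·K).

## Domain model and conventions

Configurations live in a periodic **cubic** box; positions are stored wrapped
into [0, L) and every inter-site vector is taken by the minimum-image
convention (each displacement component mapped into [−L/2, L/2)). This is the
standard convention when interaction cutoffs are below half the box edge;
triclinic cells and binary trajectory formats are out of scope.

Waters are rigid four-site molecules with the published TIP4P/2005 geometry:
O–H 0.9572 Å, H–O–H 104.52°, a massless M charge site on the bisector
0.1546 Å from the oxygen; charges +0.5564 e per H and −1.1128 e on M, LJ on
the oxygen (ε = 0.7749 kJ/mol, σ = 3.1589 Å). The molecular dipole — the
charge-weighted first moment about the oxygen — is then 0.4795 e·Å ≈ 2.30 D,
which is also the default moment of the point-dipole particles in the toy
simulator (0.48 e·Å). Three-site waters read from files get the negative
charge on the oxygen instead.

GRO files are written in nm with four decimal places (the format permits
widths beyond Gromacs' default three), so coordinates round-trip to 10⁻³ Å;
the reader infers the column width from the decimal-point spacing and accepts
standard three-decimal files. Multi-frame XYZ carries `box=<L> t=<t>`
key–value metadata on the comment line, coordinates in Å.

## The toy dipolar-shell simulator

The Metropolis simulator is a deliberately minimal model of one hydration
shell: n point-dipole particles around a fixed central charge q, with energy

* ion–particle Lennard-Jones, 4ε[(σ/r)¹² − (σ/r)⁶] (defaults ε = 0.79
  kJ/mol, σ = 2.5 Å, the weak-dispersion cation–oxygen scale);
* charge–dipole, −k_e q (p·r̂)/r², so a dipole pointing radially away from a
  cation is bound;
* dipole–dipole, k_e [p_i·p_j − 3(p_i·r̂)(p_j·r̂)]/r³ over all pairs;
* an optional harmonic radial tether ½k(r − R₀)² emulating confinement to a
  thin single-layer shell (R₀ defaults to the LJ minimum, 2^{1/6}σ);
* a hard-core exclusion between particles (default 2.0 Å). Point dipoles
  with no inter-particle repulsion collapse head-to-tail to −∞ energy; the
  hard core is the standard regularisation and stands in for the water–water
  excluded volume that the dipole reduction discards.

Moves are single-particle translations (Gaussian, σ = 0.15 Å) or axis
perturbations renormalised to unit length (σ = 0.4 rad), auto-tuned toward
~40 % acceptance during equilibration and then frozen. The energy is tracked
incrementally and cross-checked against a full recomputation (agreement to
10⁻⁶ kJ/mol is asserted in tests). Default conditions: T = 300 K, 1000
equilibration and 4000 production sweeps, sampling every 10 sweeps.

What the model reproduces: ⟨cos θ⟩ = 0 by symmetry at q = 0, monotone growth
of dipolar order with q, and spontaneous bond-orientational ordering at
composite occupancies (the charged n = 6 shell relaxes to the octahedral
Thomson arrangement). What it does not: explicit hydrogen bonds (dipoles have
no protons), exchange with a bulk reservoir (n is fixed), long-range
electrostatics, and any quantitative correspondence to all-atom force-field
numbers — analyses needing explicit H sites use the rigid-water fixtures
instead, and no parameter of the simulator is calibrated against published
simulation values.

The charge-jump protocol equilibrates independent replicas at q_before
(per-replica seeds derived from the base seed), switches the central charge
instantaneously, and records the ensemble-averaged dipolar order and
nearest-neighbour dipole–dipole pair energy during relaxation — 50 replicas
by default, scaled to 8–12 in the test suite for speed.

## Shell structure

g(r) is the shell-volume-normalised ion–oxygen pair histogram averaged over
frames and ions (default bin 0.02 Å), with the partner density taken as the
global oxygen number density of the box. The running coordination number is
exposed both as the direct cumulative count (reported at bin centres with a
half-bin correction) and as the integral 4πρ∫g r²dr; the two agree within 2 %
on homogeneous test systems, and the **direct count** is what `locate_shell`
reports as n. Extrema are refined on a three-point parabola through the
discrete extremum; the first-minimum search runs only beyond the first peak
and requires a depth exceeding one noise standard deviation (estimated from
the profile tail) so that shallow shoulders of weakly bound shells are not
mistaken for shell boundaries. An isolated shell whose g drops to a flat
floor takes the first point attaining that floor as r1; flat or monotone
profiles are flagged as errors rather than guessed at.

The translational order parameter integrates |g − 1| on the density-scaled
abscissa ξ = rρ^{1/3} up to ξ_c = 2.843 (trapezoid on a 4096-point resampled
grid; the first bin's value is extended to ξ = 0). ρ is the global oxygen
density, matching the one-component order-map convention from which the
ξ_c value comes.

## Hydrogen bonds

The Luzar–Chandler criterion: donor and acceptor oxygens closer than 3.5 Å
(minimum image) and the angle between the donor's O–H bond vector and the
donor-O→acceptor-O vector below 30°. The angle vertex sits at the donor
oxygen; both donated and accepted bonds count toward a water's
N_H-bond^HW-HW (role-agnostic, so a ring water donating once and accepting
once scores 2). A bridging water is a non-shell water between r1 and a
second limit (the second minimum of g(r) when resolvable, else r1 + 1.5 Å)
H-bonded to at least two distinct first-shell waters; counts are reported
per ion, with a per-shell-water normalisation alongside.

## Bond-orientational order

Pair angles at the ion are histogrammed on (0, π) (720 bins), smoothed with a
Gaussian kernel (default 5°) and normalised by the uniform-sphere pair-angle
density sin φ/2 **smoothed with the same kernel** — smoothing only the
numerator would bias g(φ) at the 0 and π boundaries, which matters exactly in
the uniform case that defines the zero of entropy. Instantaneous single
configurations and time-averaged stacks of configurations are both accepted;
the kernel plays the role that thermal broadening plays in long trajectory
averages, and its width is a fixed, logged analysis parameter.

The entropy is evaluated as s_φ = −(n/4)∫[g ln g − g + 1] sin φ dφ with
0·ln 0 = 0. The prefactor is the per-particle two-body excess entropy of a
point pattern on a sphere, i.e. −πρ_s R²∫ with the surface density
ρ_s = n/(4πR²): it gives exactly 0 for uniform coverage and scales linearly
in n at fixed pattern, which is all the downstream uses (ordering
comparisons, the Rosenfeld-like fit) require. A `literal=True` switch
evaluates the variant with ρ = n/(πR²) and no area factor for cross-reading
against tabulations that print that convention; the two differ by the fixed
factor 4/R².

The characteristic angle φ_ion is the parabolic-refined global maximum of
P(φ), accepted only where g exceeds 1.2 — P(φ) of a structureless shell peaks
at 90° through the sin φ measure alone, so a raw argmax would assign a fake
characteristic angle to uniform shells instead of flagging them.

The Thomson solver minimises Σ 1/r_ij for n unit charges on the unit sphere
by L-BFGS-B on radially normalised ambient coordinates (the analytic gradient
projected onto the sphere's tangent space), best of 20 random restarts.
Energies reproduce the closed-form tetrahedron (3.674235) and octahedron
(9.985281) values to 10⁻⁶ and are seed-independent at that level for n ≤ 12;
there is no global-optimality guarantee for large n. φ_T is the median over
particles of the nearest-neighbour pair angle, which is exact for the
regular solids and robust for near-degenerate solutions.

## Kinetics

The residence correlation uses the intermittent indicator (re-entries count),
every `origin_stride`-th frame as a time origin, and lags up to half the
trajectory by default. The stretched-exponential fit is unweighted nonlinear
least squares on points with P above a floor (default 0.01), with τ
initialised at the 1/e crossing, β = 1, P₀ = 1, and bounds 0 < β ≤ 2,
P₀ ≤ 1.5. Reference scales for neutral particles (τ_w, D_w) come from the
same operations on simulator runs with the charge switched off.

The conditioned MSD unwraps coordinates by accumulating minimum-image
increments, conditions particles on shell membership at each origin, and
averages over multiple origins. D₁ is the least-squares slope (intercept
free) divided by 6, restricted to 8 ≤ MSD ≤ 16 Å² — the lower bound keeps the
fit in the diffusive regime, the upper keeps the displacement local to the
shell; both bounds are in Å², the natural unit of an MSD window. An MSD that
never reaches the window is an error, not a silent extrapolation.

The Rosenfeld-like fit is linear regression of ln τ on s_φ (τ₀ from the
intercept, α the slope); the Jones–Dole fit is linear least squares of
η/η₀ − 1 on [√c, c]. Both refuse degenerate designs.

## Energetics

`pair_potential` sums LJ between one designated site per group (oxygens, or
the ion) and Coulomb over all charged site pairs, minimum-image, with no
cutoff truncation for the pair analyses (a cutoff parameter exists for
whole-box scans). Attraction is negative everywhere. E_w-w averages over
neighbouring shell-water pairs (O–O below 3.5 Å) and exports the full pair
energy distribution for unimodality checks. ΔE_ion-water is implemented as
the magnitude of the mean ion–(single shell water) interaction energy — a
deliberate, documented operationalisation chosen because the λ_HB crossover
condition ΔE_ion-water = E_H-bond compares like-for-like pair energies;
whether a reference-state subtraction is intended elsewhere is not decidable
from the available description. E_H-bond averages `pair_potential` over
(unordered) Luzar–Chandler-bonded pairs and reports a ±1 standard-deviation
thermal band.

A caveat verified while building the fixtures: pairs selected by the
*geometric* H-bond criterion in a randomly oriented box average to a
*positive* energy, because random acceptor orientations are frequently
repulsive — the familiar ≈ −20 kJ/mol bond strength belongs to thermally
relaxed liquids. The `hbond_dimer` generator therefore produces
near-minimum-energy dimers (donor O–H on the O–O axis, acceptor bisector
tilted ≈ 50°) for physically meaningful E_H-bond values; the random box
remains the fixture for detection-counting logic. Similarly, the far-field
ion–water Coulomb energy of a rigid aligned water falls off as the
charge–dipole 1/d² (measured exponent ≈ −1.96 over 4–10 Å); statements that
thermally averaged shell energies scale roughly as 1/d involve orientation
and occupancy co-varying with d and are not a property this fixture can or
should reproduce.

## Phase maps

Scan grids follow the reference construction: cation charge q = k·δq with
δq = 0.17 e for k = 1…20 (maximum 3.4 e), σ_cation-O shifted in steps of
δσ = 0.04 Å, 10 cations per 3456 waters (0.16 mol/kg), and the smallest
integral anion count that makes the box exactly neutral. With the default
anion charge magnitude 0.85 e this yields anion counts 2, 4, …, 40; an anion
charge of 0.75 e admits no integral neutral count for these charge levels and
raises — both magnitudes appear in the source force-field description, and
the package prefers the one consistent with the printed counts while exposing
the other through the `anion_charge` argument. A small-fractional-charge
preset (δq = 0.05 e, anion charge equal to the cation's, equal counts) covers
the low-q refinement region.

χ = ∂n/∂d uses central differences (one-sided at boundaries). The
transformation line takes, per d, the parabolic-refined maximum of |∂n/∂q|
after 3-point smoothing, flagging flat-derivative columns as gaps rather than
inventing a crossover. λ_HB(q) is the monotone-interpolated root of
ΔE_ion-water(d) = E_H-bond per charge level, with band edges from
E_H-bond ± band; unbracketed levels leave per-q gaps. Generic crossover
contours (ratio = 1 level sets) use marching squares with linear
interpolation; an empty contour is a valid result, and disconnected segments
are preserved.

## Synthetic data: what passing tests do and do not show

The generators define the test conditions: uniform sphere samples (the
pair-angle null model with its analytic (1 − cos φ)/2 law), exact Platonic
vertex sets, Brownian walks with known D, stretched-exponential occupancy
series with known (τ, β), two-state Markov occupancy chains with a closed-form
autocorrelation, and packed rigid-water boxes (O–O floor 2.2 Å) with optional
verbatim motifs. Against these, the pipeline's estimators recover their
generators (τ and β to 5 %/0.05 at the seeded noise level, D within the
window estimator's 10 %, regression coefficients exactly on noiseless data),
and the toy simulator passes symmetry, monotonicity, energy-bookkeeping and
temperature-reweighting diagnostics. None of this certifies force-field
accuracy on real solutions: the synthetic data have no polarisability, no
bulk phase coexisting with the shell, idealised noise, and desk-scale
statistics. What the tests do establish is that the *operations* — the
estimators, criteria, fits and constructions — are implemented correctly and
behave continuously under the perturbations the generators control.

## Problem sizes

Defaults used by the test suite and the acceptance script: shells of 4–12
particles, 10⁴-sweep Monte Carlo chains, 8–12 charge-jump replicas, 500
Brownian walkers over 2000 steps, 60-water boxes, 200-frame uniform-shell
stacks, and 20-point scan grids. These sizes were chosen so that every
statistical assertion has comfortable margins while the whole suite completes
in well under five minutes of single-core compute; all of them scale up
through ordinary parameters.
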