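# Methods

This note documents the models, the numerical choices and the open design
decisions behind `alchemkit`, and states what the bundled toy systems do
and do not probe.

## Model systems

All Hamiltonians are configurational only. Every estimator in the package
consumes ensemble averages of configuration-dependent observables, and the
kinetic contribution cancels identically in each ΔG, so momenta are never
represented and sampling is Metropolis Monte Carlo rather than dynamics.
Units are kJ mol⁻¹, nm, elementary charges and kelvin throughout;
k_B = 0.00831446 kJ mol⁻¹ K⁻¹, and the default temperature is 298 K.

### Coupling and parameter interpolation

Two independent coupling axes live on the unit square: λ drives the first
perturbed species (a "growing" interaction site: dummy at λ = 0, fully
interacting at λ = 1) and κ the second (a removable water-like particle:
dummy at κ = 0, present at κ = 1). Pair interactions interpolate the
interaction parameters themselves: charges linearly,
q(c) = (1−c)q_A + c·q_B, and the Lennard-Jones coefficients linearly on
their square roots, √C12(c) = (1−c)√C12_A + c√C12_B (likewise C6). With
geometric combination rules the pair coefficients are then simple products
of the per-atom interpolated roots, and the four corner states recover the
plain end-state physics exactly.

### Soft-core form

The pair interaction is a Beutler-style soft core,

    E_LJ = C12/D² − C6/D,      D = r⁶ + α_LJ Λ² C126,
    E_C  = f q_i q_j / √(r² + α_CRF Λ²),

with α_LJ = 0.5 and α_CRF = 0.5 nm² by default and an optional
reaction-field correction (off by default). Two conventions had to be
fixed where the source formulation is ambiguous:

- **Cross-axis softening.** Each perturbed atom carries a de-coupling
  extent Λ_k — its distance from the fully interacting end of its own axis
  (1−c when the A state is the null/dummy end, c when B is null,
  4c(1−c) when both ends interact, 0 for unperturbed atoms). The pair
  combines them as Λ² = 1 − (1−Λ_i²)(1−Λ_j²). This reverts exactly to the
  single-axis soft-core expression when only one partner is perturbed,
  vanishes at every corner (plain physics at end states), and — unlike a
  plain product — keeps the softening alive on the mixed edges (λ interior,
  κ = 1), where a growing particle against a fully present partner would
  otherwise regain its r → 0 singularity and a divergent ⟨∂H/∂λ⟩.
- **Soft-core radius.** C126 = C12/C6 is evaluated from the pair's
  *reference* coefficients: for an atom with a null end, the fully
  interacting end's parameters. Using the interpolated coefficients
  instead makes C126 collapse to zero exactly at a dummy endpoint,
  silently removing the soft core where the endpoint catastrophe lives;
  with the reference radius, ⟨∂H/∂κ⟩ at κ = 0 (and all edge states) stays
  finite.

All coupling derivatives are analytic (chain rule through the interpolated
roots, the extents and the reference radius) and are validated against
central finite differences (step 10⁻⁶) in the test suite.

### The Gaussian family

`QuadraticSystemSpec` defines H = ½xᵀA(λ,κ)x − b(λ,κ)ᵀx with A positive
definite on the unit square. Its absolute configurational free energy is
closed form, G = ½k_BT ln det A − (d/2)k_BT ln(2πk_BT) − ½bᵀA⁻¹b, so
free-energy differences between any two coupling states are exact
reference values. Bundled members: a 1D well with stiffness interpolating
100 → 400 kJ mol⁻¹ nm⁻² (ΔG = ½k_BT ln 4), a genuinely coupled 2D family
(off-diagonal stiffness ∝ λκ), a pair of offset wells for the EDS tests
(exact gap ½k_BT ln(120/100) + 4 kJ mol⁻¹), and a "curved-profile" well
whose stiffness carries a narrow Lorentzian bump
(k = 100 + 2400/(1 + 300(λ−0.6)²)); the bump makes the 10-point trapezoid
error of TI (+0.34 kJ mol⁻¹) an order of magnitude larger than the Monte
Carlo noise at the study sizes, so the dense-profile advantage of X-TI is
a real effect, not a seed accident.

### The four-state clash toy

`clash_toy()` is the desk-scale analogue of a binding-site water displaced
by a growing side chain: a fixed methyl-sized grower at the origin
(σ = 0.3 nm, ε = 1 kJ mol⁻¹, q_B = +0.1, coupled to λ), a mobile
SPC-oxygen-like water particle (coupled to κ, q_B = −0.1) restrained to
the grower's site with the production force constant
500 kJ mol⁻¹ nm⁻², and a fixed SPC-like background particle at 0.35 nm
(q = +0.1) that gives the water surroundings to interact with when the
grower is a dummy. The water moves in one dimension, keeping the
deterministic quadrature oracle (−k_BT ln ∫e^{−H/k_BT}dx, relative
tolerance 10⁻¹⁰) cheap and exact.

Corner labels follow the benchmark convention G/A (grower dummy/present)
× D/H (water dummy/present): GD = (0,0), GH = (0,1), AD = (1,0),
AH = (1,1). Because the grower interacts only with the water, the κ = 0
edge (GD→AD) is exactly zero — the easy test case degenerates to a null
perturbation — while the κ-edges, the κ = 1 edge and both diagonals are
nontrivial; the hardest leg is GD→AH, where the end states' dominant
configurations exclude each other sterically.

**Strain metric.** At AH the restraint (minimum at r = 0) and the
water-grower repulsion fight: the minimum-energy distance is ≈ 0.29 nm,
far outside the restraint target. Note that the Boltzmann weight *below*
the LJ minimum distance 2^{1/6}σ is necessarily large (the restraint force
is inward and the LJ force vanishes at its own minimum, so the combined
minimum always sits below 2^{1/6}σ); the package therefore quantifies the
clash as the probability of penetrating the strongly repulsive core (pair
LJ above 10 k_BT), which is < 0.05 whenever the steric wall is respected.

## Sampling

Metropolis Monte Carlo with single-particle displacement moves; the
proposal half-width is tuned toward an acceptance fraction of 0.3–0.5
during burn-in (default 10% of the trajectory) and then frozen, so the
production phase obeys detailed balance exactly. Frames are recorded every
10 moves by default. Each recorded frame carries the total energy, both
coupling derivatives, the end-state energies along the perturbation axis
(hence ΔV_BA), cross-energies at requested neighbour states, and — for
X-TI — the probe-grid energies and derivatives, all computed on the fly
(vectorized over the probe grid). Identical (seed, config, system) inputs
give bit-identical series. Starting configurations come from a coarse
grid scan for the state's energy minimum: at strongly coupled states the
region between the grower and the background particle is a caged local
trap that a badly placed start cannot leave.

The EDS reference state is sampled with the same machinery on
H_ref = −(k_BT/s) ln Σᵢ e^{−s(Hᵢ−Eᵢ)/k_BT} (log-sum-exp with max
subtraction). For EDS-TI the recorded reference derivative includes the
contribution of λ-interpolated envelope parameters,
dH_ref/dλ = Σ pᵢ(∂Hᵢ/∂λ − dEᵢ/dλ) + (ds/dλ)(Σpᵢaᵢ − H_ref)/s.

## Estimator numerics

- **BAR.** The self-consistency residual ln Σ f(w_R + C) − ln Σ f(w_F − C)
  is strictly decreasing in C; a sign-changing bracket from
  exponential-averaging bounds plus Brent's method finds the root to
  |residual| < 10⁻¹⁰, and ΔG = C − k_BT ln(n_R/n_F) (the correction
  vanishes for equal-length runs). Errors come from re-solving on ten
  contiguous block pairs. A missing bracket after bracket expansion raises
  an overlap error instead of returning a number.
- **TI.** Trapezoidal rule; the per-point half-interval weights Δλ_i make
  the weighted profile sum identical to the integral, and the propagated
  error √Σ(σ_iΔλ_i)² matches the effective-error weighting of the
  convergence criteria. A grid that does not span [0, 1] is refused —
  extrapolation is never silent.
- **X-TI.** Defaults to 101 probes; per-source errors from 100 seeded
  bootstrap resamples (the same resamples across probes, preserving the
  probe-to-probe correlation of a prediction). A probe coinciding with a
  simulated point is that state's plain average bit-for-bit. Elsewhere the
  per-source predictions are combined by inverse-variance weighting over
  the **bracketing** sources only: distant sources can be
  "pseudo-converged" — nearly flat weights within the wrong ensemble, so
  effective sample size and bootstrap error look excellent while the
  estimate is biased — and restricting to the bracketing states removes
  exactly those contributions. When the bracketing sources disagree beyond
  their stated errors the combined error is inflated by the χ² scale
  factor. The *integral* error is taken from bootstrap replicates of the
  whole profile carried through combination and trapezoid integration:
  the 101 probe errors are nearly fully correlated (every source predicts
  all probes from the same frames), and the independent-point propagation
  would understate the integral error by an order of magnitude.
- **EDS.** ΔG = −k_BT ln[⟨e^{−(H_B−H_ref)/k_BT}⟩/⟨e^{−(H_A−H_ref)/k_BT}⟩]
  with max-subtracted exponentials; errors by block averaging of the
  log-ratio over 16 contiguous blocks; an overlap warning is attached when
  either end state is carried by fewer than 10 effective frames. The
  per-leg form G_end − G_ref is also exposed for the EDS-TI cycle sums.
- **EDS-TI.** End-state profiles by exponential reweighting of the
  recorded per-end-state derivatives; diagonals as
  −ΔG_EDS(start) + ΔG_TI + ΔG_EDS(end) with quadrature error propagation.
  On the clash toy the study conditions interpolate E linearly along λ and
  hold s constant at 0.05: a λ-dependent s adds a (1/s)-amplified ds/dλ
  term to the reference integrand that dominates its curvature at desk
  scale, and the two end pairs tolerate a common smoothness.
- **2D-TI.** The landscape is filled row-major from G(0,0) = 0; each node
  combines up to three predecessor estimates (diagonal with both
  derivatives, a λ-step, a κ-step) by the exponential average
  −k_BT ln((1/m)Σe^{−G_i/k_BT}), with 1/m for the m estimates available
  at edges. Each step uses a trapezoidal increment (the mean of the
  predecessor's and the target node's derivative), which makes the surface
  exact for separable derivatives linear in their own variable and closes
  the four-corner cycle identically. Corner errors propagate the
  block-average point errors along an L-shaped edge path.

Every reweighted quantity reports the effective sample size
(Σw)²/Σw²; exponential averages use max subtraction throughout.

## EDS parameter search

The alternating (E, s) scheme starts from a deliberately low s = 0.002 and
a manual offset estimate E = ⟨ΔV_BA⟩ from a short unbiased state-A run. A
sampling round (default 2000 MC moves, continuing the trajectory) is
followed by one update: in the offset phase E moves toward the
undersampled state by max(k_BT, 0.1|E|)·2(ratio_A − ½); in the smoothness
phase s is lowered ×0.9 while transitions are scarce (< 10 per round) and
raised ×1.05 when they are abundant and the ratio balanced, with a small
accompanying offset correction; the refinement phase applies ±2%
alternating corrections and has balanced-and-abundant sampling as an
exact fixed point. A phase advances after its criterion holds for 10
consecutive rounds (the offset phase also hands over when transitions are
absent for 10 rounds, since balance is unreachable without them).
Convergence is assessed mainly on the s series: relative drift below 5%
over the trailing 50 rounds, plus a nonzero trailing transition count —
the search never reports success while one direction of transitions is
dead. If s falls below 10⁻⁴ the search flags the steric-clash failure
mode (the reference state no longer samples the relevant phase space).
All constants are exposed on `SearchSettings`.

Frame-to-state assignment compares offset-levelled energies,
sign(ΔV_BA − E). At desk scale the end-state gap is not dominated by the
instantaneous fluctuations (unlike solvated MD, where ΔV_BA swings by
hundreds of kJ mol⁻¹ and its raw sign flips), so the raw-sign rule would
label every frame identically whenever |E| exceeds the fluctuation scale;
the offset-levelled rule reduces to it at E = 0 and matches the
envelope's own bookkeeping of which state dominates H_ref.

On the bundled well pair the search balances the ratio to 0.5 and
plateaus s within 200 rounds; on the clash diagonal the initial offset
estimate explodes (the unbiased A-ensemble samples configurations whose
B-state energy is astronomically repulsive), E then chases the gap at 10%
per round, transitions never appear, s collapses to the floor and the
failure is reported — the qualitative behaviour of the benchmark's
parameter-evolution plots.

## Convergence and prolongation

The retrospective algorithm splits the allowed total deviation and total
error (½k_BT each) evenly over the contributions — one per λ-point for
TI/X-TI, one per interval for BAR (a slightly stricter budget than
splitting the squared error). Starting from the minimal length it
repeatedly prolongs the largest accuracy violator (both flanking points
for a BAR interval) until none remain, then processes the precision
criterion the same way; ties resolve toward the lowest λ, and a
contribution already at its maximum available length marks the plan
unconverged instead of looping. The predictive rule greedily assigns a
fixed budget one increment at a time to the contribution with the largest
effective error σ_jΔλ_j under a 1/√n decay of σ with assigned increments.

## Error estimators

Block averaging uses the successive pairwise-averaging (blocking)
transformation; the reported error is the maximum blocked standard error
over all levels retaining at least eight blocks — a deterministic,
conservative proxy for the blocking plateau (validated against white
noise and an AR(1) process with ρ = 0.9). The bootstrap uses 100 seeded
resamples by default.

## Cycle metrics

Σ is the sum of absolute cycle closures and Ω = (1/N_cycles)Σ|closure|/N_legs;
edges traversed against their stored direction flip sign, and both
summaries are invariant under reversing any edge. The bundled benchmark
fixtures (pairwise estimates and closure rows of the published
tripeptide×water study at full length and at a 20-ns budget) validate the
arithmetic: the acceptance-ratio network reproduces its printed closures
exactly, Σ = 1.4 and Ω = 0.09 → 0.1 at full length, Σ = 4.1 and
Ω = 0.255 → 0.3 at the 20-ns budget. Rows whose printed closures are not
rounding-consistent with their printed pairwise inputs (e.g. the TI row's
Σ) are validated from the closure columns only.

## Problem sizes of the test suite

The suite runs 2×10⁴–2×10⁵ MC steps per coupling state (recording every
5–10 moves), 5–21 states per 1D path, 17 reference states for the
clash-toy EDS-TI diagonal, 10×10 (Gaussian family) and 12×12
(clash toy, clustered where the profiles are steep) grids for 2D-TI, and
200 search rounds of 2000 moves. All statistical acceptance checks are
3σ tests against exact oracles with honestly propagated errors; the
whole suite completes in about five minutes on one CPU.

## What the toys do and do not show

The toy systems reproduce the *structural* difficulties of the benchmark
problem — the endpoint singularities handled by the soft core, the sharp
TI profiles that punish sparse grids, a steric clash that starves one EDS
end state and collapses the smoothness search, and reweighting overlap
loss — with exact reference values. They do not contain solvent degrees
of freedom, long-range electrostatics, conformational entropy of a real
peptide, or MD integrator/thermostat effects; passing the suite validates
the estimators, their error models and their failure diagnostics, not the
force-field physics of any particular molecular system.

## Known limitations

- Multistate envelopes (more than two end states) are sampled and
  recorded but no multistate free-energy production path is provided.
- The reaction-field term is a minimal optional correction; no cutoffs,
  pair lists or periodic boundaries exist.
- X-TI's bracketing combination deliberately discards distant sources;
  on profiles with basin-changing transitions the reweighted prediction
  between sources can remain biased if the sources themselves do not
  sample both basins (the χ² inflation widens the reported error in that
  case, it does not remove the bias).
- Automated placement of *new* λ-points is out of scope; the prolongation
  algorithms only extend existing windows.
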