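# Methods

## The solubility–diffusion integral

The ISD model treats permeation as 1D diffusion over the free-energy
profile w(z) (kcal/mol, zeroed in bulk water) with position-dependent
diffusivity D(z) (Å²/ns).  The resistance integral ∫ exp(+βw)/D dz is
evaluated by composite trapezoid on the finer of the two native grids
(profiles typically arrive pre-binned at 0.1–0.2 Å), entirely in log space
(`logsumexp` with trapezoid weights), so barriers of tens of kcal/mol are
exact to floating precision rather than overflowing.  Permeability is
converted once, at result assembly, with 1 Å/ns = 10 cm/s.  Default
integration bounds are the full common grid range; an explicit membrane
span (z₁, z₂) can be supplied.  Trapezoid discretization error scales as
h²; at 0.2 Å spacing on a barrier of width ~3 Å it is a few tenths of a
percent, at 0.05 Å below 0.1% (tested against 10× refinement).

Profiles are symmetrized before use — bilayers with identical leaflets
give statistically symmetric profiles — by averaging p(z) with p(−z) after
recentring the grid midpoint to z = 0; the |p − sym| residual is the
conventional error estimate.  PMFs are re-anchored so the mean over the
outermost 10% of each tail is zero, giving the bulk reference the ISD
integral needs.  Diffusivity profiles are symmetrized by the same
arithmetic mirror average; a harmonic mean would be defensible too, but
the choice only matters where D is strongly asymmetric, which the error
bars would flag first.

## Ionization states

Macrostate fractions follow sequential Henderson–Hasselbalch: with
macroscopic pKas ordered from the most acidic dissociation, the state that
has lost k protons carries log₁₀-weight Σ_{i≤k}(pH − pKa_i).  Microstates
are nodes of a deprotonation graph whose edges carry microscopic pk
values; weights are products of 10^(pk − pH) protonation factors along any
path from the fully deprotonated reference.  Path independence is exactly
cycle closure — the signed pk sum around every independent cycle
(networkx cycle basis) must vanish — validated at model construction
(default tolerance 10⁻⁶ for assembled models, configurable for
experimental inputs, which close only approximately).

The shipped tetracycline model uses the titration pKas (3.33, 7.75, 9.61)
for the macrostate ladder and the model-compound microscopic values
(pk21 = 5.97, pk12 = 8.8, pk13 = 7.80, with pk31 ≈ pk21) only through the
pH-independent tautomer ratios f_N/f_Z = 10^(5.97−8.8) and
f_Z′/f_Z = 10^(5.97−7.8).  The two data sources are not mutually exact —
the microscopic values come from different model compounds — so the stored
edge pks are rescaled such that the lumped macrostate ladder reproduces
the titration pKas exactly while the tautomer ratios equal the microscopic
differences.  This is the same combination a hand calculation performs
when it splits the zero-charge fraction by 1 : 10^−2.83 : 10^−1.83.
Charged macrostates are lumped single states unless the user supplies
their tautomer structure.  pH is treated as exact; no activity
corrections.

`assignment_variants` builds the documented alternatives for sensitivity
analysis: the model-compound assignment (`leeson`), the same with the
roles of pk12/pk13 exchanged (`stephens-like-swap`), and the two naive
per-site uses of the macroscopic values (`naive-forward`,
`naive-reverse`).  The naive variants move the computed effective
permeability by up to ~3 orders of magnitude, which is why the package
refuses to conflate macroscopic and microscopic constants silently.

## Effective-permeability protocols

pH-partitioning sums f_s·P_s.  States without computed profiles may
declare `proxy_of`: their permeability (and, for BWAP, their PMF) is taken
from a donor state — for TC, the charged macrostates and TC_Z′ ride on the
zwitterion.  The proxy-sensitivity scan rescales only the proxied states'
permeabilities and reports the change in P_eff, bounding the error of the
approximation.

BWAP mixes PMFs by bulk fraction with log-sum-exp:
w_m = −k_BT ln Σ f_s e^(−βw_s).  The companion effective diffusivity is
the *local Boltzmann population weighted* average
D_m(z) = Σ φ_s(z) D_s(z), φ_s ∝ f_s e^(−βw_s(z)); this reproduces the
single-state and local-dominance limits exactly.  Other weightings exist
in the literature (the original formulation's exact form is not
reproduced here); where several states coexist at comparable local
population and very different D the choice matters, and is therefore
isolated in one function and recorded in the result's notes.

## Assay kinetics

For liposomal fluorescence assays, P_app = k·d/6 converts the fluorescence
rate k to an apparent permeability for vesicles of diameter d (nm; a 10⁷
nm/cm factor is applied internally).  Protonation rates are
order-of-magnitude estimates: k_on = k₀·10^(−pH) treats 10^(−pH) as a
molar proton concentration with the diffusion-limited k₀ = 10¹⁰ M⁻¹s⁻¹,
and k_off = k₀·10^(−pKa).  The regime is *permeation-limited* when both
protonation rates exceed the assay rate by a configurable factor (default
10×); this is a screening heuristic, not a kinetic model of the dye.

## Synthetic data

`make_w_pmf` builds the canonical "W" permeation shape from three
Gaussians (central barrier, mirrored interfacial wells) with a 2×2 linear
correction so the landmarks are hit exactly despite overlap; defaults
(barrier 4.5 kcal/mol, wells −4.9 kcal/mol at ±14 Å, bulk extent 40 Å,
0.2 Å spacing) mirror the neutral-tautomer landmarks of the tetracycline
study, and the zwitterion-like variant uses 13.6 / −2.1.  Only the
landmarks and the integrated permeability are meaningful; the curve shape
between them is an analytic stand-in, as are the constant calibrated
diffusivities of the `tc_like` fixture (chosen by root-finding on log₁₀ D
so each tautomer's ISD permeability equals its published value at 310 K —
about 10 Å²/ns for both, a physically sensible membrane value).

`simulate_langevin` integrates the overdamped (Brownian) equation in the
Itô convention with the explicit ∂D/∂z drift term,

    z ← z + [−β D(z) w′(z) + D′(z)] dt + sqrt(2 D(z) dt) ξ,

so the stationary density is Boltzmann even for position-dependent D —
required for the simulator/estimator consistency tests to be exact in
principle.  Boundaries reflect; a stability check refuses any dt whose
maximum drift step exceeds the potential grid spacing and suggests a
working value.  All randomness flows through one explicit seeded
generator; same seed, same trajectory, bit for bit.

`crossing_permeability` is the independent, quadrature-free check of the
ISD integral: at equilibrium the one-way rate of complete membrane
traversals equals P times the bulk linear concentration (time fraction in
the bulk regions per unit bulk length).  Traversals are counted in both
directions and halved; the standard error is a bootstrap over
trajectories; zero traversals return a flagged upper bound.  Near-wall
reflections bias per-step statistics, so diffusion-law checks exclude
steps starting within ~3 step-lengths of a wall.

These emulators reproduce the statistics the estimators assume —
Markovian overdamped motion on a known 1D landscape.  They do not emulate
lipid relaxation, permeant reorientation, hydrogen-bond dynamics or
membrane undulations, so passing tests validate the numerics of the
pipeline, not the fidelity of any particular MD-derived profile.

## Diffusivity inference

`DiffusionMAPModel` estimates piecewise-constant D(z) (default 1 Å bins)
from lag-τ displacements under the short-time Gaussian (Euler) propagator
of the Smoluchowski equation: mean [βD F + D′]τ, variance 2Dτ, with
F = −U′ from the known total potential (in the inverse-PMF protocol the
total landscape is flat).  Parameters are log D per bin (positivity by
construction) with a Gaussian smoothness prior on adjacent log-D
increments (scale σ, default 1; doubling σ can only roughen the MAP
profile).  Interior bins enter through closed-form per-bin sufficient
statistics, making each objective evaluation O(n_bins); the two
wall-adjacent bins add a single method-of-images term per observation to
correct for reflection.  Optimization is L-BFGS-B; per-bin uncertainties
come from the local curvature of the negative log posterior.

Guidance on the lag: the propagator assumes the rms displacement per lag
stays below the bin width (a diagnostic flags violations), and with
strongly correlated input (e.g. MD data at fine output intervals) the lag
should exceed the velocity decorrelation time.  With one bin and zero
force the MAP reduces to the textbook estimator D = ⟨Δz²⟩/2τ (verified
numerically).  Degenerate inputs: starved interior bins raise an error
naming them; a frozen trajectory is reported as D = 0 with a degeneracy
flag by the MSD oracle.

Validation is recovery-based (no tabulated D values exist to match):
constant D = 50 Å²/ns is recovered within 10% in every bin and sinusoidal
D (±50%) within 15% pointwise from 10⁶-step trajectories; an independent
MSD fit agrees within 10%; and the likelihood at the true profile beats
2× and 0.5× rescalings.

## Problem sizes and numerical defaults

Stochastic tests use 4×10⁵–2×10⁶ step trajectories (dt 0.2–2.5 ps,
chosen so the per-step rms displacement is ~0.2–0.5 Å), 6–16 trajectories
for counting statistics, and 200–400 bootstrap resamples — sizes at which
every tolerance above carries a ≥3× safety margin while the full suite
runs in well under a minute of simulation time.  Equality tolerances:
"symmetric" means 10⁻⁹ in profile units on matched grids; cycle residuals
10⁻⁶ (assembled models 10⁻⁹); population maps sum to 1 within 10⁻¹²;
pH-partitioning contributions sum to P_eff within 10⁻¹² relative.

## Known limitations

- 1D only: no 2D/3D collective variables, no membrane-patch phenomena,
  no hysteresis diagnosis, no transition-path-theory rates.
- Classical Smoluchowski only; no fractional/anomalous-diffusion variant.
- The BWAP effective-diffusivity weighting is one defensible choice among
  several (see above).
- The reflecting-boundary image correction uses a single image at the
  nearer wall; with bins comparable to the rms step and both walls close
  it under-corrects.
- No pKa prediction, no constant-pH simulation, no activity corrections;
  all pk inputs are the user's responsibility.
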