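# Methods

## Model structure

Every gene product x in a genotype's system evolves by

    ∂x/∂t = D ∇²x + α − β x + γ ( U_x / (1 + U_x + V_x) )²

with U_x and V_x nonnegative linear combinations of the activator-like and
inhibitor-like species concentrations.  The squared Hill form encodes two
identical, independent TF binding sites with competitive activator /
inhibitor occupancy; alternative exponents (cooperative or single-site
binding) are not modeled.  Concentration units are arbitrary: only the
dimensionless products κ·concentration enter the dynamics, so rescaling
concentrations rescales the κ table inversely and nothing else.

A diploid genotype at the activator (U) and inhibitor (V) loci
instantiates the four-species system in the fixed order (u, v, û, v̂),
chosen so the Jacobian exposes its 2×2 haplotype block structure.  Within
a heterozygous locus, haplotype 1 always carries allele A and haplotype 2
allele B; the heterozygote is unordered genetically, and the choice only
labels which species carries which allele.

**Contraction.** At a homozygous locus the two gene products obey
identical equations, so their total x̄ = x + x̂ satisfies a closed
equation with α and γ doubled and β unchanged.  Contraction is performed
symbolically — rewriting the rate and weight tables, not numerically — so
full and contracted systems can be cross-validated; the test suite checks
agreement of steady states, ODE trajectories and 2D fields.  Contraction
keys off the genotype only: a heterozygous locus whose two alleles happen
to carry identical parameters is deliberately not auto-contracted, since
the bookkeeping (which constants a genotype references) is part of the
model.  Contracted species are ordered activators first (e.g. (u, û, v̄)
for U:AB,V:BB).

## Parameters

| class | meaning | units | default sampling range |
|---|---|---|---|
| α | baseline production | conc/time | log-uniform [0.01, 1] |
| β | first-order degradation | 1/time | log-uniform [0.1, 2] |
| γ | maximal regulated production | conc/time | log-uniform [1, 30] |
| κ (cis) | association constant, same-allele binding | 1/conc | log-uniform [0.1, 10] |
| trans/cis ratio | κ^trans / κ^cis per pair | — | log-uniform [0.05, 1] |
| D_u, D_v | diffusion coefficients | length²/time | set by wavelength calibration |

The sampler draws trans constants as the regulated allele's cis value
times a ratio ≤ 1, reflecting the working assumption that small structural
differences between allelic TFs weaken binding across haplotypes — which
is also the regime in which the F1 separates from its parents.  The
ranges bracket order-unity steady states with saturating-but-not-saturated
Hill terms, the regime where two-species activator–inhibitor networks are
Turing-capable.

## Linear stability analysis

Steady states are found with a damped Newton/hybrid root finder
(`scipy.optimize.root`, analytic Jacobian) from 32 starts: the γ = 0
closed form α/β first, then log-uniform multiples over [1e-3, 1e3].
Distinct roots (pairwise relative separation > 1e-6) mark the state
non-unique; the model can produce three coexisting uniform states, and
admissibility requires uniqueness.  Root residual tolerance is 1e-10.

The reaction Jacobian is closed-form:
∂f_i/∂x_j = −β_i δ_ij + 2 γ_i U_i (a_ij (1+V_i) − b_ij U_i) / (1+U_i+V_i)³,
verified against central finite differences on randomized systems
(relative error ≤ 1e-6 over 100 systems in the test suite).

The dispersion relation σ(k) is the maximum real eigenvalue of
J − k² diag(D).  The supremum over k is computed continuously (not
grid-limited): a coarse log-spaced grid in k² seeds a bounded
golden-section/Brent refinement.  "Stable" means max Re λ < −1e-9 — a
strict margin so marginal cases are never classified stable.

**Critical diffusion ratio.**  With d = D_v/D_u, the critical ratio d★ is
located by bisection of sup_k σ(k; d) on d (relative tolerance 1e-6,
default bracket [1, 1e4]); d★ is independent of the overall diffusion
scale.  A system with no instability below the bracket ceiling reports
the ∞ sentinel; one already unstable at the floor raises an explicit
bracket error.  The bisection is validated against a dense (d, k) grid
scan at d-resolution 1e-4 using the closed-form 2×2 eigenvalue.

**Admissibility.**  A parameter set is admissible when parents and F1
all have unique, strictly stable uniform states and
d★(F1) < d < min(d★(A), d★(B)).  The search accepts the first sampled
candidate passing the screen, sets d to the geometric mean of the window
(or twice d★(F1) when the parents have no finite threshold), and then
rescales D_u so the F1's fastest-growing mode has wavelength 16 grid
units on the default 128×128 domain — purely a calibration of the
arbitrary length unit, since d★ and the admissibility verdict are
scale-free.  The search is deterministic given its seed and logs
rejection statistics.

## 2D simulation

Time integration uses operator splitting on a rectangular nx×ny grid with
no-flux boundaries:

- **Diffusion** by Peaceman–Rachford ADI: an x-implicit then a y-implicit
  half step, each Crank–Nicolson-weighted, solved as banded tridiagonal
  systems.  The reflecting-boundary Laplacian has zero column sums, so
  both implicit and explicit sub-operators conserve each species' spatial
  sum to machine precision.
- **Reaction** explicitly, by default in Strang order (half step before
  and after the diffusion step).  The Strang default matters: the
  patterned/unpatterned call hinges on growth rates within a few 1e-2 of
  zero, and first-order (Lie) splitting at dt = 0.1 was measured to shift
  the effective growth rate of a near-marginal mode by +0.05 — enough to
  spuriously pattern a stable parent.  With Strang at the default
  dt = 0.05 the effective rate matches the dispersion relation to ~1e-4.
  Lie splitting remains available (`SimConfig(strang=False)`) for
  comparison.

Defaults (all config-overridable): 128×128 grid, dx = 1, dt = 0.05,
t_max = 5000, initial condition = uniform steady state plus seeded i.i.d.
uniform noise at 1% of each species' steady-state level, clamped at zero.
dt must respect the explicit-reaction bound (warning when dt·max β > 1);
the ADI part is unconditionally stable.  Negative concentrations from
roundoff are clamped to zero and counted; more than 0.1% clamped updates
triggers a warning.  Convergence is declared when the max rate of change
over a 100-step window falls below `convergence_tol` (1e-7 by default;
patterned runs coarsen slowly, and the test suite uses 1e-5 with finite
t_max, flagging non-converged fields rather than hiding them).  The
domain is rectangular; petal-shaped masks would be a rendering concern
only.

## Phenotype classification

Total activator u + û is the pigment proxy.  A field is "patterned" when
its spatial coefficient of variation exceeds 0.05 — in practice Turing
patterns sit 3–5 orders of magnitude above the roundoff-level CV of
relaxed uniform fields, so the threshold is uncritical; it is exposed in
the API because the underlying quantity is continuous.  The dominant
wavelength is the peak of the radially averaged power spectrum (bin width
= one fundamental frequency); spots are 8-connected components above the
(max+min)/2 level, with a "labyrinthine" flag when the largest component
spans more than 25% of the domain.  Renderings map total activator
through a yellow-to-red colormap with a shared range across the panels of
a figure.

## Fixtures

No external numeric parameter sets are available for this model's
published figure simulations, so the packaged fixtures are outputs of the
package's own seeded searches, with deterministic curation rules recorded
in their `.meta.json` sidecars and in `turingcross.fixtures`:

- `admissible`: first search seed (1, 2, 3, …) whose accepted set also
  gives all nine F2 genotypes unique, reaction-stable steady states with
  classification margins |σ_max(d)| ≥ 0.03 and d ≤ 100.  The margin rule
  exists so the patterned/unpatterned dichotomy is numerically crisp for
  every genotype; sets failing it are physically fine but make poor test
  substrates.
- `symmetric`: first candidate of a fixed sampling stream whose parent
  system has 3 < d★ < 60 and whose four single-pathway d★(m) sweeps are
  monotone with the common direction pattern (cross pathways lower d★,
  self pathways raise it).  Non-monotone sweeps and opposite-direction
  parameter sets exist — the directions are parameter-dependent, not
  theorems — so the packaged fixture pins the representative case.

## What the synthetic setup does and does not show

The generator emulates the study conditions — Mendelian parameter
inheritance over two generations, trans-weaker-than-cis binding, one
shared diffusion ratio — not measured *Mimulus* kinetics: rate constants,
domain size and noise are in arbitrary units, the petal is a rectangle,
and no cell-level gene expression noise or growth is modeled.  Passing
tests therefore demonstrate the mechanism (transgressive patterning from
inherited network parameters) and the internal consistency of analysis
and simulation; they do not quantify real spot counts, wavelengths or
pigment levels, and quantitative reproduction of published figure layouts
is not claimed.

## Known limitations

- Two alleles per locus, two loci, no linkage, no backcross CLI (the
  cross machinery itself is general).
- No bHLH/WD40 accessory proteins or multiple inhibitor copies; the
  activator axis is one-dimensional, so pigment hue variation beyond
  intensity is out of scope.
- One-axis trans-efficacy sweeps only; the full 4D m-space is not
  characterized.
- No amplitude equations or bifurcation continuation: inheritance is a
  discrete parameter map, so there is no continuously varying bifurcation
  parameter to continue along.
- Steady-state multiplicity is detected (multi-start) but basins are not
  mapped; admissibility simply requires uniqueness.
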