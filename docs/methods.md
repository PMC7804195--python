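# Methods

## The model

`kdfa` implements a machine-learned correlation-energy functional that is
pure (a functional of the electron density alone), non-local, and
size-extensive by construction.

**Density representation.** A molecular electron density is expanded in
atom-centered auxiliary Gaussian functions (density fitting, DF):

    rho(r) ~= sum_A sum_Q C_Q^A phi_Q(r - r_A) = sum_A rho_A(r).

Unlike an orbital-product expansion, this decomposes the density
unambiguously into atomic contributions `rho_A`, each described by the
coefficient vector `C^A` over that element's auxiliary shells (roughly 40-60
coefficients per atom with the shipped basis). The coefficients are obtained
from a metric least-squares solve `M C = b`. Two metrics are supported: the
overlap metric, evaluated by Becke-grid quadrature against any
pointwise-evaluable density (the self-contained path used throughout the
tests), and the Coulomb metric, the standard RI-J choice when an
electronic-structure backend supplies the Hartree-Fock density.

**Invariant features (RIDR).** DF coefficients rotate with the molecule, so
they are contracted to the rotationally invariant power spectrum per atom:

    p_{n n' l} = s * sum_m c_{n l m} c_{n' l m},   n <= n',

with `s = sqrt(2)` for `n < n'` so that the flattened upper-triangle dot
product equals the Frobenius inner product of the full per-l Gram matrices.
Each fixed-l coefficient block transforms by an orthogonal Wigner matrix
under rotation, which the m-contraction annihilates exactly; the residual
invariance error of the quadrature path is purely the grid's angular
anisotropy (measured: ~6e-4 relative at the production grid, <1e-7 at the
converged grid; see "Numerical choices").

**Kernel and regression.** Atomic similarity is the normalized polynomial
kernel

    k(rho_A, rho_B) = (p_A . p_B / |p_A||p_B|)^2,

assembled into a system kernel by a plain double sum over atoms,
`K(rho_i, rho_j) = sum_{A in i} sum_{B in j} k(rho_A, rho_B)`.  Because K is
additive over atoms, the prediction

    E_c[rho] = sum_i alpha_i K(rho, rho_i)

is exactly extensive: two non-interacting fragments predict to the sum of
the fragment predictions, to solver precision. The regression coefficients
come from the closed-form ridge solve `(K + lambda I) alpha = E_c` with one
step of iterative refinement (thermal ensembles produce nearly parallel
feature vectors and hence ill-conditioned Gram matrices; refinement keeps
the interpolation error at the 1e-8 meV level where naive solves leave
1e-6 meV).

Atoms of different elements have feature vectors of different lengths and
layouts, so the kernel between them is defined as zero (`element_blocked`,
default on).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| kernel exponent | 2 | - | lowest even power; smooth, positive semi-definite |
| ridge lambda | 1e-8 | - | noise floor of the synthetic labels; recorded in provenance |
| off-diagonal scaling | sqrt(2) | - | makes the flattened dot product exact (see above) |
| grid (production) | 35 radial x 12 x 24 angular | points/atom | residual converged to ~1e-4, charge to ~0.3% |
| grid (converged) | 70 x 24 x 48 | points/atom | invariance checks at <1e-6 relative |
| bin width (FES) | 0.02 | Angstrom | resolves the ~0.1 Angstrom thermal well |
| temperature (FES) | 300 | K | ensemble temperature of the dimer analysis |
| jitter sigma | 0.05 | Angstrom | thermal displacement amplitude of ~350 K snapshots |
| label noise | 1 | meV | numerical noise of a converged reference calculation |

Energies are Hartree internally; meV at user-facing boundaries
(1 Hartree = 27211.386245988 meV). Geometry is Bohr internally, Angstrom in
XYZ and CLI output. kB = 8.617333262e-5 eV/K.

## The synthetic data generator

The fixture module emulates the study conditions without any
electronic-structure engine:

* **Geometries** — template monomers (water, hydronium, a protonated water
  dimer with r_OO = 2.45 Angstrom, zig-zag alkanes) assembled on a jittered
  3.1 Angstrom lattice with random orientations, then Gaussian-jittered by
  0.05 Angstrom per coordinate to mimic decorrelated thermal snapshots.
  Frames with interatomic distances below 0.7 Angstrom are regenerated.
* **Densities** — sums of isotropic Gaussians at atoms (charge proportional
  to the element's electron count, net charge absorbed proportionally) and
  at bonded-pair midpoints (0.15 e per bond, a typical covalent bond-density
  accumulation). The off-center bond lobes force nonzero l > 0 DF
  coefficients, exercising the full angular machinery. The analytic integral
  equals the electron count exactly, which gives a sharp validation of every
  fit: the package rejects fits whose integrated charge is off by >1%.
* **Labels** — per-atom smooth functionals of the features,
  `E = sum_A [o_e + a_e tanh(g u_e . (p_hat_A - r_e))] + eps`, with
  per-element offsets (-800/-4000/-7000 meV for H/C/O) and amplitudes
  (150/300/400 meV) on the scale of per-atom correlation-energy means and
  thermal fluctuations, fixed unit directions `u_e` orthogonalized against
  a fixed template reference environment `r_e` per element, gain g = 40,
  and Gaussian noise of 1 meV. The orthogonalization and gain matter:
  thermal jitter moves the normalized power spectrum by only ~1e-3
  relative, and projecting that small deviation (rather than the large
  constant feature component) scaled by g realizes a within-ensemble
  molecular label spread of ~50-130 meV — the scale on which correlation
  energies of thermal snapshots actually fluctuate, and what makes the
  learning problem realistically conditioned. The labels are exactly
  additive over non-interacting fragments — the structure the functional
  is built to exploit. The bounded, smooth tanh form reflects that
  correlation energies vary far more smoothly with geometry than total
  energies, which is what makes 10-100 training configurations
  sufficient.
* **Protonated-dimer ensembles** — (r_OO, nu) drawn from the exact Boltzmann
  distribution of a harmonic surrogate surface (force constants 2600 and
  1150 meV/Angstrom^2, minimum at r_OO = 2.45 Angstrom, nu = 0), with
  geometries rebuilt to reproduce the sampled coordinates exactly.

What the fixtures do **not** emulate: self-consistent densities, basis-set
effects of real wavefunctions, anharmonicity and mode coupling of real MD,
inter-molecular charge transfer, or nuclear quantum effects. Passing tests
therefore demonstrate the correctness and statistical behavior of the
pipeline — invariance, extensivity, learning-curve decay, reweighting —
not the chemical accuracy of any particular trained functional.

## Numerical choices

* **Quadrature**: per-atom product grids (Gauss-Legendre radial points under
  the Becke mapping r = R(1+x)/(1-x) with R = 1 Bohr; Gauss-Legendre in
  cos(theta) x uniform phi) with Becke fuzzy-cell partitioning (3 smoothing
  iterations). The angular rule integrates spherical-harmonic products of
  the supported l <= 3 exactly.
* **Metric conditioning**: the SPD solve uses an eigendecomposition with a
  relative eigenvalue floor of 1e-10; discarded near-dependent modes are
  logged with a condition estimate.
* **Fit residual**: evaluated pointwise on the grid rather than via the
  algebraic identity, which cancels catastrophically for densities inside
  the basis span.
* **Real solid harmonics**: tesseral harmonics in standard m = -l..+l order
  as explicit polynomials (finite at the nucleus); the RIDR layout depends
  on this ordering, which is frozen.
* **Ties and seeds**: every stochastic step (jitter, placement, splits,
  label noise, resampling draws) takes an explicit integer seed; random
  train/test splits are seeded shuffles.
* **Degenerate inputs**: zero-norm feature vectors (empty atomic densities)
  raise rather than silently contributing k = 0; duplicate training systems
  at lambda = 0 raise with advice to regularize; empty FES bins are NaN,
  never 0.

## The ensemble-resampling stage

A cheap, long MD ensemble with energies `E_low` is reweighted toward a
high-level surface `E_high` (e.g. HF plus the predicted correlation energy)
with Boltzmann factors `w_i ~ exp(-(E_high,i - E_low,i)/kB T)`, max-shifted
before exponentiation. The weighted 2-D histogram over the proton-transfer
coordinates (r_OO, nu) yields `F = -kB T ln(P / max P)`; the Kish effective
sample size `1/sum w_i^2` diagnoses weight degeneracy. Explicit multinomial
resampling is also provided and converges to the weighted histogram as the
number of draws grows. With `E_high = E_low + const`, the original ensemble
is recovered exactly (uniform weights, ESS = N).

The shared proton of a protonated water dimer is identified per frame as
the hydrogen nearest the O-O midpoint; `nu = d(H, O1) - d(H, O2)` with O1
the lower-indexed oxygen, so `nu = 0` means the proton is equidistant.

## Problem sizes in the shipped experiments

The learning-curve experiments run on 130 thermal configurations (65 water
dimers + 65 trimers) at the production grid, training on 100 (and 10)
random configurations over 5 split seeds. The transferability experiment
trains on 100 of 120 frames of 2-4-monomer clusters and predicts 10
octamer frames on a reduced (20 x 8 x 16) grid. The free-energy surface
uses 20,000 surrogate-ensemble frames. These sizes give seed-stable
statistics while keeping a full test run on a single CPU core comfortable.

## Design choices where the design was open

* **Fitting metric**: overlap for the quadrature path (no Coulomb integrals
  needed for synthetic densities), Coulomb for the backend path (standard
  RI-J for total densities); exposed as configuration.
* **Auxiliary family**: the shipped `kdfa-light` set is this package's own
  compact even-tempered family (H/C/N/O, l <= 2), with s-exponent ladders
  dense enough to hold the fitted charge within 1% for all fixture systems.
  Literature families (e.g. the def2 Coulomb-fitting sets) can be loaded
  from Gaussian94-format files and used interchangeably.
* **Labels are raw correlation energies**, not atom-referenced; an optional
  per-element baseline subtraction exists but is off by default, since the
  atomic-sum kernel absorbs per-element offsets naturally.
* **Transferability accounting**: three regimes are distinguished and
  tested separately. (i) Disjoint composites of training-sized fragments:
  errors add at most linearly, exactly as extensivity dictates. (ii)
  In-distribution sizes (dimers to tetramers): per-atom error is flat.
  (iii) Dense clusters beyond the training size (hexamers, octamers): a
  bounded environment-shift component appears because their monomers are
  more highly coordinated than in any training frame; the tests bound the
  hexamer-to-octamer per-atom growth and require genuine skill (MAE well
  below the label spread) plus relative energies at least as accurate as
  total ones — the same qualitative pattern the full-scale experiments
  report for the water octamer.

## Known limitations

* The quadrature path requires a pointwise-evaluable density; real HF
  densities enter only through the optional backend adapter (pyscf), which
  is not exercised by the test suite.
* Elements beyond H/C/N/O need user-supplied auxiliary shells and density
  widths.
* Angular momenta above l = 3 in auxiliary sets are not implemented.
* The functional is evaluated non-self-consistently on a fixed density; no
  gradients/forces, so it cannot itself drive MD.
* Element-blocked kernels mean an element absent from training contributes
  exactly zero correlation energy (a warning is emitted).
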