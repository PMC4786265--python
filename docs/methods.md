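# Methods

## The model

`gosbm` builds and simulates structure-based ("Go-type") models: potential
energy functions whose global minimum is pinned, term by term, to a known
native structure.  The coarse-grained C-alpha Hamiltonian is

    V(x) = sum_bonds     eps_b/2  (r - r0)^2
         + sum_angles    eps_th/2 (theta - theta0)^2
         + sum_dihedrals eps_D F_D(phi - phi0)
         + sum_contacts  eps_C [ 5 (r0/r)^12 - 6 (r0/r)^10 ]
         + sum_others    eps_NC (sigma_NC / r)^12

with the dihedral form

    F_D(d) = [1 - cos d] + 1/2 [1 - cos 3d].

Every superscript-0 quantity is measured from the input structure (the
template placeholder `?`), which makes the native configuration the exact
minimum of each structure-derived term: the test suite asserts
V_bond = V_angle = F_D = 0 and V_contact = -sum(eps_C) at native
coordinates to machine precision.

Units are reduced: eps = 1 (native contact energy), k_B = 1, mass = 1,
lengths in nm.  GROMACS-convention temperatures follow from eps = 1 kJ/mol
via T_mdp = T_reduced / 0.00831451.

## Parameters and defaults

Bundled C-alpha template (`SBM_CA`): eps_b = 20000 eps/nm^2,
eps_th = 40 eps/rad^2, eps_D = 1 eps, eps_C = 1 eps, eps_NC = 1 eps,
sigma_NC = 0.4 nm, exclusion depth 3 bonds.  Only the bond constant is a
community-printed value; the remaining constants follow the classic
C-alpha model family and are all overridable in the XML templates.

All-atom template (`SBM_AA`): all heavy atoms, uniform types, proper
dihedrals only (no improper/planarity terms — a documented limitation of
the bundled subset), sigma_NC = 0.21 nm (the conventional uniform
heavy-atom diameter), and a post-assembly normalization
(`normalize_energies`) that rescales dihedral and contact strengths to a
2:1 contact:dihedral ratio with total stabilizing energy equal to the atom
count.  These normalization constants are provisional conventions, not
fitted values; anyone requiring bit-compatibility with externally
distributed all-atom templates must cross-check them.

Elastic network (`ENM`): covalent bonds plus uniform harmonic springs
(k = 1000 eps/nm^2, a system-independent choice) on all atomic contacts
within the 0.6 nm cutoff; angle/dihedral enumeration is disabled.

Gaussian contacts: the literature does not fix a single printed form, so
the shipped default is the implementation-chosen plain Gaussian well
V = -eps_C exp(-(r - r0)^2 / 2 w^2) with width w = 0.05 nm, declared as a
three-slot function so templates can override both depth and width.

## Contact maps

Native contacts are generated by a distance cutoff (default 0.6 nm between
atoms) with residue-separation filtering: same-residue exclusion for
atomic maps, >= 4 residues for coarse-grained maps; inter-chain pairs are
always eligible.  An optional line-of-sight filter removes pairs whose
connecting segment passes within a screening radius (default 0.1 nm) of a
third atom.  This filter is a simplified occlusion criterion — a stand-in
with similar intent to shadow-style map generators, not a reimplementation
of one; the defaults are deliberately conservative and configurable.
Contact entries that fall within the bonded exclusion depth are dropped at
assembly time (they are already parameterized as bonded terms), keeping
the contact and bond sets disjoint.

## The synthetic test protein

Real structure files cannot be bundled, so desk-scale folding experiments
use `make_fixture("synthetic_ci2")`: a *constructed* 64-residue alpha/beta
fold of CI2-like size and architecture — an N-terminal strand, a 13-residue
helix packed against a four-stranded sheet (strand spacing 0.5 nm), and a
long active-site-like loop.  The C-alpha trace is laid out from ideal
secondary-structure geometry, relaxed by deterministic gradient descent to
uniform 0.38 nm spacing without clashes, then decorated with approximate
backbone (N, C, O) and side-chain (CB, CG) atoms pointing into the core.
Design targets, chosen once for realism and verified by tests: radius of
gyration ~1.25 nm and ~2 native contacts per residue at sequence
separation >= 4 — both typical of small single-domain proteins.

What it emulates: protein-like chain connectivity, compactness, secondary
structure, contact density and two-state folding behaviour.  What it does
not: a real sequence (residue names cycle through eight side-chain-bearing
amino acids), crystallographic geometry, side chains beyond CG, hydrogen
atoms, or the specific contact topology of any real protein.  Passing
folding tests therefore demonstrates that the pipeline produces a
two-state folder with the expected thermodynamics for a protein-scale
input — not agreement with any particular experimental structure.

## Simulation numerics

Langevin dynamics uses the BAOAB splitting, which reduces exactly to
velocity Verlet at zero friction (the NVE drift test runs in that limit).
Default dt = 5e-4 reduced time: the stiffest term (eps_b = 20000) has
omega ~ 141, so omega dt ~ 0.07, comfortably stable; the equipartition and
distribution tests use dt = 2e-4 to keep discretization bias well below
their tolerances.  One counter-based generator (PCG64) seeded once drives
the whole run; Gaussian draws are consumed in fixed step/atom order, so
trajectories are bit-reproducible for a given seed, independent of
neighbor-list rebuild timing.

Excluded volume runs through a Verlet neighbor list (cutoff 1.2 nm = 3
sigma_NC, skin 0.3 nm) with the cutoff re-applied inside the kernel and a
displacement trigger at 40 % of the skin, which guarantees no pair inside
the cutoff is ever missed; the test suite audits this by checking
bit-identical trajectories against an effectively exhaustive list.  The
r^-12 tail is truncated at the cutoff ((sigma/rc)^12 ~ 2e-6 eps);
`compute_energy` always evaluates the untruncated sum.  Pair lists are
kept in canonical (i, j) order so floating-point accumulation order is
reproducible.  Collinear dihedral centers contribute zero torque
(regularization); coordinates beyond 1e6 nm abort the run with
diagnostics.  When numba is importable the kernels are JIT-compiled;
otherwise the same code runs as plain Python.

## Analysis estimators

Q is the fraction of native pairs within `ratio` times their native
distance (default 1.5; 1.2 is the common alternative for atomic contact
counting).  F(Q) = -ln P(Q) uses 40 uniform bins by default (suited to a
64-residue-scale contact count), reported on visited bins with unvisited
gaps treated as infinite barriers.  Cv(T) = var(E)/T^2 with the peak
located by three-point quadratic interpolation.  T_F is primarily
estimated by folded/unfolded population balance: basins are split at the
F(Q) barrier top between the two deepest minima (ties toward lower Q) and
p_fold(T) = 1/2 is located by linear interpolation; the Cv peak serves as
a cross-check.  No multi-temperature reweighting is performed — each
temperature is analyzed independently, so desk-scale results target the
qualitative two-basin structure and a bracketed T_F rather than exact
free-energy curve overlays.

## Desk-scale folding experiment

`folding_temperature_scan` runs seven temperatures spanning 1.00-1.30
reduced units, two replicas each, 2e6 steps per replica (dt = 5e-4,
friction 0.5, frames every 2000 steps, first 20 % discarded as burn-in).
The light friction speeds diffusion across the folding barrier without
changing the sampled ensemble; pooling replicas suppresses the hysteresis
noise of rare transitions.  These sizes give multiple folding/unfolding
events per trajectory for the 64-bead model and a population-balance T_F
reproducible to a few percent across seeds.  All-atom folding
thermodynamics requires orders of magnitude more sampling and is exercised
only through an extended-run configuration (larger `n_steps`, the same
drivers); the desk-scale suite validates the all-atom machinery (assembly,
normalization, native-basin stability) instead.

## Known limitations

* The occlusion filter approximates, but does not reproduce, shadow-style
  contact screening; contact counts differ accordingly.
* The bundled all-atom template omits hydrogens, impropers and
  residue-specific radii; its energy normalization constants are
  provisional.
* [pairs] sections with 12-10/gaussian/harmonic coefficients follow this
  package's documented dialect; stock GROMACS reads [pairs] type 1 as
  6-12, so those files are meant for the bundled simulator or an
  SBM-enhanced MD build.
* Electrostatics, multi-basin merging, constraint algorithms and
  replica-exchange are out of scope.
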