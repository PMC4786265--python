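# gosbm

Structure-based ("Go-type") models for biomolecular folding and dynamics:
from a PDB structure and a declarative forcefield template set to
simulation-ready GROMACS-dialect topologies, with a built-in reduced-units
Langevin engine and native-structure analysis for validating the models.

Structure-based models encode the principle of minimal frustration: the
interactions present in the native structure are stabilizing, everything
else is reduced to excluded volume.  They are the workhorse for studying
folding mechanisms, transition-state ensembles and large-scale functional
motions at a fraction of the cost of transferable forcefields.  This
package is aimed at researchers who want to generate such models from
structures, customize their functional forms through templates, and verify
folding thermodynamics on a desktop.

## The model

For the coarse-grained C-alpha flavor (one bead per residue), the
Hamiltonian is

```
V(x) = Σ_bonds  ε_b/2 (r − r⁰)²  +  Σ_angles ε_θ/2 (θ − θ⁰)²
     + Σ_dihedrals ε_D F_D(φ − φ⁰)
     + Σ_contacts ε_C [5 (r⁰/r)¹² − 6 (r⁰/r)¹⁰]
     + Σ_non-contacts ε_NC (σ_NC/r)¹²,       F_D(δ) = [1−cos δ] + ½[1−cos 3δ]
```

where every `⁰` quantity is measured from the input structure (the
template placeholder `?`), making the native configuration the exact
global minimum.  Units are reduced (ε = k_B = mass = 1, lengths in nm);
the folding temperature T_F is where folded and unfolded basins are
equally populated along Q, the fraction of native contacts formed.

Four template sets ship with the package: `SBM_CA`, `SBM_CA_gaussian`,
`SBM_AA` (all heavy atoms) and `ENM` (elastic network).  The XML template
schema is documented in `docs/template_schema.md`; the science and the
numerical choices in `docs/methods.md`.

## Worked example

Generate, simulate and analyze the bundled 64-residue synthetic test
protein (a constructed CI2-scale alpha/beta fold; no downloads needed):

```bash
python -c "from gosbm import make_fixture, write_pdb; \
           write_pdb(make_fixture('synthetic_ci2'), 'ci2_synthetic.pdb')"
gosbm generate -i ci2_synthetic.pdb -t SBM_CA --cg -dname ci2
gosbm simulate -p ci2.top -g ci2.gro -dname run \
      --n-steps 200000 --save-every 1000 --temperature 1.15 --seed 0
gosbm analyze -x run.traj.npz -g ci2.gro -c ci2.contacts -dname ana
```

which prints

```
INFO atoms 64
INFO bonds 63
INFO angles 62
INFO dihedrals 61
INFO contacts 132
INFO simulate: 200000 steps at T=1.15 (seed 0, ...) -> 201 frames
INFO analyze: 201 frames, mean Q 0.961 (...)
```

The generate step coarse-grained the all-atom input to 64 C-alpha beads
(one per residue), built the chain topology (63 bonds, 62 angles, 61
dihedrals) and mapped 132 residue-level native contacts; every bond
carries the template's harmonic force constant 20000 with its minimum at
the measured native length.  The short run at T = 1.15 stays mostly folded
(mean Q 0.96); `ana.fq.tsv` holds the free-energy profile F(Q) and
`ana.q.tsv` the per-frame Q series.  Longer ladders around T ~ 1.0–1.3
(see below) resolve the two-state transition: a bimodal F(Q) and a
population-balance folding temperature near 1.17 reduced units (~141 K in
GROMACS .mdp convention with ε = 1 kJ/mol).

The same pipeline is scriptable from Python:

```python
from gosbm.experiments import build_synthetic_ci2_ca_model, folding_temperature_scan
model = build_synthetic_ci2_ca_model()
scan = folding_temperature_scan(model, seed=1)   # ~10 min on one core
print(scan.tf_population, scan.bimodal_temperature)
```

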