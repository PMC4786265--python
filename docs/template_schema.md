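# Template-set XML schema

A forcefield template set is a directory containing four XML documents.
The bundled sets (`SBM_CA`, `SBM_CA_gaussian`, `SBM_AA`, `ENM`) under
`src/gosbm/template_sets/` are the reference examples.

## `residues.xml` — residue definitions

```xml
<residues>
  <residue name="ALA" class="amino">
    <atom name="N"  bType="B" nbType="NB" pType="P" charge="0" mass="1"/>
    <atom name="CA" bType="B" nbType="NB" pType="P"/>
    ...
    <bond a1="N" a2="CA"/>
    ...
    <connect in="N" out="C"/>
  </residue>
</residues>
```

* `residue@name` — must match the (normalized) PDB residue name.
* `residue@class` — `amino` | `nucleic` | `ligand` (default `amino`).
* `atom` — one per declared atom.  The three type attributes control rule
  matching: `bType` (bonded rules), `nbType` (excluded volume), `pType`
  (native-contact rules); each defaults to the atom name when omitted.
  `charge` (elementary charges) defaults to 0 and `mass` (reduced) to 1.
* `bond` — covalent bonds internal to the residue; both endpoints must be
  declared atoms.  A bond may reference `connect` atoms of the *same*
  residue (e.g. proline's CD–N ring closure).
* `connect` — the atoms forming the inter-residue link: `out` of residue
  *i* bonds to `in` of residue *i + 1* within a chain.

## `settings.xml` — functions and system-wide settings

```xml
<settings>
  <functions>
    <function name="bond_harmonic" form="harmonic_bond"/>
    ...
  </functions>
  <nonbonded sigma_NC="0.4" epsilon_NC="1.0" exclusion_depth="3"/>
  <enumerate angles="true" dihedrals="true"/>
  <coarse_graining partner="SBM_AA"/>
</settings>
```

* `function@form` is one of the physical forms below; the declared `name`
  is what rules reference.

  | form                    | parameter slots (in order)        | `?` allowed |
  |-------------------------|-----------------------------------|-------------|
  | `harmonic_bond`         | r0 (nm), eps_b                    | slot 0      |
  | `harmonic_angle`        | theta0 (rad), eps_theta           | slot 0      |
  | `periodic_dihedral_1_3` | phi0 (rad), eps_D                 | slot 0      |
  | `contact_12_10`         | r0 (nm), eps_C                    | slot 0      |
  | `contact_gaussian`      | r0 (nm), eps_C, width (nm)        | slot 0      |
  | `contact_harmonic`      | r0 (nm), k (eps/nm^2)             | slot 0      |
  | `excluded_12`           | sigma (nm), eps                   | none        |

* `nonbonded` — the Hamiltonian's sigma_NC / epsilon_NC and the bonded
  exclusion depth (GROMACS `nrexcl` semantics).
* `enumerate` — set `angles`/`dihedrals` to `false` to suppress automatic
  enumeration (used by the elastic-network template).
* `coarse_graining@partner` — for single-bead templates: the name of the
  atomistic template used to interpret all-atom input (the two-template
  coarse-graining mechanism).  A coarse-graining template declares exactly
  one atom per residue; that atom is the kept bead.

## `bonded.xml` — bonded rules

```xml
<bonded>
  <bond func="bond_harmonic(?,20000)">
    <bType>*</bType>
    <bType>*</bType>
  </bond>
  <angle func="angle_harmonic(?,40)"> ... 3 bType tokens ... </angle>
  <dihedral func="dihedral_sbm(?,1)"> ... 4 bType tokens ... </dihedral>
</bonded>
```

## `nonbonded.xml` — excluded volume and native contacts

```xml
<nonbonded>
  <nonbond func="excluded_12(0.4,1.0)">
    <nbType>*</nbType>
  </nonbond>
  <pair func="contact_12_10(?,1.0)">
    <pType>*</pType>
    <pType>*</pType>
  </pair>
</nonbonded>
```

## Rule semantics

* Type tokens are matched whole; `*` is the whole-token wildcard (no
  partial globs).
* The most specific matching rule wins (specificity = number of literal
  tokens); tuples match in either orientation (symmetric interactions).
* Two *distinct* rules of equal specificity matching the same tuple is an
  error — declare an exact rule instead.
* At most one rule per exact pattern (reversals count as the same
  pattern).
* `?` marks a parameter measured from the native structure (bond length,
  angle, dihedral or contact distance, in the slot's native units).
* Every non-wildcard type token must appear on at least one declared atom,
  and every referenced function must be declared in `settings.xml`.
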