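kind	n_residues_default	atoms_per_residue	geometry
dimer	2	1	two CA beads 0.38 nm apart along z
triatomic_bent	3	1	three CA beads, interior angle 100 deg, bond length 0.38 nm
planar_four	4	1	coplanar zig-zag, trans arrangement (dihedral pi)
ca_helix	10	1	ideal alpha-helix CA trace: radius 0.23 nm, 100 deg/residue, consecutive spacing exactly 0.38 nm
ca_hairpin	12	1	two antiparallel strands 0.5 nm apart joined by a 2-residue turn
two_chain	10	1	two separate helical CA chains (chain break between them)
aa_peptide	5	5	extended poly-alanine with N/CA/C/O/CB heavy atoms per residue
synthetic_ci2	64	6	synthetic 64-residue alpha/beta fold (strand-helix-sheet), N/CA/C/O/CB/CG per residue; constructed CI2-scale stand-in
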