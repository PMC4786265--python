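<?xml version='1.0' encoding='UTF-8'?>
<settings>
  <functions>
    <function name="bond_harmonic" form="harmonic_bond"/>
    <function name="angle_harmonic" form="harmonic_angle"/>
    <function name="dihedral_sbm" form="periodic_dihedral_1_3"/>
    <function name="contact_12_10" form="contact_12_10"/>
    <function name="contact_gaussian" form="contact_gaussian"/>
    <function name="contact_harmonic" form="contact_harmonic"/>
    <function name="excluded_12" form="excluded_12"/>
  </functions>
  <nonbonded sigma_NC="0.21" epsilon_NC="1.0" exclusion_depth="3"/>
  <enumerate angles="false" dihedrals="false"/>
</settings>
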