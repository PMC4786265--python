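<?xml version='1.0' encoding='UTF-8'?>
<residues>
  <residue name="ALA" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="ARG" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="ASN" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="ASP" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="CYS" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="GLN" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="GLU" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="GLY" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="HIS" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="ILE" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="LEU" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="LYS" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="MET" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="PHE" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="PRO" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="SER" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="THR" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="TRP" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="TYR" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
  <residue name="VAL" class="amino">
    <atom name="CA" bType="B_CA" nbType="NB_CA" pType="P_CA"/>
    <connect in="CA" out="CA"/>
  </residue>
</residues>
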