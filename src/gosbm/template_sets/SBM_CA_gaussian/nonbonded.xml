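<?xml version='1.0' encoding='UTF-8'?>
<nonbonded>
  <nonbond func="excluded_12(0.4,1)">
    <nbType>*</nbType>
  </nonbond>
  <pair func="contact_gaussian(?,1,0.05)">
    <pType>*</pType>
    <pType>*</pType>
  </pair>
</nonbonded>
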