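<?xml version='1.0' encoding='UTF-8'?>
<bonded>
  <bond func="bond_harmonic(?,20000)">
    <bType>*</bType>
    <bType>*</bType>
  </bond>
</bonded>
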