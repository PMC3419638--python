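# Repeat taxonomy used for the hierarchical ledger.  Two spaces per level;
# the implicit root aggregates all repeat bases.
Transposable Element
  RNA transposon
    LTR Retrotransposon
      Copia
      Gypsy
    Non-LTR Retrotransposon
      L1
      RTE
      SINE
      SINE2/tRNA
  DNA transposon
    EnSpm
    Harbinger
    Helitron
    MuDr
    hAT
Integrated Virus
  Caulimoviridae
Simple Repeat
  Satellite
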