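# Canonical two-branch processive processing of APP C99 by γ-secretase.
# Endoproteolysis (ε) releases an AICD; each trimming step releases the
# tri-/tetrapeptide whose sequence is listed.
substrate: C99
branches:
  - name: Aβ40
    steps:
      - {precursor: C99, product: Aβ49, coproduct: AICD50-99}
      - {precursor: Aβ49, product: Aβ46, coproduct: ITL, coproduct_sequence: ITL}
      - {precursor: Aβ46, product: Aβ43, coproduct: VIV, coproduct_sequence: VIV}
      - {precursor: Aβ43, product: Aβ40, coproduct: IAT, coproduct_sequence: IAT}
  - name: Aβ42
    steps:
      - {precursor: C99, product: Aβ48, coproduct: AICD49-99}
      - {precursor: Aβ48, product: Aβ45, coproduct: VIT, coproduct_sequence: VIT}
      - {precursor: Aβ45, product: Aβ42, coproduct: TVI, coproduct_sequence: TVI}
      - {precursor: Aβ42, product: Aβ38, coproduct: VVIA, coproduct_sequence: VVIA}
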