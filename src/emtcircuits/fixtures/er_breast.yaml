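network:
  name: er_breast
  nodes:
  - miR200
  - ZEB
  - SLUG
  - ELF3
  - ERa66
  - ERa36
  edges:
  - source: miR200
    target: ZEB
    sign: inhibition
    mechanism: microRNA
  - source: ZEB
    target: miR200
    sign: inhibition
    mechanism: transcriptional
  - source: ZEB
    target: ZEB
    sign: activation
    mechanism: transcriptional
  - source: SLUG
    target: miR200
    sign: inhibition
    mechanism: transcriptional
  - source: miR200
    target: SLUG
    sign: inhibition
    mechanism: microRNA
  - source: SLUG
    target: SLUG
    sign: activation
    mechanism: transcriptional
  - source: SLUG
    target: ELF3
    sign: inhibition
    mechanism: transcriptional
  - source: ELF3
    target: ZEB
    sign: inhibition
    mechanism: transcriptional
  - source: ELF3
    target: ELF3
    sign: activation
    mechanism: transcriptional
  - source: ELF3
    target: ERa66
    sign: inhibition
    mechanism: transcriptional
  - source: ERa66
    target: ELF3
    sign: inhibition
    mechanism: transcriptional
  - source: ZEB
    target: ERa66
    sign: inhibition
    mechanism: transcriptional
  - source: ERa66
    target: ERa36
    sign: inhibition
    mechanism: transcriptional
  - source: ERa36
    target: ZEB
    sign: activation
    mechanism: transcriptional
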