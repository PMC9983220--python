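network:
  name: core_emt_elf3_grhl2
  nodes:
  - SNAIL
  - SLUG
  - KLF4
  - miR200
  - ZEB
  - ELF3
  - GRHL2
  edges:
  - source: SNAIL
    target: SLUG
    sign: activation
    mechanism: transcriptional
  - source: SNAIL
    target: KLF4
    sign: inhibition
    mechanism: transcriptional
  - source: SNAIL
    target: miR200
    sign: inhibition
    mechanism: transcriptional
  - source: SNAIL
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
  - source: KLF4
    target: SLUG
    sign: inhibition
    mechanism: transcriptional
  - source: ELF3
    target: ELF3
    sign: activation
    mechanism: transcriptional
  - source: SNAIL
    target: ELF3
    sign: inhibition
    mechanism: transcriptional
  - source: SLUG
    target: ELF3
    sign: inhibition
    mechanism: transcriptional
  - source: ELF3
    target: ZEB
    sign: inhibition
    mechanism: transcriptional
  - source: GRHL2
    target: ZEB
    sign: inhibition
    mechanism: transcriptional
  - source: ZEB
    target: GRHL2
    sign: inhibition
    mechanism: transcriptional
  - source: GRHL2
    target: ELF3
    sign: activation
    mechanism: transcriptional
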