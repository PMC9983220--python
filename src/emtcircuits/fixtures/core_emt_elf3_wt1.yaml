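network:
  name: core_emt_elf3_wt1
  nodes:
  - Iext
  - SNAIL
  - SLUG
  - KLF4
  - miR200
  - ZEB
  - ELF3
  - WT1
  edges:
  - source: Iext
    target: SNAIL
    sign: activation
    mechanism: transcriptional
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
  - source: WT1
    target: WT1
    sign: inhibition
    mechanism: transcriptional
  - source: WT1
    target: SNAIL
    sign: activation
    mechanism: transcriptional
  - source: WT1
    target: SLUG
    sign: inhibition
    mechanism: transcriptional
  signal: Iext
parameters:
  provenance: reconstructed-calibrated
  production:
    SNAIL: 2000.0
    SLUG: 150.0
    KLF4: 100.0
    miR200: 2000.0
    ZEB: 60.0
    ELF3: 160.0
    WT1: 120.0
  degradation:
    SNAIL: 0.1
    SLUG: 0.1
    KLF4: 0.1
    miR200: 0.1
    ZEB: 0.1
    ELF3: 0.1
    WT1: 0.1
  hill:
  - source: Iext
    target: SNAIL
    lambda: 25.0
    threshold: 28000.0
    n: 2
  - source: SNAIL
    target: SLUG
    lambda: 4.0
    threshold: 150000.0
    n: 2
  - source: SNAIL
    target: KLF4
    lambda: 0.3
    threshold: 150000.0
    n: 2
  - source: SNAIL
    target: miR200
    lambda: 0.25
    threshold: 120000.0
    n: 2
  - source: SNAIL
    target: ZEB
    lambda: 2.3
    threshold: 150000.0
    n: 2
  - source: SLUG
    target: miR200
    lambda: 0.6
    threshold: 3000.0
    n: 2
  - source: miR200
    target: SLUG
    lambda: 0.4
    threshold: 15000.0
    n: 2
  - source: miR200
    target: ZEB
    lambda: 0.02
    threshold: 6000.0
    n: 4
  - source: ZEB
    target: miR200
    lambda: 0.2
    threshold: 250.0
    n: 4
  - source: ZEB
    target: ZEB
    lambda: 4.0
    threshold: 2500.0
    n: 4
  - source: KLF4
    target: SLUG
    lambda: 0.6
    threshold: 1200.0
    n: 2
  - source: ELF3
    target: ELF3
    lambda: 3.0
    threshold: 2500.0
    n: 2
  - source: SNAIL
    target: ELF3
    lambda: 0.1
    threshold: 450000.0
    n: 2
  - source: SLUG
    target: ELF3
    lambda: 0.7
    threshold: 3000.0
    n: 2
  - source: ELF3
    target: ZEB
    lambda: 0.42
    threshold: 2500.0
    n: 2
  - source: WT1
    target: WT1
    lambda: 0.3
    threshold: 700.0
    n: 2
  - source: WT1
    target: SNAIL
    lambda: 2.2
    threshold: 800.0
    n: 2
  - source: WT1
    target: SLUG
    lambda: 0.6
    threshold: 800.0
    n: 2
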