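{
  "air": [
    0.5542,
    0.1725
  ],
  "water": [
    1.0461,
    0.25
  ],
  "soil": [
    1.1987,
    0.1188
  ],
  "brick": [
    0.3455,
    0.2256
  ],
  "concrete": [
    0.2744,
    0.2815
  ],
  "asphalt": [
    0.2801,
    0.3
  ],
  "wood": [
    0.4539,
    0.1319
  ],
  "insulation": [
    0.4798,
    0.0387
  ],
  "glass": [
    0.4492,
    0.1262
  ],
  "default": [
    0.31,
    0.2536
  ]
}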