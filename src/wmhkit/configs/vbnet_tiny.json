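{
  "in_channels": 3,
  "out_channels": 3,
  "levels": 3,
  "channels": [12, 24, 48],
  "bottleneck_ratio": 4,
  "enc_blocks": [1, 1, 1],
  "dec_blocks": [1, 1],
  "crop_size": 64
}
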