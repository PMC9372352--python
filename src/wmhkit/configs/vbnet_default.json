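{
  "in_channels": 3,
  "out_channels": 3,
  "levels": 5,
  "channels": [24, 48, 96, 192, 280],
  "bottleneck_ratio": 4,
  "enc_blocks": [1, 2, 3, 3, 2],
  "dec_blocks": [1, 2, 3, 2],
  "crop_size": 256
}
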