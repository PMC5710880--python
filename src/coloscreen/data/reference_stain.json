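{
  "h_vector": [
    0.6069929599761963,
    0.7462167143821716,
    0.2733500301837921
  ],
  "e_vector": [
    0.11613740026950836,
    0.9861753582954407,
    0.11819590628147125
  ],
  "h_scale_percentiles": [
    0.02842705138027668,
    0.9563801884651184
  ],
  "e_scale_percentiles": [
    0.32199251651763916,
    0.47736454010009766
  ],
  "white_point": [
    246.16819763183594,
    247.68417358398438,
    245.1686553955078
  ]
}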