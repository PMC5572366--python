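{
  "label": "memristive 3-neuron Hopfield network, reference parameters",
  "k": 0.8,
  "a": 1.0,
  "b": 0.26,
  "weights": [[-1.4, 1.2, -7.0], [1.1, 0.0, 2.8], [null, -2.0, 4.0]],
  "memristive_slot": [2, 0]
}
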