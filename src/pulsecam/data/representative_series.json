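{
  "description": "Published 10-harmonic Fourier coefficients of a representative human radial pressure pulse (healthy young adult male), normalized period T = 1. Evaluating a0 + sum_k [a_k cos(2 pi k theta) + b_k sin(2 pi k theta)] yields the three-peak radial waveform (percussion peak, late-systolic peak, dicrotic wave).",
  "notes": "The symbol of the fifth cosine coefficient is garbled in the published coefficient listing ('e5'); its value 0.1227 is adopted as a5.",
  "n": 10,
  "a0": 0.9490,
  "a": [0.5150, 0.2893, 0.2838, 0.1498, 0.1227, 0.1177, 0.0569, 0.0105, 0.0008, 0.0056],
  "b": [0.5873, 0.1871, 0.0459, -0.0032, -0.1109, -0.0743, -0.0196, -0.0086, -0.0043, -0.0007]
}
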