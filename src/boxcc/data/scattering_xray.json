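{
  "name": "it92-xray",
  "version": 1,
  "description": "X-ray atomic scattering factor fits f(s) = sum_i a_i exp(-b_i s^2) + c with s = sin(theta)/lambda = 1/(2d), a_i and c in electrons, b_i in A^2. Four-Gaussian-plus-constant analytic fits from International Tables for Crystallography Vol. C (Cromer-Mann form), padded with a fifth zero-amplitude Gaussian so every element carries five (a_i, b_i) pairs plus the constant term.",
  "constant_policy": "fold_as_zero_width_gaussian",
  "elements": {
    "H": {"a": [0.493002, 0.322912, 0.140191, 0.04081, 0.0],
          "b": [10.5109, 26.1257, 3.14236, 57.7997, 1.0],
          "c": 0.003038, "z": 1},
    "C": {"a": [2.31, 1.02, 1.5886, 0.865, 0.0],
          "b": [20.8439, 10.2075, 0.5687, 51.6512, 1.0],
          "c": 0.2156, "z": 6},
    "N": {"a": [12.2126, 3.1322, 2.0125, 1.1663, 0.0],
          "b": [0.0057, 9.8933, 28.9975, 0.5826, 1.0],
          "c": -11.529, "z": 7},
    "O": {"a": [3.0485, 2.2868, 1.5463, 0.867, 0.0],
          "b": [13.2771, 5.7011, 0.3239, 32.9089, 1.0],
          "c": 0.2508, "z": 8},
    "S": {"a": [6.9053, 5.2034, 1.4379, 1.5863, 0.0],
          "b": [1.4679, 22.2151, 0.2536, 56.172, 1.0],
          "c": 0.8669, "z": 16}
  }
}
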