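# Example scenario grid: the full 3x3 strength-by-confounding design at
# n = 30000 is expensive; this reduced grid runs in a few minutes.
scenarios:
  - {strength: weak, confounding: high, n: 10000, ns: 50}
  - {strength: mod, confounding: high, n: 10000, ns: 50}
  - {strength: strong, confounding: high, n: 10000, ns: 50}
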