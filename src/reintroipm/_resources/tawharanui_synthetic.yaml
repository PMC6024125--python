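# End-to-end pipeline on a simulated dataset mirroring the case study.
out: results/tawharanui_synthetic
seed: 20070301
simulate:
  years: 9
  dd: false
fits:
  - {mode: uninformative, dd: false}
  - {mode: informative, dd: false}
sequential:
  kmin: 2
  kmax: 4
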