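# Unrestricted biexponential phantom, no noise: isolates the reference-scheme
# artifact (fixed-q0 induces apparent diffusion-time dependence, fixed-b0 not).
seed: 7
phantom:
  wm_model: {type: biexp, f_s: 0.3, D_s: 0.2, D_f: 1.0}
  gm_model: {type: biexp, f_s: 0.3, D_s: 0.2, D_f: 1.0}
  sigma: 0.0
  snr: null
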