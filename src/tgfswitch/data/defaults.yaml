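# Default parameter sets of the TGF-β1–THBS1–FMOD switch models.
#
# core: dose-response fit of the steady-state curves under the
#   d1 = d2 = d3 = 1 convention (so a ≡ a/d1 etc.).  c (≡ c/d3) is
#   unspecified by the dose-response fit alone: the K1/K2 bistability scans
#   keep it as a free choice, and the endogenous analysis replaces it by γ.
# extended: endogenous/PDL fit; gamma is the endogenous TGF-β1 normalized
#   production rate, K1t/K2t the endogenous half-saturation constants.
core:
  a: 2.36
  d1: 1.0
  b: 0.33
  d2: 1.0
  c: 1.0          # unspecified by the dose-response fit; see note above
  d3: 1.0
  Ka: 0.016
  Kb: 0.002
  K1: 1.0         # placeholder; endogenous substitution sets 0.46
  K2: 1.0         # placeholder; endogenous substitution sets 0.62
  na: 1.6
  nb: 1.7
extended:
  alpha: 3.0
  beta: 5.0
  gamma: 3.5
  Kalpha: 10.1
  Kbeta: 5.0
  K1t: 0.46
  K2t: 0.62
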