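# Example randomization overrides matching the published Bizkaia analysis:
# the outpatient frequentation indicator was randomized with a uniform
# (rectangular) law, instead of the default triangular one, in four areas.
# Cell selection is an expert, dataset-specific choice, not a rule.
weights:
  w_tl: 0.9
  w_tr: 1.1
  w_ur: 1.1
uniform_cells:
  - {dmu: Barakaldo, variable: UFrecO8+O10}
  - {dmu: Ercilla, variable: UFrecO8+O10}
  - {dmu: Sestao, variable: UFrecO8+O10}
  - {dmu: Uribe, variable: UFrecO8+O10}
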