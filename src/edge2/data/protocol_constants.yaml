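# EDGE2 protocol constants, version 1.
# Extinction-probability anchors use the 50-year horizon CR value (0.97),
# halving with each step down in Red List severity. The rank axis splits
# [0, 1] into five equal-width category intervals ordered LC -> CR, with
# each anchor at its interval midpoint. Clip bounds keep sampled
# probabilities away from the 0 and 1 extremes.
version: 1
clip_lower: 0.0001
clip_upper: 0.9999
anchors:
  LC: 0.060625
  NT: 0.12125
  VU: 0.2425
  EN: 0.485
  CR: 0.97
rank_intervals:
  LC: [0.0, 0.2]
  NT: [0.2, 0.4]
  VU: [0.4, 0.6]
  EN: [0.6, 0.8]
  CR: [0.8, 1.0]
ge1_weights:
  LC: 0
  NT: 1
  VU: 2
  EN: 3
  CR: 4
ew_probability: 0.9999
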